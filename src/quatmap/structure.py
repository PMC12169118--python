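"""Coordinate data model for multichain protein structures.

The model is deliberately small: a :class:`Structure` is an ordered map of
chains, each chain an ordered list of :class:`Residue` objects addressed by
author numbering (the residue numbers printed in the PDB ATOM records,
including insertion codes).  Author numbering is the coordinate system for
every downstream operation, because published quaternary-epitope cluster
tables reference residues as ``NAME.number.chain`` labels in author numbers.

PDB reading is delegated to :mod:`biotite`; this module only converts the
atom arrays into the residue-level model, resolves altloc duplicates by
highest occupancy, and drops waters and non-polymer heteroatoms.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ChainNotFoundError,
    EmptyStructureError,
    LabelFormatError,
    PDBParseError,
    ResidueNotFoundError,
)

__all__ = [
    "Atom",
    "ResidueKey",
    "Residue",
    "Structure",
    "ClusterTable",
    "parse_pdb",
    "read_pdb",
    "chain_sequence",
    "parse_residue_label",
    "format_residue_label",
    "write_cluster_table",
    "write_fasta",
]

#: Standard 20 amino acids, three-letter -> one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element symbol and Cartesian position in Å."""

    name: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Address of a residue: chain id, author number, insertion code."""

    chain_id: str
    number: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ValueError("chain_id must be non-empty")

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.number}{self.insertion_code}"


@dataclass
class Residue:
    """A residue: key, three-letter name, atoms, and its Cα if present."""

    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)
    ca: Atom | None = None

    def __post_init__(self) -> None:
        self.name = self.name.upper()
        if self.ca is not None and self.ca not in self.atoms:
            raise ValueError(f"Cα of {self.key} is not among its atoms")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of all non-hydrogen atoms, shape (n, 3)."""
        pts = [a.position for a in self.atoms if a.element.upper() not in ("H", "D")]
        return np.asarray(pts, dtype=float).reshape(-1, 3)


class Structure:
    """A multichain structure: ordered chains of ordered residues.

    Residues within each chain are kept sorted by (author number, insertion
    code); duplicate :class:`ResidueKey` values are rejected.
    """

    def __init__(self, id: str, chains: Mapping[str, Sequence[Residue]]):
        if not chains:
            raise EmptyStructureError(f"structure {id!r} has no chains")
        self.id = id
        self.chains: dict[str, list[Residue]] = {}
        seen: set[ResidueKey] = set()
        for chain_id, residues in chains.items():
            ordered = sorted(residues, key=lambda r: (r.key.number, r.key.insertion_code))
            for r in ordered:
                if r.key.chain_id != chain_id:
                    raise ValueError(f"residue {r.key} filed under chain {chain_id!r}")
                if r.key in seen:
                    raise ValueError(f"duplicate residue key {r.key}")
                seen.add(r.key)
            self.chains[chain_id] = list(ordered)
        self._index: dict[ResidueKey, Residue] = {
            r.key: r for residues in self.chains.values() for r in residues
        }

    def __repr__(self) -> str:
        n = sum(len(c) for c in self.chains.values())
        return f"<Structure {self.id}: {len(self.chains)} chains, {n} residues>"

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    def __getitem__(self, key: ResidueKey) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise ResidueNotFoundError(
                f"residue {key} not found in structure {self.id!r}"
            ) from None

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    def n_residues(self) -> int:
        return len(self._index)

    def find(self, chain_id: str, number: int, insertion_code: str = "") -> Residue:
        """Look up a residue by chain + author number (names are advisory)."""
        return self[ResidueKey(chain_id, number, insertion_code)]


@dataclass
class ClusterTable:
    """Rows of residue labels, e.g. parsed from a published cluster listing."""

    structure_id: str
    rows: list[list[tuple[ResidueKey, str]]]

    def __post_init__(self) -> None:
        for i, row in enumerate(self.rows):
            if len(row) < 2:
                raise ValueError(f"cluster row {i} has fewer than 2 residues")


# ---------------------------------------------------------------------------
# PDB reading


def _check_atom_lines(text: str) -> None:
    """Cheap pre-scan so parse failures can name the offending line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        try:
            int(line[22:26])
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: unparsable number in coordinate record"
            ) from None


def parse_pdb(text: str, id: str = "structure") -> Structure:
    """Parse PDB-format content into a :class:`Structure`.

    Keeps polymer (amino-acid) residues only; waters and other heteroatoms
    are dropped.  Altloc duplicates are resolved to the highest-occupancy
    conformer (ties: first seen).  Author numbering and insertion codes are
    preserved verbatim.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if "ATOM" not in text and "HETATM" not in text:
        raise EmptyStructureError("no ATOM records in input")
    _check_atom_lines(text)
    try:
        pdb_file = pdbio.PDBFile.read(io.StringIO(text))
        atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises several error types
        raise PDBParseError(f"could not parse PDB content: {exc}") from exc

    mask = struc.filter_amino_acids(atoms)
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise EmptyStructureError("input contains zero polymer residues")

    chains: dict[str, dict[ResidueKey, Residue]] = {}
    for i in range(atoms.array_length()):
        chain_id = str(atoms.chain_id[i])
        key = ResidueKey(chain_id, int(atoms.res_id[i]), str(atoms.ins_code[i]).strip())
        atom = Atom(
            name=str(atoms.atom_name[i]),
            element=str(atoms.element[i]) or "X",
            position=tuple(float(x) for x in atoms.coord[i]),
        )
        res = chains.setdefault(chain_id, {}).get(key)
        if res is None:
            res = Residue(key=key, name=str(atoms.res_name[i]), atoms=[])
            chains[chain_id][key] = res
        res.atoms.append(atom)
        if atom.name == "CA" and atom.element.upper() == "C":
            res.ca = atom

    return Structure(id, {cid: list(resmap.values()) for cid, resmap in chains.items()})


def read_pdb(path, id: str | None = None) -> Structure:
    """Read a PDB file from disk; the structure id defaults to the file stem."""
    from pathlib import Path

    p = Path(path)
    return parse_pdb(p.read_text(), id=id or p.stem)


# ---------------------------------------------------------------------------
# Sequences


def chain_sequence(structure: Structure, chain_id: str) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain plus the positionally parallel key list.

    Nonstandard residue names (e.g. MSE) become ``'X'`` but remain
    addressable through the returned keys.
    """
    if chain_id not in structure.chains:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not in structure {structure.id!r} "
            f"(present: {sorted(structure.chains)})"
        )
    residues = structure.chains[chain_id]
    seq = "".join(r.one_letter for r in residues)
    return seq, [r.key for r in residues]


def write_fasta(structure: Structure, chain_ids: Sequence[str] | None = None) -> str:
    """Render chain sequences as FASTA text (one record per chain)."""
    out = []
    for cid in chain_ids or structure.chains:
        seq, _ = chain_sequence(structure, cid)
        out.append(f">{structure.id}_{cid}")
        out.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Residue-label notation ("TYR.69.D")

_NUMBER_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def parse_residue_label(
    label: str, default_chain: str | None = None
) -> tuple[ResidueKey, str]:
    """Parse a ``NAME.number.chain`` residue label into (key, residue name).

    Tolerant of repeated separators (``GLU..280.A``) and of unrecognized
    residue-name spellings: the name is advisory, matching downstream is by
    chain + author number.  Labels lacking the chain field (they occur in
    published tables) resolve to *default_chain* if given.
    """
    if not label or not label.strip():
        raise LabelFormatError("empty residue label")
    tokens = [t for t in label.strip().split(".") if t]
    name = ""
    number: int | None = None
    ins = ""
    chain: str | None = None
    for tok in tokens:
        m = _NUMBER_RE.match(tok)
        if m and number is None:
            number = int(m.group(1))
            ins = m.group(2)
        elif number is None:
            name = tok.upper()
        else:
            chain = tok
    if number is None:
        raise LabelFormatError(f"no residue number in label {label!r}")
    if chain is None:
        chain = default_chain
    if chain is None:
        raise LabelFormatError(f"no chain in label {label!r} and no default given")
    return ResidueKey(chain, number, ins), name


def format_residue_label(key: ResidueKey, name: str) -> str:
    return f"{name}.{key.number}{key.insertion_code}.{key.chain_id}"


def parse_cluster_rows(text: str, structure_id: str = "") -> ClusterTable:
    """Parse cluster rows of comma-separated residue labels.

    One cluster per non-comment line.  Labels lacking a chain field inherit
    the chain of the next label in the row that carries one (published
    listings occasionally omit the chain on leading members of a row).
    """
    rows: list[list[tuple[ResidueKey, str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        labels = [t.strip() for t in line.split(",") if t.strip()]
        # resolve omitted chains from the right
        chains: list[str | None] = []
        for label in labels:
            tokens = [t for t in label.split(".") if t]
            explicit = None
            for tok in reversed(tokens):
                if not _NUMBER_RE.match(tok) and tok is not tokens[0]:
                    explicit = tok
                    break
            chains.append(explicit)
        next_chain: str | None = None
        defaults: list[str | None] = [None] * len(labels)
        for i in range(len(labels) - 1, -1, -1):
            if chains[i] is not None:
                next_chain = chains[i]
            defaults[i] = next_chain
        row = [
            parse_residue_label(label, default_chain=default)
            for label, default in zip(labels, defaults)
        ]
        rows.append(row)
    return ClusterTable(structure_id=structure_id, rows=rows)


def load_published_clusters(structure_id: str) -> ClusterTable:
    """Load the shipped published cluster listing for a uricase PDB entry."""
    from importlib import resources

    ref = resources.files("quatmap").joinpath(
        f"data/published_clusters/{structure_id.lower()}.clusters.tsv"
    )
    with ref.open() as fh:
        return parse_cluster_rows(fh.read(), structure_id=structure_id.upper())


# ---------------------------------------------------------------------------
# Cluster-table output


def write_cluster_table(structure: Structure, clusters) -> tuple[str, pd.DataFrame]:
    """Render quaternary clusters in the published label notation plus a table.

    Returns ``(text, frame)``: *text* has one comma-separated row of
    ``NAME.number.chain`` labels per cluster; *frame* is the machine-readable
    long form with columns structure_id, cluster_index, chain, number, name,
    role.  Ordering is deterministic: clusters sorted by (lowest chain,
    lowest residue number), members sorted chain-then-number, seeds before
    neighbors in the long form via the role column.
    """
    def member_sort(key: ResidueKey):
        return (key.chain_id, key.number, key.insertion_code)

    prepared = []
    for cl in clusters:
        seeds = sorted(cl.seeds, key=member_sort)
        neighbors = sorted(cl.neighbors, key=member_sort)
        members = sorted(list(cl.seeds) + list(cl.neighbors), key=member_sort)
        prepared.append((members, seeds, neighbors))
    prepared.sort(key=lambda t: [member_sort(k) for k in t[0]])

    lines = []
    records = []
    for idx, (members, seeds, neighbors) in enumerate(prepared):
        labels = [
            format_residue_label(k, structure[k].name) for k in members
        ]
        lines.append(", ".join(labels))
        for role, keys in (("seed", seeds), ("neighbor", neighbors)):
            for k in keys:
                records.append(
                    {
                        "structure_id": structure.id,
                        "cluster_index": idx,
                        "chain": k.chain_id,
                        "number": k.number,
                        "name": structure[k].name,
                        "role": role,
                    }
                )
    frame = pd.DataFrame(
        records,
        columns=["structure_id", "cluster_index", "chain", "number", "name", "role"],
    )
    text = "\n".join(lines) + ("\n" if lines else "")
    return text, frame
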