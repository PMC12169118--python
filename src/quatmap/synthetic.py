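"""Synthetic structures and score tracks with known ground truth.

The generators exist so every pipeline stage can be exercised without any
download: :func:`make_toy_complex` emits small multichain structures with
planted inter-chain contact patches at requested distances, and
:func:`make_synthetic_tracks` emits per-residue predictor score tracks with
planted positive regions plus positionwise flip noise.

Geometry is lattice-like and deliberately non-physical — chains are
straight Cα traces at the canonical 3.8 Å consecutive spacing, placed far
apart (> 20 Å) except where a contact patch relocates residues of one chain
next to the partner chain at the requested distance.  The pipeline consumes
only distances, so sterics and side chains are irrelevant; each residue
carries a pseudo-Cβ 1.5 Å off the trace so that ``any_heavy`` distance mode
has more than one atom to consider.

All randomness flows through the explicit integer seed in each spec, and
identical specs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ScoreTrack
from .errors import SyntheticSpecError
from .structure import Atom, Residue, ResidueKey, Structure

__all__ = [
    "ContactPatch",
    "ComplexSpec",
    "TrackSpec",
    "make_toy_complex",
    "make_synthetic_tracks",
    "structure_to_pdb",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CA_SPACING = 3.8     # Å between consecutive residues along a trace
_CHAIN_OFFSET = 100.0  # Å between chain baselines; >> any contact radius

# cyclic dummy sequence so chains have nontrivial, known sequences
_DUMMY_SEQ = ("ALA", "GLY", "SER", "LEU", "LYS", "ASP", "PHE", "THR", "VAL", "GLU")


@dataclass(frozen=True)
class ContactPatch:
    """Pairs residues of two chains at a target distance.

    ``residues_x[k]`` of ``chain_x`` is paired with ``residues_y[k]`` of
    ``chain_y`` (1-based residue numbers); each y-residue is relocated to
    sit exactly ``distance`` Å from its partner.
    """

    chain_x: str
    residues_x: tuple[int, ...]
    chain_y: str
    residues_y: tuple[int, ...]
    distance: float = 5.0


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for a toy multichain complex."""

    n_chains: int = 4
    residues_per_chain: int = 30
    contact_patches: tuple[ContactPatch, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class TrackSpec:
    """Recipe for synthetic predictor score tracks.

    ``regions`` maps predictor name to its planted positive intervals
    (1-based inclusive).  Scores are 1 inside regions and 0 outside, then
    flipped positionwise with probability ``noise``; the threshold 0.5
    makes binarization recover exactly the noisy calls.
    """

    length: int = 100
    regions: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = ()
    noise: float = 0.0
    seed: int = 0
    sequence_id: str = "synthetic"


def _validate_complex(spec: ComplexSpec) -> None:
    if spec.n_chains < 1 or spec.n_chains > len(_CHAIN_IDS):
        raise SyntheticSpecError(f"n_chains must be in 1..26, got {spec.n_chains}")
    if spec.residues_per_chain < 1:
        raise SyntheticSpecError("residues_per_chain must be positive")
    chain_ids = set(_CHAIN_IDS[: spec.n_chains])
    moved: set[tuple[str, int]] = set()
    for patch in spec.contact_patches:
        if patch.chain_x not in chain_ids or patch.chain_y not in chain_ids:
            raise SyntheticSpecError(f"patch references unknown chain: {patch}")
        if patch.chain_x == patch.chain_y:
            raise SyntheticSpecError("contact patches must join different chains")
        if len(patch.residues_x) != len(patch.residues_y):
            raise SyntheticSpecError("patch residue lists must pair up 1:1")
        if patch.distance <= 0:
            raise SyntheticSpecError("patch distance must be positive")
        if patch.distance < 1.0:
            raise SyntheticSpecError(
                f"patch distance {patch.distance} Å is infeasible for a Cα trace "
                f"with {_CA_SPACING} Å consecutive spacing"
            )
        for r in patch.residues_x + patch.residues_y:
            if not 1 <= r <= spec.residues_per_chain:
                raise SyntheticSpecError(f"patch residue {r} out of range")
        for r in patch.residues_y:
            if (patch.chain_y, r) in moved:
                raise SyntheticSpecError(
                    f"residue {patch.chain_y}:{r} relocated by two patches"
                )
            moved.add((patch.chain_y, r))


def make_toy_complex(
    spec: ComplexSpec,
) -> tuple[Structure, list[tuple[ResidueKey, ResidueKey, float]]]:
    """Build a toy complex and its ground-truth cross-chain contact list.

    Returns ``(structure, contacts)`` where *contacts* lists every
    cross-chain residue pair within 6 Å as ``(key_a, key_b, distance)``,
    recomputed from the emitted coordinates by a brute-force scan — the
    ground truth is therefore self-consistent by construction.
    """
    _validate_complex(spec)
    rng = np.random.default_rng(spec.seed)

    # baseline trace positions; tiny seeded jitter so no two runs of
    # different seeds are accidentally identical
    positions: dict[tuple[str, int], np.ndarray] = {}
    for ci in range(spec.n_chains):
        chain_id = _CHAIN_IDS[ci]
        jitter = rng.uniform(-0.1, 0.1, size=3)
        for ri in range(1, spec.residues_per_chain + 1):
            positions[(chain_id, ri)] = np.array(
                [ri * _CA_SPACING, ci * _CHAIN_OFFSET, 0.0]
            ) + jitter

    for patch in spec.contact_patches:
        for rx, ry in zip(patch.residues_x, patch.residues_y):
            anchor = positions[(patch.chain_x, rx)]
            positions[(patch.chain_y, ry)] = anchor + np.array(
                [0.0, patch.distance, 0.0]
            )

    chains: dict[str, list[Residue]] = {}
    for ci in range(spec.n_chains):
        chain_id = _CHAIN_IDS[ci]
        residues = []
        for ri in range(1, spec.residues_per_chain + 1):
            pos = positions[(chain_id, ri)]
            ca = Atom("CA", "C", tuple(pos))
            cb = Atom("CB", "C", tuple(pos + np.array([0.0, 0.0, 1.5])))
            residues.append(
                Residue(
                    key=ResidueKey(chain_id, ri),
                    name=_DUMMY_SEQ[(ri - 1) % len(_DUMMY_SEQ)],
                    atoms=[ca, cb],
                    ca=ca,
                )
            )
        chains[chain_id] = residues
    structure = Structure(f"toy-{spec.seed}", chains)

    contacts = _brute_force_contacts(structure, cutoff=6.0)
    return structure, contacts


def _brute_force_contacts(
    structure: Structure, cutoff: float
) -> list[tuple[ResidueKey, ResidueKey, float]]:
    """All cross-chain residue pairs within *cutoff* (min heavy-atom dist)."""
    residues = list(structure.residues())
    out = []
    for i, a in enumerate(residues):
        pa = a.heavy_coords()
        for b in residues[i + 1 :]:
            if a.key.chain_id == b.key.chain_id:
                continue
            pb = b.heavy_coords()
            d = float(
                np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2))
            )
            if d <= cutoff:
                pair = tuple(sorted((a.key, b.key)))
                out.append((pair[0], pair[1], d))
    return sorted(out)


def make_synthetic_tracks(spec: TrackSpec) -> list[ScoreTrack]:
    """Emit one score track per predictor named in the spec."""
    if not 0 <= spec.noise < 0.5:
        raise SyntheticSpecError(f"noise rate must be in [0, 0.5), got {spec.noise}")
    rng = np.random.default_rng(spec.seed)
    tracks = []
    for predictor, regions in spec.regions:
        scores = np.zeros(spec.length)
        for start, end in regions:
            if not 1 <= start <= end <= spec.length:
                raise SyntheticSpecError(
                    f"region {start}-{end} outside 1..{spec.length}"
                )
            scores[start - 1 : end] = 1.0
        if spec.noise > 0:
            flips = rng.random(spec.length) < spec.noise
            scores[flips] = 1.0 - scores[flips]
        tracks.append(
            ScoreTrack(
                predictor_name=predictor,
                sequence_id=spec.sequence_id,
                scores=scores,
                threshold=0.5,
            )
        )
    return tracks


def structure_to_pdb(structure: Structure) -> str:
    """Serialize a structure to minimal PDB text (ATOM/TER records only)."""
    lines = []
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:>5} {atom.name:^4}{res.name:>4}"
                    f" {chain_id}{res.key.number:>4}{res.key.insertion_code or ' ':1}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
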