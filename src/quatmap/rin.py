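"""Residue interaction networks (RINs) at a distance cutoff.

A RIN has one node per residue and an edge between residues whose distance
is at most the cutoff — 6 Å between Cα atoms by default, which is the
standard construction for network analysis of protein structures.  In
``any_heavy`` mode the inter-residue distance is instead the minimum over
all heavy-atom pairs, the natural choice when the network feeds an
atom-zone selection.

The interface subnetwork — edges whose endpoints lie on different chains,
plus their incident nodes — is where quaternary (inter-chain) epitopes
live.  Graphs are :class:`networkx.Graph` objects with residue keys as
nodes, wrapped to carry the construction parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError
from .structure import ResidueKey, Structure

__all__ = ["RINGraph", "build_rin", "interface_subnetwork", "export_sif",
           "edge_attribute_frame", "node_attribute_frame"]

logger = logging.getLogger(__name__)

CA_MODE = "CA"
ANY_HEAVY = "any_heavy"


@dataclass
class RINGraph:
    """A residue contact graph plus the parameters it was built with."""

    graph: nx.Graph
    cutoff: float
    atom_mode: str
    structure_id: str = ""

    @property
    def nodes(self) -> set[ResidueKey]:
        return set(self.graph.nodes)

    def edges(self):
        """Edges as (key_a, key_b, attrs) with keys in sorted order."""
        for u, v, attrs in self.graph.edges(data=True):
            a, b = sorted((u, v))
            yield a, b, attrs

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _residue_coords(structure: Structure, atom_mode: str):
    """(keys, per-residue coordinate arrays); skips Cα-less residues in CA mode."""
    keys, coords = [], []
    for res in structure.residues():
        if atom_mode == CA_MODE:
            if res.ca is None:
                logger.warning(
                    "residue %s (%s) lacks a Cα atom; skipped in CA mode",
                    res.key, res.name,
                )
                continue
            keys.append(res.key)
            coords.append(np.asarray(res.ca.position, dtype=float).reshape(1, 3))
        else:
            pts = res.heavy_coords()
            if len(pts) == 0:
                logger.warning("residue %s (%s) has no heavy atoms; skipped",
                               res.key, res.name)
                continue
            keys.append(res.key)
            coords.append(pts)
    return keys, coords


def build_rin(
    structure: Structure, cutoff: float = 6.0, atom_mode: str = CA_MODE
) -> RINGraph:
    """Build the residue interaction network of *structure*.

    An edge connects two distinct residues whose distance (Cα–Cα, or minimum
    over heavy-atom pairs) is ≤ *cutoff* Å.  Sequence-adjacent pairs are
    kept but flagged ``sequence_adjacent``; inter-chain edges are flagged
    ``inter_chain``.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if atom_mode not in (CA_MODE, ANY_HEAVY):
        raise ParameterError(f"unknown atom_mode {atom_mode!r}")

    keys, coords = _residue_coords(structure, atom_mode)
    g = nx.Graph()
    g.add_nodes_from(keys)

    # chain-order adjacency (not just number difference: insertion codes)
    adjacent: set[frozenset[ResidueKey]] = set()
    for chain in structure.chains.values():
        present = [r.key for r in chain if r.key in set(keys)]
        for a, b in zip(present, present[1:]):
            adjacent.add(frozenset((a, b)))

    if keys:
        flat = np.concatenate(coords)
        owner = np.repeat(np.arange(len(keys)), [len(c) for c in coords])
        tree = cKDTree(flat)
        pair_min: dict[tuple[int, int], float] = {}
        for ia, ib in tree.query_pairs(cutoff):
            ra, rb = int(owner[ia]), int(owner[ib])
            if ra == rb:
                continue
            if ra > rb:
                ra, rb = rb, ra
            d = float(np.linalg.norm(flat[ia] - flat[ib]))
            prev = pair_min.get((ra, rb))
            if prev is None or d < prev:
                pair_min[(ra, rb)] = d
        for (ra, rb), d in pair_min.items():
            ka, kb = keys[ra], keys[rb]
            g.add_edge(
                ka, kb,
                distance=d,
                inter_chain=ka.chain_id != kb.chain_id,
                sequence_adjacent=frozenset((ka, kb)) in adjacent,
            )
    return RINGraph(graph=g, cutoff=cutoff, atom_mode=atom_mode,
                    structure_id=structure.id)


def interface_subnetwork(rin: RINGraph) -> RINGraph:
    """Keep exactly the inter-chain edges and their incident nodes."""
    sub = nx.Graph()
    for u, v, attrs in rin.graph.edges(data=True):
        if attrs["inter_chain"]:
            sub.add_edge(u, v, **attrs)
    return RINGraph(graph=sub, cutoff=rin.cutoff, atom_mode=rin.atom_mode,
                    structure_id=rin.structure_id)


def _sorted_edges(rin: RINGraph):
    return sorted(rin.edges(), key=lambda e: (e[0], e[1]))


def export_sif(rin: RINGraph, interaction: str = "contact") -> str:
    """Render the graph as SIF text (one ``node interaction node`` line per
    edge), deterministically ordered for byte-identical reruns."""
    lines = [f"{a} {interaction} {b}" for a, b, _ in _sorted_edges(rin)]
    return "\n".join(lines) + ("\n" if lines else "")


def edge_attribute_frame(rin: RINGraph) -> pd.DataFrame:
    """Companion edge table: distance, inter_chain, sequence_adjacent."""
    rows = [
        {
            "source": str(a),
            "target": str(b),
            "distance": round(attrs["distance"], 4),
            "inter_chain": attrs["inter_chain"],
            "sequence_adjacent": attrs["sequence_adjacent"],
        }
        for a, b, attrs in _sorted_edges(rin)
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "distance", "inter_chain",
                       "sequence_adjacent"]
    )


def node_attribute_frame(rin: RINGraph, structure: Structure) -> pd.DataFrame:
    """Node table: chain, author number, residue name, degree."""
    rows = [
        {
            "node": str(k),
            "chain": k.chain_id,
            "number": k.number,
            "name": structure[k].name if k in structure else "",
            "degree": rin.graph.degree[k],
        }
        for k in sorted(rin.graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "chain", "number", "name", "degree"])
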