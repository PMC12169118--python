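"""Quaternary-epitope localization by cross-chain proximity.

A quaternary epitope exists only in the assembled multimer: residues from
different chains jointly form the antibody-binding surface.  Starting from
conformational-epitope residues on one chain (the *seeds*), every residue on
a *different* chain within a fixed radius (default 6 Å) of a seed is
selected as a potential quaternary-epitope residue.  Seeds and their
cross-chain neighbors are then grouped into clusters — connected components
of the seed↔neighbor contact relation — and any component confined to a
single chain is discarded, since it cannot be quaternary.

Distances default to the minimum over heavy-atom pairs (``any_heavy``),
matching an atom-zone selection around the seed residues; Cα–Cα mode is
available for consistency with the interaction-network construction.

A monomer can never yield a cluster: with one chain there are no cross-chain
neighbors at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateClusterError, ParameterError, ResidueNotFoundError
from .rin import ANY_HEAVY, CA_MODE
from .structure import ResidueKey, Structure

__all__ = [
    "EpitopeSeedSet",
    "QuaternaryCluster",
    "select_cross_chain_neighbors",
    "build_quaternary_clusters",
    "verify_cluster_geometry",
]


@dataclass
class EpitopeSeedSet:
    """Conformational-epitope residues seeding the cross-chain search."""

    structure_id: str
    residues: set[ResidueKey] = field(default_factory=set)

    def validate(self, structure: Structure) -> None:
        for key in self.residues:
            if key not in structure:
                raise ResidueNotFoundError(
                    f"seed residue {key} not present in structure {structure.id!r}"
                )


@dataclass
class QuaternaryCluster:
    """One inter-chain epitope cluster: seeds plus cross-chain neighbors."""

    seeds: set[ResidueKey]
    neighbors: set[ResidueKey]

    def __post_init__(self) -> None:
        if self.seeds & self.neighbors:
            raise ValueError("seeds and neighbors must be disjoint")
        if len(self.chains_spanned) < 2:
            raise ValueError("a quaternary cluster must span at least 2 chains")

    @property
    def chains_spanned(self) -> set[str]:
        return {k.chain_id for k in self.seeds | self.neighbors}

    @property
    def members(self) -> set[ResidueKey]:
        return self.seeds | self.neighbors


def _residue_points(structure: Structure, atom_mode: str):
    keys, coords = [], []
    for res in structure.residues():
        if atom_mode == CA_MODE:
            if res.ca is None:
                continue
            keys.append(res.key)
            coords.append(np.asarray(res.ca.position).reshape(1, 3))
        else:
            pts = res.heavy_coords()
            if len(pts):
                keys.append(res.key)
                coords.append(pts)
    return keys, coords


def _contact_pairs(
    structure: Structure,
    seeds: EpitopeSeedSet,
    radius: float,
    atom_mode: str,
) -> list[tuple[ResidueKey, ResidueKey]]:
    """All (seed, cross-chain residue) pairs within *radius*."""
    if not seeds.residues:
        raise ParameterError("seed set is empty")
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if atom_mode not in (CA_MODE, ANY_HEAVY):
        raise ParameterError(f"unknown atom_mode {atom_mode!r}")
    seeds.validate(structure)

    keys, coords = _residue_points(structure, atom_mode)
    index = {k: i for i, k in enumerate(keys)}
    flat = np.concatenate(coords) if keys else np.empty((0, 3))
    owner = np.repeat(np.arange(len(keys)), [len(c) for c in coords])
    tree = cKDTree(flat)

    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    for seed in seeds.residues:
        i = index.get(seed)
        if i is None:  # seed exists but has no usable atoms in this mode
            continue
        seed_pts = coords[i]
        hit_atoms = tree.query_ball_point(seed_pts, r=radius)
        hit_res = {int(owner[a]) for atom_hits in hit_atoms for a in atom_hits}
        for j in hit_res:
            other = keys[j]
            if other.chain_id != seed.chain_id:
                pairs.add((seed, other))
    return sorted(pairs)


def select_cross_chain_neighbors(
    structure: Structure,
    seeds: EpitopeSeedSet,
    radius: float = 6.0,
    atom_mode: str = ANY_HEAVY,
) -> set[ResidueKey]:
    """Residues on other chains within *radius* Å of any seed.

    Seed residues themselves are never returned, even when seeds sit on
    multiple chains within range of one another.
    """
    pairs = _contact_pairs(structure, seeds, radius, atom_mode)
    return {n for _, n in pairs} - seeds.residues


def build_quaternary_clusters(
    structure: Structure,
    seeds: EpitopeSeedSet,
    radius: float = 6.0,
    atom_mode: str = ANY_HEAVY,
) -> list[QuaternaryCluster]:
    """Group seeds and their cross-chain neighbors into epitope clusters.

    Clusters are connected components of the bipartite seed↔neighbor contact
    relation.  Seeds with no cross-chain partner drop out; components that
    do not span ≥ 2 chains are discarded.  Output order is deterministic
    (by the smallest member key of each cluster).
    """
    pairs = _contact_pairs(structure, seeds, radius, atom_mode)
    relation = nx.Graph()
    for s, n in pairs:
        relation.add_edge(("seed", s), ("nbr", n))

    clusters = []
    for component in nx.connected_components(relation):
        cseeds = {k for role, k in component if role == "seed"}
        cnbrs = {k for role, k in component if role == "nbr"} - cseeds
        chains = {k.chain_id for k in cseeds | cnbrs}
        if len(chains) < 2:
            continue
        clusters.append(QuaternaryCluster(seeds=cseeds, neighbors=cnbrs))
    clusters.sort(key=lambda c: min(c.members))
    return clusters


def verify_cluster_geometry(
    structure: Structure,
    cluster: list[ResidueKey],
    atom_mode: str = ANY_HEAVY,
) -> float:
    """Worst-case cross-chain separation within a residue cluster, in Å.

    For each residue the minimum distance to any cluster member on a
    different chain is taken; the maximum of those minima is returned.  For
    a cluster built by radius-``r`` cross-chain selection this value cannot
    exceed ``r``, so it is the quantity to check when auditing published
    cluster tables.  Residues are resolved by chain + author number; names
    in labels are advisory.
    """
    residues = [structure[k] for k in cluster]
    chains = {r.key.chain_id for r in residues}
    if len(chains) < 2:
        raise DegenerateClusterError(
            f"cluster lies entirely on chain(s) {sorted(chains)}; "
            "cross-chain distances are undefined"
        )
    points = []
    for res in residues:
        if atom_mode == CA_MODE:
            if res.ca is None:
                raise ResidueNotFoundError(f"residue {res.key} has no Cα atom")
            points.append(np.asarray(res.ca.position).reshape(1, 3))
        else:
            points.append(res.heavy_coords())
    worst = 0.0
    for i, res in enumerate(residues):
        best = np.inf
        for j, other in enumerate(residues):
            if other.key.chain_id == res.key.chain_id:
                continue
            d = np.min(
                np.linalg.norm(points[i][:, None, :] - points[j][None, :, :], axis=2)
            )
            best = min(best, float(d))
        worst = max(worst, best)
    return worst
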