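import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quatmap.structure import Atom, Residue, ResidueKey, Structure

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def ca_residue(chain: str, number: int, pos, name: str = "ALA",
               extra_atoms=()) -> Residue:
    """Residue with a Cα at *pos* (plus optional extra heavy atoms)."""
    ca = Atom("CA", "C", tuple(float(x) for x in pos))
    atoms = [ca] + [Atom(n, "C", tuple(float(x) for x in p)) for n, p in extra_atoms]
    return Residue(key=ResidueKey(chain, number), name=name, atoms=atoms, ca=ca)


def make_structure(residue_specs, id="test") -> Structure:
    """Build a Structure from (chain, number, pos[, name]) tuples."""
    chains = {}
    for spec in residue_specs:
        chain, number, pos = spec[:3]
        name = spec[3] if len(spec) > 3 else "ALA"
        chains.setdefault(chain, []).append(ca_residue(chain, number, pos, name))
    return Structure(id, chains)


@pytest.fixture
def toy_linear_structure():
    """Three Cα-only residues on a line: A:1 (0,0,0), A:2 (4,0,0), B:1 (9,0,0).

    Pairwise distances: A1–A2 = 4, A2–B1 = 5, A1–B1 = 9.
    """
    return make_structure([
        ("A", 1, (0.0, 0.0, 0.0)),
        ("A", 2, (4.0, 0.0, 0.0)),
        ("B", 1, (9.0, 0.0, 0.0), "GLY"),
    ])


def random_ca_structure(rng: np.random.Generator, n_residues: int,
                        n_chains: int = 2, box: float = 40.0,
                        with_sidechain: bool = False) -> Structure:
    """Random coordinates in a box; used against brute-force distance oracles."""
    specs = []
    chains = "ABCDEFGH"[:n_chains]
    per_chain = max(1, n_residues // n_chains)
    for ci, chain in enumerate(chains):
        for ri in range(1, per_chain + 1):
            pos = rng.uniform(0, box, size=3)
            specs.append((chain, ri, pos))
    structure = make_structure(specs)
    if with_sidechain:
        for res in structure.residues():
            offset = rng.uniform(-2, 2, size=3)
            extra = Atom("CB", "C", tuple(np.array(res.ca.position) + offset))
            res.atoms.append(extra)
    return structure
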