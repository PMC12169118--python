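"""Local alignment and Kabsch superposition, checked against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from quatmap.errors import GeometryError, NoAlignmentError
from quatmap.structal import (
    SubstitutionMatrix,
    align_structures,
    kabsch_superpose,
    load_blosum62,
    smith_waterman,
)
from tests.conftest import make_structure

B62 = load_blosum62()


def enumerate_local_score(seq_a, seq_b, matrix=B62, gap_open=11.0, gap_extend=1.0):
    """Brute-force optimal local score: enumerate every order-preserving set
    of matched position pairs; a gap of length L costs open + extend*L."""
    n, m = len(seq_a), len(seq_b)
    best = 0.0
    for k in range(1, min(n, m) + 1):
        for ia in itertools.combinations(range(n), k):
            for ib in itertools.combinations(range(m), k):
                score = sum(matrix.score(seq_a[i], seq_b[j])
                            for i, j in zip(ia, ib))
                for t in range(k - 1):
                    da = ia[t + 1] - ia[t] - 1
                    db = ib[t + 1] - ib[t] - 1
                    if da:
                        score -= gap_open + gap_extend * da
                    if db:
                        score -= gap_open + gap_extend * db
                best = max(best, score)
    return best


class TestSmithWaterman:
    def test_identical_tetra_alanine(self):
        res = smith_waterman("AAAA", "AAAA")
        assert res.score == 16  # 4 x BLOSUM62 A/A = 4
        assert res.pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_negative_single_substitution_gives_empty(self):
        res = smith_waterman("A", "D")  # A/D = -2
        assert res.score == 0 and res.pairs == []

    def test_self_alignment_is_full_diagonal(self):
        seq = "MKTAYIAKQR"
        res = smith_waterman(seq, seq)
        assert res.pairs == [(i, i) for i in range(len(seq))]

    def test_empty_sequence(self):
        assert smith_waterman("", "AAA").score == 0
        assert smith_waterman("AAA", "").pairs == []

    def test_x_scores_zero(self):
        assert B62.score("X", "W") == 0
        assert smith_waterman("XXX", "XXX").score == 0

    def test_pairs_strictly_increase_and_score_matches_pairs(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ARNDCQEGHILKMFPSTWYV"))
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(3, 12)))
            b = "".join(rng.choice(letters, size=rng.integers(3, 12)))
            res = smith_waterman(a, b)
            for (i0, j0), (i1, j1) in zip(res.pairs, res.pairs[1:]):
                assert i1 > i0 and j1 > j0

    def test_matches_enumeration_oracle_on_short_pairs(self):
        rng = np.random.default_rng(42)
        alphabet = "AGKW"  # spans match scores 4..11 and mismatches down to -4
        seqs = ["".join(rng.choice(list(alphabet), size=rng.integers(1, 7)))
                for _ in range(30)]
        for a in seqs[:15]:
            for b in seqs[15:]:
                assert smith_waterman(a, b).score == pytest.approx(
                    enumerate_local_score(a, b)), (a, b)


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(1).uniform(size=(6, 3)) * 10
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_recovers_known_rotation(self):
        pts = np.random.default_rng(2).uniform(size=(8, 3)) * 10
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ Rz.T + np.array([5.0, 0.0, 0.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd <= 1e-10
        # mapping moved -> pts must invert the applied transform
        assert np.allclose(sup.rotation, Rz.T, atol=1e-8)

    def test_mirror_image_keeps_proper_rotation(self):
        # chiral 4-point set; reflection cannot be undone by any rotation
        pts = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 5]], float)
        mirrored = pts * np.array([1, 1, -1])
        sup = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1

    def test_too_few_or_collinear_points(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    def test_rmsd_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(size=(10, 3)) * 10
        B = A + rng.normal(scale=0.5, size=A.shape)
        base = kabsch_superpose(A, B).rmsd
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = kabsch_superpose(A @ R.T + t, B @ R.T + t).rmsd
            assert moved == pytest.approx(base, abs=1e-8)

    def test_not_worse_than_untransformed_pairing(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(size=(12, 3)) * 15
        B = rng.uniform(size=(12, 3)) * 15
        raw = float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
        assert kabsch_superpose(A, B).rmsd <= raw + 1e-12


def helix_specs(seq="MKTAYIAKQRQISFVK", chain="A", seed=0):
    rng = np.random.default_rng(seed)
    one_to_three = {"M": "MET", "K": "LYS", "T": "THR", "A": "ALA", "Y": "TYR",
                    "I": "ILE", "Q": "GLN", "R": "ARG", "S": "SER", "F": "PHE",
                    "V": "VAL"}
    specs = []
    for i, aa in enumerate(seq):
        # loose helical trace; exact geometry is irrelevant, only rigidity is
        pos = (2.3 * np.cos(i), 2.3 * np.sin(i), 1.5 * i) + rng.normal(0, 0.1, 3)
        specs.append((chain, i + 1, pos, one_to_three[aa]))
    return specs


def helix_structure(**kwargs):
    return make_structure(helix_specs(**kwargs), id="helix")


class TestAlignStructures:
    def test_rigid_copy_superposes_exactly(self):
        ref = helix_structure()
        rng = np.random.default_rng(7)
        R, t = random_rigid(rng)
        moved_specs = []
        for res in ref.residues():
            pos = np.array(res.ca.position) @ R.T + t
            moved_specs.append(("A", res.key.number, pos, res.name))
        mobile = make_structure(moved_specs, id="moved")
        aln, sup = align_structures(ref, mobile, "A", "A")
        assert len(aln.pairs) == ref.n_residues()
        assert sup.rmsd <= 1e-8

    def test_residue_rename_does_not_change_geometry(self):
        # interior K -> R (BLOSUM62 K/R = 2 > 0): alignment keeps the pair,
        # and since names never enter coordinates the fit is unchanged
        ref = helix_structure()
        specs = helix_specs()
        chain, number, pos, _ = specs[1]
        specs[1] = (chain, number, pos, "ARG")
        mobile = make_structure(specs, id="renamed")
        aln0, sup0 = align_structures(ref, ref, "A", "A")
        aln1, sup1 = align_structures(ref, mobile, "A", "A")
        assert aln1.pairs == aln0.pairs
        assert sup1.rmsd == pytest.approx(sup0.rmsd, abs=1e-12)

    def test_unalignable_chains_raise(self):
        # W vs (D,G): every substitution is negative, local score stays 0
        a = make_structure([("A", i, (i * 3.8, 0, 0), "TRP") for i in (1, 2, 3)])
        b = make_structure([("A", i, (i * 3.8, 0, 0), ["ASP", "GLY"][i % 2])
                            for i in (1, 2, 3)])
        with pytest.raises(NoAlignmentError):
            align_structures(a, b, "A", "A")

    def test_pruning_drops_outlier_pairs(self):
        ref = helix_structure()
        specs = helix_specs()
        chain, number, pos, name = specs[-1]
        specs[-1] = (chain, number, np.array(pos) + [8, 0, 0], name)
        mobile = make_structure(specs, id="outlier")
        _, unpruned = align_structures(ref, mobile, "A", "A")
        _, pruned = align_structures(ref, mobile, "A", "A", prune_cutoff=2.0)
        assert pruned.n_pairs == unpruned.n_pairs - 1
        assert pruned.rmsd < unpruned.rmsd


def test_shipped_blosum62_is_symmetric_with_canonical_diagonals():
    m = B62.scores
    assert np.array_equal(m, m.T)
    diag = dict(zip(B62.alphabet, np.diag(m)))
    assert diag["W"] == 11 and diag["C"] == 9 and diag["A"] == 4


def test_blosum62_matches_biotite_reference():
    """Cross-check the shipped matrix file against biotite's canonical copy."""
    from biotite.sequence.align import SubstitutionMatrix as BioMatrix

    ref = BioMatrix.std_protein_matrix()
    for a in B62.alphabet:
        for b in B62.alphabet:
            assert B62.score(a, b) == ref.get_score(a, b)
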