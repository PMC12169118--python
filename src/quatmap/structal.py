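"""Sequence-guided structural superposition.

The superposition strategy mirrors the classical "match maker" approach:
a local sequence alignment of the two chains under BLOSUM62 (Smith–Waterman
with affine gaps) selects residue pairs, whose Cα coordinates are then
superposed by the Kabsch least-squares rotation, reporting the RMSD.

The BLOSUM62 matrix ships as a data file (``data/blosum62.txt``); ``'X'``
scores 0 against every letter.  Gap costs use the BLAST convention: a gap of
length L costs ``gap_open + gap_extend * L`` (defaults 11/1, the standard
pairing for BLOSUM62).

Tie-breaking is deterministic: among equal-scoring alignment endpoints the
one with the smallest (position in A, position in B) wins, and the traceback
prefers diagonal over up (gap in B) over left (gap in A).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import GeometryError, NoAlignmentError
from .structure import Structure, chain_sequence

__all__ = [
    "SubstitutionMatrix",
    "load_blosum62",
    "AlignmentResult",
    "SuperpositionResult",
    "smith_waterman",
    "kabsch_superpose",
    "align_structures",
]


class SubstitutionMatrix:
    """A symmetric residue substitution matrix over the 20-letter alphabet.

    Letters outside the alphabet (notably 'X') score ``unknown_score``
    against everything.
    """

    def __init__(self, alphabet: str, scores: np.ndarray, unknown_score: float = 0.0):
        self.alphabet = alphabet
        self.scores = np.asarray(scores, dtype=float)
        self.unknown_score = float(unknown_score)
        self._idx = {a: i for i, a in enumerate(alphabet)}

    def score(self, a: str, b: str) -> float:
        ia = self._idx.get(a.upper())
        ib = self._idx.get(b.upper())
        if ia is None or ib is None:
            return self.unknown_score
        return float(self.scores[ia, ib])

    def score_profile(self, seq_a: str, seq_b: str) -> np.ndarray:
        """Pairwise score matrix, shape (len(a), len(b))."""
        return np.array(
            [[self.score(a, b) for b in seq_b] for a in seq_a], dtype=float
        )


def load_blosum62() -> SubstitutionMatrix:
    """Load BLOSUM62 from the shipped data file."""
    ref = resources.files("quatmap").joinpath("data/blosum62.txt")
    alphabet = ""
    rows = []
    with ref.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts or line.lstrip().startswith("#"):
                continue
            if len(parts) == 20 and all(len(p) == 1 for p in parts):
                alphabet = "".join(parts)
            elif alphabet and parts[0] in alphabet:
                rows.append([int(x) for x in parts[1:]])
    scores = np.array(rows, dtype=float)
    if scores.shape != (20, 20) or not np.allclose(scores, scores.T):
        raise ValueError("shipped BLOSUM62 file is malformed")
    return SubstitutionMatrix(alphabet, scores, unknown_score=0.0)


@dataclass
class AlignmentResult:
    """A local alignment: matched (0-based) position pairs and its score."""

    pairs: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if not (a1 > a0 and b1 > b0):
                raise ValueError("alignment pairs must strictly increase")
        if self.score < 0:
            raise ValueError("local alignment score cannot be negative")


@dataclass
class SuperpositionResult:
    """A proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if self.rmsd < 0:
            raise ValueError("rmsd cannot be negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


def smith_waterman(
    seq_a: str,
    seq_b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal local alignment with affine gaps (Gotoh recursion).

    Empty input yields an empty alignment with score 0, as does a pair with
    no positively scoring local alignment.
    """
    if matrix is None:
        matrix = load_blosum62()
    n, m = len(seq_a), len(seq_b)
    if n == 0 or m == 0:
        return AlignmentResult([], 0.0)

    sub = matrix.score_profile(seq_a, seq_b)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)   # ends in a match at (i, j)
    Ix = np.full((n + 1, m + 1), neg)  # ends in a gap in B (consumes A, "up")
    Iy = np.full((n + 1, m + 1), neg)  # ends in a gap in A ("left")
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        Mi1, Mi, Ixi1, Ixi, Iyi = M[i - 1], M[i], Ix[i - 1], Ix[i], Iy[i]
        for j in range(1, m + 1):
            best_prev = max(0.0, Mi1[j - 1], Ixi1[j - 1], Iy[i - 1][j - 1])
            Mi[j] = best_prev + sub[i - 1, j - 1]
            Ixi[j] = max(Mi1[j] - first_gap, Ixi1[j] - gap_extend)
            Iyi[j] = max(Mi[j - 1] - first_gap, Iyi[j - 1] - gap_extend)

    # local alignments end on a match; pick the best cell, ties to the
    # smallest (i, j) in row-major order
    flat = np.argmax(M)
    best = float(M.flat[flat])
    if best <= 0:
        return AlignmentResult([], 0.0)
    i, j = divmod(int(flat), m + 1)

    pairs: list[tuple[int, int]] = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev = M[i, j] - sub[i - 1, j - 1]
            # stop when the alignment start is reached; then diag > up > left
            if abs(prev) <= 1e-9:
                break
            if abs(M[i - 1, j - 1] - prev) <= 1e-9:
                state = "M"
            elif abs(Ix[i - 1, j - 1] - prev) <= 1e-9:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            if abs(M[i - 1, j] - first_gap - Ix[i, j]) <= 1e-9:
                state = "M"
            i -= 1
        else:  # Iy
            if abs(M[i, j - 1] - first_gap - Iy[i, j]) <= 1e-9:
                state = "M"
            j -= 1
    pairs.reverse()
    return AlignmentResult(pairs, best)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> SuperpositionResult:
    """Least-squares superposition of *coords_b* onto *coords_a*.

    Returns the proper rotation R and translation t minimizing the RMSD of
    ``R @ b + t`` against a.  The reflection branch of the SVD solution is
    sign-corrected so the determinant stays +1 even for mirror-image inputs.
    """
    A = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    B = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if A.shape != B.shape:
        raise GeometryError(f"coordinate sets differ in size: {A.shape} vs {B.shape}")
    if len(A) < 3:
        raise GeometryError(f"need at least 3 point pairs, got {len(A)}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinear (rank < 2) point sets leave the rotation under-determined
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) coordinates")
    H = B0.T @ A0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(A))


def align_structures(
    ref: Structure,
    mobile: Structure,
    ref_chain: str,
    mobile_chain: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    prune_cutoff: float | None = None,
) -> tuple[AlignmentResult, SuperpositionResult]:
    """Align two chains by sequence, then superpose their matched Cα atoms.

    With *prune_cutoff* set (Å), pairs farther apart than the cutoff after
    superposition are dropped and the fit repeated until stable — the
    iterative-pruning refinement familiar from interactive structure
    viewers.  Off by default so the result is a pure function of the
    sequence alignment.
    """
    seq_a, keys_a = chain_sequence(ref, ref_chain)
    seq_b, keys_b = chain_sequence(mobile, mobile_chain)
    aln = smith_waterman(seq_a, seq_b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    if not aln.pairs:
        raise NoAlignmentError(
            f"no local alignment between {ref.id}:{ref_chain} and "
            f"{mobile.id}:{mobile_chain}"
        )
    coords = []
    for ia, ib in aln.pairs:
        ra, rb = ref[keys_a[ia]], mobile[keys_b[ib]]
        if ra.ca is not None and rb.ca is not None:
            coords.append((ra.ca.position, rb.ca.position))
    if len(coords) < 3:
        raise GeometryError(
            f"only {len(coords)} aligned residue pairs have Cα atoms; need ≥ 3"
        )
    A = np.array([c[0] for c in coords])
    B = np.array([c[1] for c in coords])
    sup = kabsch_superpose(A, B)
    if prune_cutoff is not None:
        while True:
            dist = np.linalg.norm(sup.apply(B) - A, axis=1)
            keep = dist <= prune_cutoff
            if keep.all() or keep.sum() < 3:
                break
            A, B = A[keep], B[keep]
            sup = kabsch_superpose(A, B)
    return aln, sup
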