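"""Consensus linear-epitope calling from per-residue predictor scores.

External predictors (BepiPred 1/2/3, Ellipro, SEMA, ...) are never re-run
here; their per-residue score tables are ingested as plain TSV, thresholded
into binary calls, and combined by the at-least-two-predictors rule:
a position belongs to a consensus epitope when at least ``min_support``
predictors call it positive, and maximal runs of such positions become
contiguous epitope regions.

Default thresholds follow the predictors' published operating points:
BepiPred-1 0.35, BepiPred-2 0.5, BepiPred-3 0.15, Ellipro 0.5, SEMA 1.1.
Threshold comparison is inclusive (score ≥ threshold is a positive call).

Conformational (discontinuous) predictor output is structure-addressed
rather than sequence-addressed; :func:`read_residue_score_table` and
:func:`combine_conformational` handle that variant, producing the residue
sets that seed quaternary-epitope mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TrackConsistencyError, TrackFormatError
from .structure import ResidueKey

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ScoreTrack",
    "BinaryTrack",
    "EpitopeRegion",
    "read_score_track",
    "binarize",
    "regions_from_binary",
    "consensus_regions",
    "regions_frame",
    "read_residue_score_table",
    "combine_conformational",
]

#: Published operating thresholds of the ingested linear/structural predictors.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "bepipred1": 0.35,
    "bepipred2": 0.5,
    "bepipred3": 0.15,
    "ellipro": 0.5,
    "sema": 1.1,
}


@dataclass
class ScoreTrack:
    """Per-position scores of one predictor over one sequence."""

    predictor_name: str
    sequence_id: str
    scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.threshold):
            raise TrackFormatError(
                f"{self.predictor_name}: threshold must be finite"
            )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class BinaryTrack:
    """Thresholded positive/negative calls of one predictor."""

    predictor_name: str
    sequence_id: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class EpitopeRegion:
    """A contiguous epitope interval, 1-based inclusive coordinates."""

    start: int
    end: int
    sequence: str = ""
    support: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region bounds {self.start}-{self.end}")
        if self.sequence and len(self.sequence) != self.end - self.start + 1:
            raise ValueError("region sequence length does not match bounds")

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


def read_score_track(
    source,
    predictor_name: str,
    sequence_id: str = "",
    threshold: float | None = None,
    reference_sequence: str | None = None,
) -> ScoreTrack:
    """Read a predictor score table (TSV with position, residue, score).

    Positions must be contiguous from 1.  If the table carries a residue
    column and a reference sequence is supplied, the two are cross-checked
    position by position.  The threshold defaults to the predictor's
    published operating point when the name is recognized.
    """
    table = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", comment="#"
    )
    cols = {c.lower(): c for c in table.columns}
    if "position" not in cols or "score" not in cols:
        raise TrackFormatError(
            f"{predictor_name}: need columns position and score, got {list(table.columns)}"
        )
    positions = table[cols["position"]].to_numpy()
    expected = np.arange(1, len(positions) + 1)
    if len(positions) == 0 or not np.array_equal(positions, expected):
        bad = int(np.argmax(positions != expected)) if len(positions) else 0
        raise TrackFormatError(
            f"{predictor_name}: positions must be contiguous from 1 "
            f"(first problem near row {bad + 1})"
        )
    if reference_sequence is not None and "residue" in cols:
        residues = table[cols["residue"]].astype(str).str.upper().to_numpy()
        ref = np.array(list(reference_sequence.upper()[: len(residues)]))
        if len(residues) != len(reference_sequence):
            raise TrackConsistencyError(
                f"{predictor_name}: track length {len(residues)} != "
                f"reference length {len(reference_sequence)}"
            )
        mismatch = np.nonzero(residues != ref)[0]
        if mismatch.size:
            p = int(mismatch[0]) + 1
            raise TrackConsistencyError(
                f"{predictor_name}: residue {residues[p - 1]!r} at position {p} "
                f"does not match reference {ref[p - 1]!r}"
            )
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(predictor_name.lower())
    if threshold is None:
        raise TrackFormatError(
            f"no threshold given and predictor {predictor_name!r} has no default"
        )
    return ScoreTrack(
        predictor_name=predictor_name,
        sequence_id=sequence_id,
        scores=table[cols["score"]].to_numpy(dtype=float),
        threshold=float(threshold),
    )


def binarize(track: ScoreTrack) -> BinaryTrack:
    """Threshold a score track: positions scoring ≥ threshold are positive."""
    return BinaryTrack(
        predictor_name=track.predictor_name,
        sequence_id=track.sequence_id,
        calls=track.scores >= track.threshold,
    )


def regions_from_binary(track: BinaryTrack, sequence: str = "") -> list[EpitopeRegion]:
    """Maximal runs of positive calls as 1-based inclusive regions."""
    return _runs_to_regions(track.calls, support=None, sequence=sequence)


def consensus_regions(
    tracks: list[BinaryTrack], min_support: int = 2, sequence: str = ""
) -> list[EpitopeRegion]:
    """Combine predictor calls by the at-least-``min_support`` rule.

    Per-position support is the number of positive calls across tracks;
    maximal runs of positions with support ≥ *min_support* become regions,
    each annotated with the maximum per-position support inside it.
    """
    if not tracks:
        raise TrackConsistencyError("need at least one track")
    n = len(tracks[0])
    ids = {t.sequence_id for t in tracks}
    if len(ids) > 1:
        raise TrackConsistencyError(f"tracks address different sequences: {sorted(ids)}")
    for t in tracks:
        if len(t) != n:
            raise TrackConsistencyError(
                f"track {t.predictor_name!r} has length {len(t)}, expected {n}"
            )
    support = np.sum([t.calls for t in tracks], axis=0)
    return _runs_to_regions(support >= min_support, support=support, sequence=sequence)


def _runs_to_regions(mask, support, sequence: str) -> list[EpitopeRegion]:
    mask = np.asarray(mask, dtype=bool)
    if sequence and len(sequence) != len(mask):
        raise TrackConsistencyError("sequence length does not match track length")
    regions = []
    padded = np.concatenate(([False], mask, [False]))
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
    for s, e in zip(starts, ends):  # 0-based half-open [s, e)
        regions.append(
            EpitopeRegion(
                start=int(s) + 1,
                end=int(e),
                sequence=sequence[s:e] if sequence else "",
                support=int(support[s:e].max()) if support is not None else 1,
            )
        )
    return regions


def regions_frame(regions: list[EpitopeRegion], sequence_id: str = "") -> pd.DataFrame:
    """Region list as a table (start, end, sequence, support) for TSV export."""
    return pd.DataFrame(
        [
            {
                "sequence_id": sequence_id,
                "start": r.start,
                "end": r.end,
                "sequence": r.sequence,
                "support": r.support,
            }
            for r in regions
        ],
        columns=["sequence_id", "start", "end", "sequence", "support"],
    )


# ---------------------------------------------------------------------------
# Structure-addressed (conformational) predictor output


def read_residue_score_table(
    source, predictor_name: str, threshold: float | None = None
) -> set[ResidueKey]:
    """Read a conformational-predictor table keyed by chain + author number.

    Expects columns ``chain``, ``number``, ``score`` (an optional ``name``
    column is advisory).  Returns the set of residue keys scoring ≥ the
    threshold.
    """
    table = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", comment="#"
    )
    cols = {c.lower(): c for c in table.columns}
    for needed in ("chain", "number", "score"):
        if needed not in cols:
            raise TrackFormatError(
                f"{predictor_name}: need columns chain, number, score"
            )
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(predictor_name.lower())
    if threshold is None:
        raise TrackFormatError(
            f"no threshold given and predictor {predictor_name!r} has no default"
        )
    keep = table[cols["score"]].astype(float) >= float(threshold)
    return {
        ResidueKey(str(row[cols["chain"]]), int(row[cols["number"]]))
        for _, row in table[keep].iterrows()
    }


def combine_conformational(
    residue_sets: list[set[ResidueKey]], mode: str = "union", min_support: int = 2
) -> set[ResidueKey]:
    """Merge per-predictor conformational residue sets.

    ``union`` keeps every residue called by any predictor (default);
    ``consensus`` keeps residues called by at least *min_support* of them.
    """
    if mode == "union":
        return set().union(*residue_sets) if residue_sets else set()
    if mode == "consensus":
        counts: dict[ResidueKey, int] = {}
        for s in residue_sets:
            for k in s:
                counts[k] = counts.get(k, 0) + 1
        return {k for k, c in counts.items() if c >= min_support}
    raise TrackFormatError(f"unknown combination mode {mode!r}")
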