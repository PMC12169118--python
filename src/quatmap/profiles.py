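"""Classical sliding-window B-cell propensity profiles.

Implements the sequence-property tracks commonly inspected when mapping
linear B-cell epitopes: Parker hydrophilicity, Karplus–Schulz flexibility,
Emini surface accessibility, Kolaskar–Tongaonkar antigenicity and
Chou–Fasman beta-turn propensity.  The numeric per-residue tables ship as
data files with literature citations (see ``data/scales/``); they are
inputs, not code constants.

Two aggregation modes exist:

* ``mean`` — the profile value at the window center is the unweighted mean
  of the scale values across an odd-length window (default 7).
* ``product`` — the windowed product of the scale values; used by the Emini
  accessibility method, where the hexapeptide product is normalized by
  ``0.37**window`` so a window of average-accessibility residues scores 1,
  and the value is assigned to the 4th residue of the window.

Positions whose window would extend past either sequence end carry no score
(NaN).  Residues absent from a scale (``'X'`` and other unknowns) contribute
the scale's mean value so that a single unknown residue does not blank a
whole window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ScaleConfigurationError, WindowSizeError

__all__ = [
    "PropensityScale",
    "Profile",
    "load_scale",
    "builtin_scale_names",
    "sliding_window_profile",
    "emini_accessibility",
    "kolaskar_antigenicity",
    "profile_frame",
]

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: builtin scale name -> (aggregator, default window)
_BUILTIN = {
    "parker_hydrophilicity": ("mean", 7),
    "karplus_schulz_flexibility": ("mean", 7),
    "emini_accessibility": ("product", 6),
    "kolaskar_antigenicity": ("mean", 7),
    "chou_fasman_beta_turn": ("mean", 7),
}


@dataclass(frozen=True)
class PropensityScale:
    """A per-amino-acid propensity table plus its aggregation convention."""

    name: str
    values: dict[str, float]
    aggregator: str = "mean"
    default_window: int = 7

    def __post_init__(self) -> None:
        missing = set(_STANDARD_AA) - set(self.values)
        if missing:
            raise ScaleConfigurationError(
                f"scale {self.name!r} lacks values for {sorted(missing)}"
            )
        if not all(np.isfinite(list(self.values.values()))):
            raise ScaleConfigurationError(f"scale {self.name!r} has non-finite values")
        if self.aggregator not in ("mean", "product"):
            raise ScaleConfigurationError(f"unknown aggregator {self.aggregator!r}")
        if self.default_window < 1:
            raise ScaleConfigurationError("default_window must be positive")

    @property
    def mean_value(self) -> float:
        """Mean over the 20 standard residues; substituted for unknowns."""
        return float(np.mean([self.values[a] for a in _STANDARD_AA]))

    def lookup(self, seq: str) -> np.ndarray:
        fallback = self.mean_value
        return np.array([self.values.get(a, fallback) for a in seq.upper()])


@dataclass
class Profile:
    """Per-position profile scores (NaN at window-truncated ends)."""

    sequence: str
    window: int
    scores: np.ndarray
    scale_name: str = ""
    calls: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.sequence):
            raise ValueError("scores length must equal sequence length")
        if self.calls is not None and len(self.calls) != len(self.sequence):
            raise ValueError("calls length must equal sequence length")

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def builtin_scale_names() -> list[str]:
    return sorted(_BUILTIN)


def load_scale(name: str) -> PropensityScale:
    """Load one of the builtin literature scales from package data."""
    if name not in _BUILTIN:
        raise ScaleConfigurationError(
            f"unknown scale {name!r}; available: {builtin_scale_names()}"
        )
    aggregator, window = _BUILTIN[name]
    ref = resources.files("quatmap").joinpath(f"data/scales/{name}.tsv")
    with ref.open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    values = dict(zip(table["aa"], table["value"].astype(float)))
    return PropensityScale(name, values, aggregator, window)


def _window_positions(n: int, window: int) -> tuple[int, int]:
    """Index range [first, last] of positions that receive a score."""
    center = window // 2
    first = center
    last = n - window + center
    return first, last


def sliding_window_profile(
    seq: str,
    scale: PropensityScale,
    window: int | None = None,
    center_weighted: bool = False,
) -> Profile:
    """Slide a window over *seq* and aggregate scale values per position.

    For the mean aggregator the window must be odd and the score lands on
    the window center; for the product aggregator any window length ≥ 1 is
    allowed and the score lands on position ``window // 2`` of the window
    (the 4th residue of a hexapeptide).

    ``center_weighted`` switches the mean to a normalized triangular
    weighting peaking at the window center (the emphasis used by the
    original flexibility method); the default is the plain unweighted mean.
    """
    window = scale.default_window if window is None else window
    n = len(seq)
    if window < 1:
        raise ScaleConfigurationError("window must be positive")
    if window > n:
        raise WindowSizeError(f"window {window} exceeds sequence length {n}")
    if scale.aggregator == "mean" and window % 2 == 0:
        raise ScaleConfigurationError("mean aggregation requires an odd window")
    if center_weighted and scale.aggregator != "mean":
        raise ScaleConfigurationError("center weighting applies to mean scales")

    vals = scale.lookup(seq)
    if scale.aggregator == "mean":
        if center_weighted:
            half = window // 2
            kernel = np.concatenate(
                [np.arange(1, half + 2), np.arange(half, 0, -1)]
            ).astype(float)
            kernel /= kernel.sum()
        else:
            kernel = np.ones(window) / window
        agg = np.convolve(vals, kernel, mode="valid")
    else:
        # log-space product would lose signs; plain cumulative product is fine
        # at these window lengths and magnitudes
        agg = np.array(
            [float(np.prod(vals[i : i + window])) for i in range(n - window + 1)]
        )
    scores = np.full(n, np.nan)
    first, last = _window_positions(n, window)
    scores[first : last + 1] = agg
    return Profile(seq, window, scores, scale_name=scale.name)


def emini_accessibility(
    seq: str, window: int = 6, scale: PropensityScale | None = None
) -> Profile:
    """Surface-accessibility profile: windowed product of accessibility
    fractions normalized by ``0.37**window``.

    A hexapeptide of residues with fraction exactly 0.37 scores 1.0; values
    above 1 mark windows more surface-probable than average.
    """
    scale = scale or load_scale("emini_accessibility")
    if scale.aggregator != "product":
        raise ScaleConfigurationError("emini_accessibility needs a product scale")
    prof = sliding_window_profile(seq, scale, window)
    prof.scores = prof.scores / (0.37**window)
    return prof


def kolaskar_antigenicity(
    seq: str, window: int = 7, scale: PropensityScale | None = None
) -> Profile:
    """Antigenicity profile with the per-protein adaptive threshold.

    The windowed mean of antigenic propensities is computed, then positions
    scoring strictly above the mean of all defined scores of this sequence
    are flagged as antigenic calls.  On a flat profile nothing is called.
    """
    scale = scale or load_scale("kolaskar_antigenicity")
    prof = sliding_window_profile(seq, scale, window)
    defined = prof.defined()
    threshold = float(np.nanmean(prof.scores)) if defined.any() else np.nan
    calls = np.zeros(len(seq), dtype=bool)
    calls[defined] = prof.scores[defined] > threshold
    prof.calls = calls
    return prof


def profile_frame(profile: Profile) -> pd.DataFrame:
    """Long-form table (position, residue, score[, call]) for TSV export.

    Positions are 1-based to match score-track files consumed by the
    consensus module.
    """
    data = {
        "position": np.arange(1, len(profile.sequence) + 1),
        "residue": list(profile.sequence),
        "score": profile.scores,
    }
    if profile.calls is not None:
        data["call"] = profile.calls.astype(int)
    return pd.DataFrame(data)
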