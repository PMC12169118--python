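"""Exception hierarchy.

Every error raised by quatmap derives from :class:`QuatmapError`, so callers
(and the CLI) can catch one base class and report the failing stage.
"""


class QuatmapError(Exception):
    """Base class for all quatmap errors."""


class PDBParseError(QuatmapError):
    """A PDB record could not be parsed; the message names the line number."""


class EmptyStructureError(QuatmapError):
    """The input contained no polymer residues."""


class ChainNotFoundError(QuatmapError, KeyError):
    """A requested chain id is not present in the structure."""


class ResidueNotFoundError(QuatmapError, KeyError):
    """A residue key (chain + author number) is not present in the structure."""


class LabelFormatError(QuatmapError, ValueError):
    """A residue label such as ``TYR.69.D`` could not be parsed."""


class TrackFormatError(QuatmapError, ValueError):
    """A score-track table violates its format contract (e.g. position gaps)."""


class TrackConsistencyError(QuatmapError, ValueError):
    """Score tracks disagree with each other or with a reference sequence."""


class WindowSizeError(QuatmapError, ValueError):
    """A sliding window does not fit the sequence."""


class ScaleConfigurationError(QuatmapError, ValueError):
    """A propensity scale or window configuration is invalid."""


class NoAlignmentError(QuatmapError):
    """Local alignment found no positively scoring region."""


class GeometryError(QuatmapError, ValueError):
    """Too few or degenerate coordinates for a superposition."""


class DegenerateClusterError(QuatmapError, ValueError):
    """A residue cluster lies entirely on one chain."""


class ParameterError(QuatmapError, ValueError):
    """A numeric parameter (cutoff, radius, ...) is out of range."""


class SyntheticSpecError(QuatmapError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class PipelineConfigError(QuatmapError, ValueError):
    """The pipeline configuration file is invalid."""
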