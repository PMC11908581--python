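"""Exception hierarchy for chromqc.

Every error raised by the package derives from :class:`ChromQCError` so
callers can catch the package's failures with a single except clause while
still distinguishing parameter misuse from signal pathologies.
"""


class ChromQCError(Exception):
    """Base class for all chromqc errors."""


class ParameterError(ChromQCError, ValueError):
    """Invalid or non-finite parameter value."""


class BaselineError(ChromQCError):
    """Baseline cannot be estimated (too few idle points)."""


class NoiseError(ChromQCError):
    """Noise level cannot be estimated (too few idle points)."""


class NoPeakError(ChromQCError):
    """No peak rises above the detection floor in the search window."""


class UnresolvedPeakError(ChromQCError):
    """Signal never falls below the requested height fraction on one side."""


class DegeneratePeakError(ChromQCError):
    """Peak geometry is degenerate (zero half-width)."""


class DegenerateFeatureError(ChromQCError):
    """A feature has zero variance on the fit rows; names the feature."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"feature {feature!r} has zero variance on the fit rows")


class AssemblyError(ChromQCError):
    """Quality-table assembly failed (e.g. duplicated compound ids)."""


class EmptyTableError(ChromQCError):
    """An operation produced or received an empty table."""


class RankError(ChromQCError):
    """Requested more principal components than the matrix rank supports."""


class NoElbowError(ChromQCError):
    """WCSS curve has no point of positive discrete curvature."""


class RankingError(ChromQCError):
    """No cluster survived evaluation, so clusters cannot be ranked."""


class ConfigError(ChromQCError):
    """Pipeline configuration is invalid."""


class StageError(ChromQCError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
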