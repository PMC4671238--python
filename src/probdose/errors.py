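"""Exception hierarchy.

Validation problems raise distinct, named errors so callers (and the CLI) can
report which input rule was violated rather than a generic parse failure.
"""


class ProbdoseError(Exception):
    """Base class for all package errors."""


class DatasetValidationError(ProbdoseError, ValueError):
    """A dose-response dataset violates a structural invariant."""


class MissingColumnError(DatasetValidationError):
    """Input file lacks a required header column."""


class NonNumericCellError(DatasetValidationError):
    """Input file contains a cell that cannot be parsed as a number."""


class NonIncreasingDoseError(DatasetValidationError):
    """Doses are not strictly increasing (duplicates included)."""


class AffectedExceedsGroupError(DatasetValidationError):
    """A quantal group reports more affected animals than its group size."""


class MixedGroupKindError(DatasetValidationError):
    """Continuous and quantal groups mixed in one dataset."""


class TooFewGroupsError(DatasetValidationError):
    """Fewer than three dose groups; no model leaves a residual df."""


class EndpointSpecError(ProbdoseError, ValueError):
    """Endpoint class / effect metric combination is inconsistent."""


class UnknownFamilyError(ProbdoseError, KeyError):
    """Model family id not recognised."""


class FitError(ProbdoseError, RuntimeError):
    """Maximum-likelihood fit failed (non-convergence or degenerate data)."""


class BMDRangeError(ProbdoseError, RuntimeError):
    """Benchmark response not reached within 10x the maximum tested dose."""


class AllModelsRejectedError(ProbdoseError, RuntimeError):
    """No candidate model passed the goodness-of-fit screen (p > 0.05)."""


class ConfigError(ProbdoseError, ValueError):
    """Assessment configuration invalid or incomplete."""
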