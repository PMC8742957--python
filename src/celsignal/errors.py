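"""Exception hierarchy for the celsignal pipeline.

Validation problems (bad inputs, malformed tables, inconsistent layouts)
and numerical failures (non-convergent fits, degenerate mixtures) are kept
distinct so the CLI can map them to different exit codes.
"""


class CelsignalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CelsignalError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file does not conform to the expected CSV/YAML dialect."""


class CoverageError(ValidationError):
    """A trace does not cover the requested scoring window."""


class CompletenessError(ValidationError):
    """A required well / table cell is missing; message lists what is absent."""


class ConfigError(ValidationError):
    """Run configuration is inconsistent or incomplete."""


class NumericalError(CelsignalError):
    """Base class for numerical/optimisation failures."""


class DegeneracyError(NumericalError):
    """Mixture EM collapsed (component SD pinned at the floor) in every restart."""


class FitError(NumericalError):
    """Nonlinear regression failed to converge after restarts."""


class OrientationError(ValidationError):
    """Dose-response data contradicts the declared inhibitor/agonist direction."""


class InformationError(ValidationError):
    """Data carry no information for the requested fit (e.g. all points clipped)."""


class InfeasibleCutoffError(CelsignalError):
    """No cutoff on the grid satisfies the false-positive constraint."""


class StageError(CelsignalError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
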