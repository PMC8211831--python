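"""Exception hierarchy for ventcal.

All package errors derive from :class:`VentcalError` so callers (and the
CLI) can distinguish validation problems from genuine bugs.
"""


class VentcalError(Exception):
    """Base class for all ventcal errors."""


class DomainError(VentcalError, ValueError):
    """An argument is outside the physically/mathematically valid domain."""


class InvalidStateError(VentcalError, ValueError):
    """A state object is internally inconsistent (e.g. supersaturated gas)."""


class InconsistentInputsError(VentcalError, ValueError):
    """Inputs are individually valid but mutually contradictory."""


class UnequilibratedError(VentcalError):
    """Bag temperature/pressure were not equilibrated; the record is dismissed."""


class NonPositiveUptakeError(InconsistentInputsError):
    """Computed O2 uptake is non-positive, signalling inconsistent inputs."""


class InfeasibleSubjectError(VentcalError, ValueError):
    """Simulator parameters yield a physically impossible gas state."""


class ConfigError(VentcalError, ValueError):
    """A simulation/analysis configuration cannot be satisfied."""


class ChecksumError(VentcalError):
    """A packaged fixture failed its integrity check."""


class QCError(VentcalError):
    """A quality-control gate failed."""


class PipelineStageError(VentcalError):
    """A stage of the metabolic pipeline failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
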