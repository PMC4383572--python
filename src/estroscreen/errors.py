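"""Exception hierarchy.

Every user-facing failure mode maps onto one of these classes so callers
can distinguish bad configuration from bad data from degenerate inputs.
"""


class EstroscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(EstroscreenError, ValueError):
    """A configuration object has an invalid field (the message names it)."""


class StudyValidationError(EstroscreenError, ValueError):
    """An expression study or its files violate a structural invariant."""


class DesignError(EstroscreenError, ValueError):
    """The experimental design cannot support the requested computation
    (e.g. a batch without vehicle controls, a single treatment group)."""


class DataError(EstroscreenError, ValueError):
    """Numerically unusable data (negative counts, zero housekeeping counts)."""


class UndefinedCorrelationError(EstroscreenError, ValueError):
    """Correlation requested against a constant vector."""


class EmptyPanelError(EstroscreenError, RuntimeError):
    """Panel derivation emptied the candidate set; `stage` says where."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(message or f"no candidate probes left after stage '{stage}'")


class PanelError(EstroscreenError, ValueError):
    """A biomarker panel is unusable (e.g. degenerate discriminant axis)."""


class StageError(EstroscreenError, RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
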