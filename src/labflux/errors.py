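"""Exception hierarchy for labflux."""

from __future__ import annotations


class LabfluxError(Exception):
    """Base class for all labflux errors."""


class GPRSyntaxError(LabfluxError):
    """Raised when a gene-protein-reaction boolean expression cannot be parsed."""


class ModelFormatError(LabfluxError):
    """Raised when a model file does not parse in the declared dialect."""


class ModelValidationError(LabfluxError):
    """Raised when a model violates a structural invariant.

    Carries the full list of problems so callers can report every offending id
    at once rather than failing one element at a time.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "model validation failed:\n  " + "\n  ".join(self.problems)
        )


class MediumError(LabfluxError):
    """Raised when a medium references exchanges absent from the model."""


class SolverError(LabfluxError):
    """Raised when the LP solver fails for a reason other than infeasibility
    or unboundedness."""


class FitError(LabfluxError):
    """Raised when GAM fitting cannot bracket the measured growth rate."""
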