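"""Exception hierarchy shared across the package."""


class PetkinError(Exception):
    """Base class for all petkin errors."""


class FormatError(PetkinError, ValueError):
    """A tabular input file is malformed (missing/misnamed column, bad dtype)."""


class ValidationError(PetkinError, ValueError):
    """A domain object violates one of its invariants."""


class InsufficientDataError(PetkinError, ValueError):
    """Too few samples/points to perform the requested estimation."""


class CompartmentMismatchError(PetkinError, ValueError):
    """A parent-fraction model for the wrong compartment was supplied."""


class DomainError(PetkinError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class UnitError(PetkinError, ValueError):
    """A curve carries a unit the operation does not accept."""


class DegenerateModelError(PetkinError, ValueError):
    """The kinetic model collapses (all exchange rates zero)."""


class UndefinedMacroparameterError(PetkinError, ValueError):
    """VT/BPND are undefined because k2 or k4 is zero."""


class FitError(PetkinError, RuntimeError):
    """A nonlinear fit could not be carried out at all."""


class PipelineError(PetkinError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
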