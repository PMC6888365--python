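"""Exception hierarchy for combsyn.

All library errors derive from :class:`CombsynError` so callers can catch
one base class at pipeline boundaries.
"""


class CombsynError(Exception):
    """Base class for all combsyn errors."""


class InvalidInputError(CombsynError, ValueError):
    """An argument violates a precondition (negative dose, fa outside (0,1), ...)."""


class InsufficientDataError(CombsynError):
    """Too few usable points remain for a fit (fewer than 2 after exclusions)."""


class DegenerateDesignError(CombsynError):
    """The dose design cannot support a fit (e.g. a single distinct dose)."""


class InconsistentInputError(CombsynError):
    """Inputs contradict each other (equal doses claimed to give unequal effects)."""


class UndeterminedSelectivityError(CombsynError):
    """A selectivity index cannot be bounded from the given censored IC50s."""


class PlateSchemaError(CombsynError):
    """A plate CSV is missing required columns or has an unreadable header."""


class PlateValidationError(CombsynError):
    """A plate CSV row violates an invariant (dead > total, negative dose, ...)."""
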