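"""Exception hierarchy.

Every error raised by this package derives from :class:`HemebundleError`,
so callers can catch domain failures without masking programming errors.
"""


class HemebundleError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HemebundleError):
    """A coordinate or table file could not be parsed.

    Carries ``line_number`` when the offending line is known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class ConsistencyError(HemebundleError):
    """Models of one ensemble disagree on atom identity."""


class TopologyError(HemebundleError):
    """A required topology entry (residue or atom name) is missing."""


class EmptySelectionError(HemebundleError):
    """An atom selection matched nothing."""


class DegenerateGeometryError(HemebundleError):
    """Input points are collinear/coincident where a fit needs spread."""


class InsufficientDataError(HemebundleError):
    """Too few points/models for the requested operation."""


class RadiusAssignmentError(HemebundleError):
    """No van der Waals radius is available for an atom."""


class ElementError(HemebundleError):
    """No atomic mass is available for an element."""


class IllDefinedOrientationError(HemebundleError):
    """The His imidazole plane is too close to parallel with the porphyrin."""


class ValidationError(HemebundleError):
    """An input value violates a documented precondition."""


class AssignmentError(HemebundleError):
    """Isomer assignment failed (undetermined or ambiguous contacts)."""


class AmbiguityError(AssignmentError):
    """Contact pattern supports more than one isomer."""


class UndeterminedError(AssignmentError):
    """Contact pattern supports no isomer."""


class RangeError(HemebundleError):
    """A physical parameter lies outside the plausible range."""


class CoverageError(HemebundleError):
    """A simulation grid does not cover the spectral lines."""


class FitError(HemebundleError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_cost: float | None = None):
        self.best_cost = best_cost
        super().__init__(message)


class AssemblyError(HemebundleError):
    """Synthetic assembly produced steric clashes."""
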