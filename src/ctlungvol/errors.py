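"""Exception hierarchy shared across the pipeline stages."""


class CTLungVolError(Exception):
    """Base class for all package errors."""


class FormatError(CTLungVolError):
    """Unreadable or inconsistent image file/series."""


class SpacingError(FormatError):
    """Non-uniform slice spacing beyond tolerance."""


class DegenerateInputError(CTLungVolError):
    """Input is valid in form but empty/degenerate in content."""


class AlignmentError(CTLungVolError):
    """Two grids that must share a shape do not."""


class SeedError(CTLungVolError):
    """An airway seed point does not satisfy its preconditions."""


class EquationDomainError(CTLungVolError):
    """A reference equation produced a non-physical prediction."""


class SpecError(CTLungVolError):
    """A synthetic phantom or cohort specification violates its invariants."""
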