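"""Exception hierarchy shared across the package."""


class GrowthScreenError(Exception):
    """Base class for all growthscreen errors."""


class DomainError(GrowthScreenError, ValueError):
    """An argument lies outside the mathematical domain of a transform."""


class OutOfRangeError(GrowthScreenError):
    """An age or height falls outside the coverage of a reference or table."""


class ReferenceFormatError(GrowthScreenError):
    """A growth-reference file is malformed (missing column, bad cell, duplicate row)."""


class CoverageError(GrowthScreenError):
    """A reference does not cover the months a computation needs."""


class TableInvariantError(GrowthScreenError):
    """A screening table violates its structural invariants."""


class ThirdReadingRequired(GrowthScreenError):
    """Two duplicate measurements disagree beyond tolerance; a third is needed."""
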