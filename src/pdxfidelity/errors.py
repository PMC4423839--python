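"""Exception hierarchy for the pdxfidelity pipeline."""


class PdxFidelityError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PdxFidelityError):
    """A file does not conform to its expected tabular/GMT layout."""


class ValidationError(PdxFidelityError):
    """Inputs violate a documented precondition or invariant."""


class ConstantInputError(ValidationError):
    """A rank correlation was requested on a constant vector.

    Spearman correlation is undefined when either argument has zero rank
    variance; callers must handle this explicitly rather than receive a
    silent 0.
    """
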