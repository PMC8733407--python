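"""Exception types shared across the package."""


class AdiagError(Exception):
    """Base class for package-specific errors."""


class CohortFormatError(AdiagError, ValueError):
    """A cohort file or table violates the expected layout."""


class UnprocessableColumnError(AdiagError, ValueError):
    """A column cannot be imputed or analysed (e.g. entirely missing)."""


class DegenerateDataError(AdiagError, ValueError):
    """A statistic is undefined for the given data (zero variance, zero margin)."""


class InvalidTrainingDataError(AdiagError, ValueError):
    """A classifier cannot be trained on the given cohort (e.g. one class only)."""


class DivergenceError(AdiagError, RuntimeError):
    """Iterative training produced a non-finite loss."""


class ModelFormatError(AdiagError, ValueError):
    """A serialized model file has an unknown or incompatible format version."""
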