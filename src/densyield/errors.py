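"""Exception hierarchy for the density-yield toolkit."""


class DensyieldError(Exception):
    """Base class for all package errors."""


class CatalogError(DensyieldError, KeyError):
    """Unknown curve-family identifier."""


class ParameterDomainError(DensyieldError, ValueError):
    """Parameters violate a family's admissible intervals."""


class DensityDomainError(DensyieldError, ValueError):
    """Planting density outside (0, inf) or other x-domain violation."""


class UnsupportedFamilyError(DensyieldError, ValueError):
    """Operation (e.g. a symbolic limit rule) not available for a family."""


class InsufficientDataError(DensyieldError, ValueError):
    """Too few records / distinct densities for the requested fit."""


class DegreesOfFreedomError(DensyieldError, ValueError):
    """Goodness statistics requested with n <= number of parameters."""


class UndefinedCorrelationError(DensyieldError, ValueError):
    """Pearson r undefined because a vector has zero variance."""


class NormalizationError(DensyieldError, ValueError):
    """Reference density missing from a variety/year group."""


class ValidationError(DensyieldError, ValueError):
    """A configuration or synthetic-truth object failed validation."""
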