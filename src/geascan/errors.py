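"""Exception hierarchy shared across the package."""


class GeascanError(Exception):
    """Base class for all package errors."""


class FormatError(GeascanError):
    """A file does not conform to the expected dialect (missing column, bad header...)."""


class ValidationError(GeascanError):
    """A file parsed but its content violates an invariant (duplicate id, out-of-range value...)."""


class ConfigurationError(GeascanError):
    """Parameters are inconsistent with each other or with the data size."""


class ConstantInputError(GeascanError):
    """A correlation is undefined because one input has fewer than two distinct values."""


class DegenerateCovariateError(GeascanError):
    """Partial correlation is undefined because a covariate is perfectly correlated."""
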