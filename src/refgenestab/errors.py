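"""Exception hierarchy shared across the package."""


class RefGeneStabError(Exception):
    """Base class for all package errors."""


class InputFormatError(RefGeneStabError):
    """The input file cannot be mapped onto the expected columns/types."""


class ValidationError(RefGeneStabError):
    """The data violate a structural invariant (duplicates, bad Cq, ...)."""


class InsufficientDataError(RefGeneStabError):
    """Too few genes/samples/complete pairs for the requested statistic."""


class ParameterError(RefGeneStabError):
    """A parameter is outside its documented domain."""
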