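"""Exception hierarchy for immfp."""


class ImmfpError(Exception):
    """Base class for all immfp errors."""


class SchemaError(ImmfpError, ValueError):
    """A clonotype table is missing mandatory columns or is otherwise unreadable."""


class ConfigurationError(ImmfpError, RuntimeError):
    """A requested backend or option is unavailable or inconsistent."""


class MissingPgenError(ImmfpError, ValueError):
    """Generation probabilities are required but absent.

    Raised when a score that weights clonotypes by generation probability is
    requested on repertoires that carry no usable pgen values. Annotate the
    repertoires first (see :func:`immfp.pgen.annotate_pgen`).
    """
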