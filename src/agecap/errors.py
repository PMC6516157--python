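"""Exception hierarchy shared across the pipeline stages."""


class AgecapError(Exception):
    """Base class for all agecap errors."""


class ConfigurationError(AgecapError):
    """An invalid configuration value; the message names the offending field."""


class ContractViolation(AgecapError):
    """An operation was called with inputs outside its documented contract."""


class ConsistencyError(AgecapError):
    """Two inputs that must describe the same objects disagree."""


class NormalizationError(AgecapError):
    """Size-factor estimation failed (e.g. no usable reference genes)."""
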