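"""Exception hierarchy shared by all pipeline stages."""


class MirprofError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(MirprofError):
    """A configuration value violates its documented constraints."""


class InputError(MirprofError):
    """Input data is malformed or inconsistent with the requested operation."""


class EstimationError(MirprofError):
    """A statistical estimate is undefined for the given data."""
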