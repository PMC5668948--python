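"""Exception hierarchy."""


class MeikitError(Exception):
    """Base class for all package errors."""


class ParseError(MeikitError):
    """Malformed input record."""


class IndexingError(MeikitError):
    """Missing or unusable alignment index."""


class ConfigurationError(MeikitError):
    """Invalid or incomplete run configuration."""
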