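"""Exception hierarchy shared across the pipeline stages."""


class EmpflowError(Exception):
    """Base class for all package errors."""


class ValidationError(EmpflowError):
    """Invalid configuration or parameter values."""


class FormatError(EmpflowError):
    """Malformed or inconsistent input files."""


class ConfigurationError(EmpflowError):
    """Missing or contradictory run configuration."""
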