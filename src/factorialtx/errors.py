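"""Exception hierarchy.

``ConfigurationError`` signals a bad parameter or config file (CLI exit 1);
``DataError`` signals malformed or inconsistent input data (CLI exit 2).
"""


class FactorialTxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FactorialTxError):
    """Invalid configuration, simulation spec or parameter value."""


class DataError(FactorialTxError):
    """Malformed, missing or internally inconsistent input data."""
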