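"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3.
"""


class MetamarkerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetamarkerError):
    """Invalid parameters, thresholds, or pipeline configuration."""


class DataError(MetamarkerError):
    """Malformed or degenerate input data (bad TSV rows, empty samples...)."""
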