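"""Exception hierarchy shared across the package.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class DiffcornetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DiffcornetError):
    """Invalid configuration: thresholds out of range, bad simulation setup."""


class DataError(DiffcornetError):
    """Invalid or degenerate data: zero variance, all-censored metabolites,
    rank-deficient covariate designs, unreadable inputs."""
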