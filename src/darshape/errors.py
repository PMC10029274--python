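"""Exception hierarchy for darshape.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class DarshapeError(Exception):
    """Base class for all darshape errors."""


class ConfigError(DarshapeError):
    """Invalid configuration: unknown keys, bad thresholds, unmapped columns."""


class DataError(DarshapeError):
    """Invalid or insufficient input data."""
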