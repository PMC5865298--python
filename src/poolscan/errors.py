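"""Exception hierarchy.

ConfigError covers bad parameters and unusable option combinations (CLI exit
code 2); DataError covers structurally broken or inconsistent input data
(CLI exit code 3). SyncParseError carries the offending line number.
"""


class PoolscanError(Exception):
    """Base class for all poolscan errors."""


class ConfigError(PoolscanError):
    """Invalid configuration: bad parameter values, unknown options, missing files."""


class DataError(PoolscanError):
    """Structurally invalid or internally inconsistent input data."""


class SyncParseError(DataError):
    """Malformed sync line; remembers the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number
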