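"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class PairmklError(Exception):
    """Base class for all errors raised by pairmkl."""


class ConfigError(PairmklError):
    """Invalid configuration: bad parameter ranges, missing files, empty kernel lists."""


class DataError(PairmklError):
    """Invalid input data: malformed kernel/pair files, ID mismatches, degenerate kernels."""


class ConvergenceError(PairmklError):
    """An iterative solver failed to reach its tolerance within its iteration budget."""

    def __init__(self, message: str, last_gap: float | None = None):
        super().__init__(message)
        self.last_gap = last_gap
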