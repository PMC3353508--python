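"""Exception hierarchy.

Exit-code mapping in the CLI relies on these classes: configuration
problems, data problems and optimizer failures map to distinct nonzero
codes, so they are kept as separate branches rather than one ValueError.
"""


class EelgrassAllometryError(Exception):
    """Base class for all package errors."""


class ConfigError(EelgrassAllometryError):
    """Invalid configuration (simulation config, CLI options, dialects)."""


class DataError(EelgrassAllometryError):
    """Invalid or insufficient data."""


class SchemaError(DataError):
    """A mandatory column is missing or mistyped in an input file."""


class RowError(DataError):
    """A specific data row is invalid; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DegenerateDataError(DataError):
    """Data admit no unique fit (e.g. all lengths equal)."""


class ConvergenceError(EelgrassAllometryError):
    """The nonlinear optimizer failed; carries the last iterate."""

    def __init__(self, message: str, last_params=None, diagnostics=None):
        self.last_params = last_params
        self.diagnostics = diagnostics
        super().__init__(message)


class UndefinedThresholdError(EelgrassAllometryError):
    """Threshold quantities are undefined at b = 1 (models proportional)."""


class PerfectFitError(EelgrassAllometryError):
    """rss = 0: Gaussian AIC is -inf; the caller must report a perfect fit."""
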