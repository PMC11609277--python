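"""Exception hierarchy shared across the toolkit."""


class GlobalmethError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlobalmethError, ValueError):
    """Invalid generator or analysis configuration."""


class AlignmentError(GlobalmethError, ValueError):
    """Two tables that must share an index (probes, samples, states) do not."""


class PairingError(GlobalmethError, ValueError):
    """Replicates cannot be paired across arms (unequal counts or missing arm)."""


class ParseError(GlobalmethError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
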