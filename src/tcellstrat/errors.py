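"""Exception types shared across the package."""


class TCellStratError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TCellStratError, ValueError):
    """An invalid simulation or pipeline configuration; names the offending field."""


class MissingGeneError(TCellStratError, KeyError):
    """A required gene symbol is absent from the expression matrix."""

    def __init__(self, gene: str):
        super().__init__(gene)
        self.gene = gene

    def __str__(self) -> str:  # KeyError would repr-quote the message
        return f"gene {self.gene!r} not found in expression matrix"


class EmptySignatureError(TCellStratError, ValueError):
    """Signature derivation produced no genes; the caller decides how to proceed."""


class ParseError(TCellStratError, ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateStatisticError(TCellStratError, ValueError):
    """A test statistic is undefined on the given data (e.g. zero variance)."""
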