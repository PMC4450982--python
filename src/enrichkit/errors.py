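"""Exception hierarchy shared across the package."""


class EnrichkitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EnrichkitError):
    """A delimited or structured input file could not be parsed.

    Carries the offending line number when it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(EnrichkitError):
    """Input parsed but violates a contract (roles, uniqueness, labels...)."""


class InvalidPairError(EnrichkitError):
    """Two structures offered as preparation variants of one molecule are not
    the same molecule (non-isomorphic heavy-atom graphs, formula mismatch)."""


class ConfigError(EnrichkitError):
    """A synthetic-benchmark or manifest configuration is infeasible."""
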