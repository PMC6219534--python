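"""Exception hierarchy shared across the package."""


class PheropathError(Exception):
    """Base class for all package-specific errors."""


class ReactionTableParseError(PheropathError):
    """A reaction-table line could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UniverseLoadError(PheropathError):
    """Structurally valid records that violate universe invariants
    (duplicate ids, degenerate substrates == products reactions)."""


class FeasibilityError(PheropathError):
    """A reaction was applied whose substrates are not all available."""


class DuplicateReactionError(PheropathError):
    """A reaction already present in the pathway was applied again."""


class NoStartReactionError(PheropathError):
    """No reaction in the universe consumes any candidate initial substrate."""
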