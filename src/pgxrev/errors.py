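"""Exception hierarchy shared across the package."""


class PgxRevError(Exception):
    """Base class for all pgxrev errors."""


class ParseError(PgxRevError):
    """Malformed input text; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(PgxRevError):
    """A token violates the expected lexical format (e.g. allele name)."""


class ConflictError(PgxRevError):
    """Duplicate core allele definitions with conflicting variant sets."""


class UnknownGeneError(PgxRevError, KeyError):
    """Gene symbol not present in the database or table."""


class UnknownAlleleError(PgxRevError, KeyError):
    """Allele name not present for the gene."""


class UnknownDrugError(PgxRevError, KeyError):
    """Drug not declared in the recommendation table."""


class VersionOrderError(PgxRevError):
    """Version labels are not strictly increasing."""


class HistoryError(PgxRevError):
    """A version history is too short or otherwise unusable."""


class CompletenessError(PgxRevError):
    """A call matrix or call set is missing required cells."""


class CoverageError(PgxRevError):
    """No rule matches a completed phenotype profile."""


class ConfigError(PgxRevError):
    """Invalid simulation or pipeline configuration."""
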