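"""Exception hierarchy.

Data problems found by validation are *reported*, not raised; exceptions are
reserved for contract violations (bad arguments, unparseable files, degenerate
hypotheses, missing lookups).
"""


class TmarqError(Exception):
    """Base class for all package errors."""


class ValidationError(TmarqError):
    """Invalid argument or configuration value."""


class ConflictError(TmarqError):
    """Duplicate registration of an already-registered key."""


class AttributeLookupError(TmarqError, KeyError):
    """Attribute/context pair not present in the registry."""


class ParseError(TmarqError):
    """Malformed input file; carries file and line context in the message."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class MappingError(TmarqError):
    """A table column has no mapping-rule entry."""


class DomainError(TmarqError):
    """Mathematically infeasible input (bad margins, value not a subset, ...)."""


class DegenerateHypothesisError(DomainError):
    """Hypothesis value set empty or equal to the whole permissible set."""


class NoDataError(TmarqError):
    """No cores match the hypothesis; the test is undefined."""


class NotFoundError(TmarqError, KeyError):
    """Exact-match lookup (e.g. probe id) failed."""
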