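"""Exception hierarchy.

The CLI maps these onto distinct exit codes: parse/load/validation problems
are "data" errors (exit 3), mathematically undefined requests are "domain"
errors (exit 4).
"""


class PsakitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PsakitError, ValueError):
    """A clinical value string (TNM stage, Gleason score, date) is malformed."""


class LoadError(PsakitError, ValueError):
    """A cohort/table/graph file violates its format contract.

    Carries ``source`` and ``line`` attributes when they are known so the
    offending row can be reported to the user.
    """

    def __init__(self, message: str, *, source: str | None = None, line: int | None = None):
        loc = ""
        if source is not None:
            loc = f"{source}:{line}: " if line is not None else f"{source}: "
        super().__init__(loc + message)
        self.source = source
        self.line = line


class DomainError(PsakitError, ValueError):
    """The requested quantity is undefined for the given inputs
    (e.g. doubling time of a non-positive PSA, density without a volume)."""


class CoverageError(PsakitError, LookupError):
    """A lookup-table query falls outside every cell of the table."""


class GraphError(PsakitError, ValueError):
    """A guideline graph or predicate violates its schema (cycle, dangling
    edge, unknown fact name, disallowed expression)."""
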