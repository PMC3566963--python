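"""Exception hierarchy shared by all metadiff modules.

The CLI maps these onto distinct exit codes: usage errors (2), input
format/validation errors (3) and empty analysis results (4).
"""


class MetadiffError(Exception):
    """Base class for all errors raised by metadiff."""


class FormatError(MetadiffError):
    """An input file does not conform to the expected tabular format."""


class AmbiguityError(FormatError):
    """A node identifier is declared at two different hierarchy levels."""


class ValidationError(MetadiffError):
    """Input parsed but violates a domain constraint (e.g. negative counts)."""


class UnknownIdError(MetadiffError, KeyError):
    """Lookup of a node, sample or variable that does not exist."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain message
        return Exception.__str__(self)


class UsageError(MetadiffError):
    """A caller supplied incompatible options, operators or thresholds."""


class EmptyResultError(MetadiffError):
    """An analysis produced no rows (e.g. every feature filtered out)."""
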