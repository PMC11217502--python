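"""Exception hierarchy for metstab.

All errors raised by the package derive from :class:`MetstabError` so callers
can catch one base class; subclasses distinguish schema problems in input
files from violations of the statistical design contracts.
"""


class MetstabError(Exception):
    """Base class for all metstab errors."""


class SchemaError(MetstabError):
    """An input table is missing required columns or has unmappable names."""


class IntegrityError(MetstabError):
    """Duplicate keys or otherwise internally inconsistent records."""


class ParseError(MetstabError):
    """A value could not be parsed as a number."""


class DesignError(MetstabError):
    """The trial design does not support the requested analysis
    (unbalanced table, too few genotypes/environments/replicates)."""


class DomainError(MetstabError):
    """A value is outside the mathematical domain of an operation
    (log of a non-positive number, YREM of a non-positive mean, ...)."""


class ContractError(MetstabError):
    """A precondition on derived inputs was violated (missing ANOVA row,
    empty genotype overlap, ...)."""
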