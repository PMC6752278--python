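"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`StarcallError`, so callers can catch one type at the CLI boundary.
"""


class StarcallError(Exception):
    """Base class for all starcall errors."""


class FormatError(StarcallError):
    """A definition table, mapping file, or VCF record is malformed."""


class CurationError(StarcallError):
    """A curation directive refers to an unknown target or is inconsistent."""


class DataError(StarcallError):
    """Genotype data violates a contract (duplicate keys, missing GP, ...)."""


class AmbiguityError(StarcallError):
    """Unphased heterozygotes would make haplotype assignment ambiguous."""


class ConfigurationError(StarcallError):
    """An operation was requested on a platform that does not support it."""


class SimulationSpecError(StarcallError):
    """A simulation spec is internally inconsistent or infeasible."""
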