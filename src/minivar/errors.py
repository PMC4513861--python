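"""Exception hierarchy.

Config errors (bad specs, bad thresholds, unresolvable paths) and data errors
(malformed files, contract violations in inputs) are kept distinct so the CLI
can map them to distinct exit codes.
"""


class MinivarError(Exception):
    """Base class for all package errors."""


class ConfigError(MinivarError):
    """Invalid pipeline/cohort configuration."""


class SpecError(ConfigError):
    """Infeasible synthetic-cohort specification."""


class DataError(MinivarError):
    """Base class for problems in input data."""


class FormatError(DataError):
    """Structurally malformed file."""


class AlphabetError(FormatError):
    """Sequence contains characters outside the allowed alphabet."""


class ParseError(FormatError):
    """Unparseable field (carries line/sample context in the message)."""


class ValidationError(DataError):
    """Record violates a domain invariant (coordinates out of bounds etc.)."""


class ReferenceMismatchError(DataError):
    """A variant's REF base disagrees with the genome sequence."""


class OutOfScopeError(DataError):
    """Operation applied to a record outside its domain (e.g. non-CDS variant)."""


class UndefinedDafError(DataError):
    """Derived allele frequency requested where the ancestral allele is unknown."""
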