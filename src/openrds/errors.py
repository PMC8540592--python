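"""Exception hierarchy.

Every error raised on purpose by the package derives from :class:`OpenRdsError`
so callers (and the CLI) can distinguish domain errors from genuine bugs.
"""


class OpenRdsError(Exception):
    """Base class for all package errors."""


class SequenceAlphabetError(OpenRdsError, ValueError):
    """A sequence contains a character outside the unambiguous nucleotide alphabet."""


class InternalStopError(OpenRdsError, ValueError):
    """A coding sequence translates to a stop codon before its final codon."""


class ConstraintError(OpenRdsError, ValueError):
    """A mutation or search constraint was violated (e.g. touching the start codon)."""


class WindowError(OpenRdsError, ValueError):
    """A folding/opening window does not fit the sequence it is applied to."""


class LengthError(OpenRdsError, ValueError):
    """An input exceeds a documented length bound of the operation."""


class UnsupportedStartCodonError(OpenRdsError, ValueError):
    """The start codon has no entry in the initiator-tRNA energy table."""


class EmptyInputError(OpenRdsError, ValueError):
    """An operation that needs at least one element received none."""


class SearchSpaceError(OpenRdsError, ValueError):
    """The exhaustive search space exceeds the guard limit."""


class NoMoveError(OpenRdsError, ValueError):
    """No synonymous single-nucleotide move exists in the requested region."""


class GenomeError(OpenRdsError, ValueError):
    """Genome FASTA / annotation mismatch or malformed annotation."""


class ConfigError(OpenRdsError, ValueError):
    """Unknown configuration key or malformed configuration value."""
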