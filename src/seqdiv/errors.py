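"""Exception taxonomy shared across the package.

Each error class maps to a distinct CLI exit code (see :mod:`seqdiv.cli`).
"""


class SeqDivError(Exception):
    """Base class for all seqdiv errors."""


class NoSequencesError(SeqDivError):
    """FASTA file contained no sequence records."""


class NotAlignedError(SeqDivError):
    """Sequences within one file have unequal lengths."""


class UnknownResidueError(SeqDivError):
    """A character is outside the accepted alphabet, gap and ambiguity set."""


class IncompatibleAlignmentsError(SeqDivError):
    """Groups to be overlaid do not share the same number of columns."""


class ConfigError(SeqDivError):
    """Configuration file is invalid."""


class AmbiguousGroupingError(ConfigError):
    """A residue was assigned to more than one functional group."""


class NothingToDrawError(SeqDivError):
    """Every ribbon was filtered or masked away; the diagram is empty."""
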