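"""Exception hierarchy.

Every user-facing failure raises a distinct subclass of :class:`MS4Error`
so that callers (and the CLI) can report a precise diagnostic.
"""


class MS4Error(Exception):
    """Base class for all errors raised by this package."""


class FastaError(MS4Error):
    """Malformed or unusable FASTA input."""


class EmptyInputError(FastaError):
    """The input file contains no sequence records."""


class DuplicateIdentifierError(FastaError):
    """Two records share the same identifier."""


class GapCharacterError(FastaError):
    """A gap character was found; input sequences must be unaligned."""


class AlphabetError(FastaError):
    """A residue falls outside the declared alphabet."""


class ParameterError(MS4Error):
    """An operation was called with an out-of-range parameter."""


class ColumnFormatError(MS4Error):
    """Malformed partial-column text input."""


class AmbiguousColumnError(MS4Error):
    """A column contains two sites of the same sequence (contract violation)."""


class OverlappingColumnsError(MS4Error):
    """Two columns share a site (contract violation)."""


class SequenceMismatchError(MS4Error):
    """Test and reference alignments are not over the same sequences."""


class UndefinedScoreError(MS4Error):
    """A score denominator is empty (e.g. no core pairs in the reference)."""


class InfeasibleSpecError(MS4Error):
    """A synthetic fixture specification cannot be realised."""
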