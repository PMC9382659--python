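"""Exception hierarchy.

Everything raised on bad user input derives from :class:`RelmatError`, so
callers (and the CLI) can catch one type.  Bpseq validation failures get one
named class per failure mode so tests and pipelines can distinguish a broken
file from a broken expectation.
"""


class RelmatError(Exception):
    """Base class for all errors raised by relmat."""


class BpseqError(RelmatError, ValueError):
    """A Bpseq file violates the format contract."""


class FieldFormatError(BpseqError):
    """A data line does not consist of integer, base letter, integer."""


class DuplicatePositionError(BpseqError):
    """The same sequence position occurs on more than one line."""


class MissingPositionError(BpseqError):
    """Positions are not exactly 1..length in ascending order."""


class SelfPairingError(BpseqError):
    """A position lists itself as its partner."""


class ContiguousPairingError(BpseqError):
    """A position pairs with its backbone neighbour (|partner - position| == 1)."""


class NonReciprocalPairingError(BpseqError):
    """Position i names partner j but line j does not name i (or j is out of range)."""


class InvalidDiagramError(RelmatError, ValueError):
    """An arc diagram violates a structural invariant."""


class StrandBreakError(RelmatError, ValueError):
    """A strand-break position falls outside 1..length-1."""


class LoopPairError(RelmatError, ValueError):
    """A loop pair handed to the relation classifier is unordered or shares endpoints."""


class MatrixFormatError(RelmatError, ValueError):
    """A serialized relation matrix is malformed or inconsistent."""


class EmptyPatternError(RelmatError, ValueError):
    """A pattern with zero loops was supplied to the matcher (usage error)."""


class InfeasibleConfigError(RelmatError, ValueError):
    """Generator configuration admits no valid arc diagram."""


class UnrealizableMatrixError(RelmatError, ValueError):
    """No arc diagram realizes the given relation matrix."""


class RealizationLimitError(RelmatError, RuntimeError):
    """The realization search exceeded its node budget before deciding."""
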