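"""Named error classes raised across the toolkit.

All inherit :class:`BarcodiagError` so callers (and the CLI) can distinguish
data errors (exit code 1) from usage errors (exit code 2).
"""


class BarcodiagError(Exception):
    """Base class for all toolkit data errors."""


class InvalidSequenceError(BarcodiagError):
    """A sequence contains characters outside the IUPAC DNA alphabet."""


class DuplicateIdError(BarcodiagError):
    """Two records in one collection share an id."""


class EmptyInputError(BarcodiagError):
    """An input file or collection is empty where content is required."""


class AlignmentError(BarcodiagError):
    """Records of unequal length, or an operation on an invalid alignment."""


class OligoTableError(BarcodiagError):
    """A primer/probe table row is malformed or internally inconsistent."""


class DistanceError(BarcodiagError):
    """A distance computation has no comparable sites or invalid operands."""


class TreeError(BarcodiagError):
    """A tree cannot be built (too few taxa, missing distances)."""


class DesignError(BarcodiagError):
    """Primer/probe design or evaluation cannot proceed (e.g. unmappable oligo)."""
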