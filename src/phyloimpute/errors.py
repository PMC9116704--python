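"""Exception hierarchy for distance-matrix parsing and validation."""


class DistanceMatrixError(ValueError):
    """Base class for distance-matrix construction/validation failures."""


class MatrixParseError(DistanceMatrixError):
    """A distance-matrix file could not be parsed.

    Subclasses pin down the defect; the message names the offending
    row/column so the user can fix the file.
    """


class NonSquareMatrixError(MatrixParseError):
    pass


class DuplicateLabelError(MatrixParseError):
    pass


class DiagonalMissingError(MatrixParseError):
    """A missing-data sentinel appeared on the diagonal."""


class NegativeDistanceError(MatrixParseError):
    pass


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the reader's position info."""
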