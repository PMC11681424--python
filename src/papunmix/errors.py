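"""Exception hierarchy.

All package errors derive from :class:`PapunmixError`.  The split between
validation errors (bad user input: shapes, labels, empty masks) and
computation errors (numerically degenerate problems such as a collinear
stain matrix) is mirrored by the CLI exit codes.
"""


class PapunmixError(Exception):
    """Base class for all errors raised by papunmix."""


class ValidationError(PapunmixError, ValueError):
    """Invalid user input: bad values, empty masks, unknown labels."""


class DimensionError(ValidationError):
    """Shape or band-count mismatch between paired objects."""


class SingularStainMatrixError(PapunmixError, ValueError):
    """Stain matrix is rank deficient (collinear dye spectra)."""
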