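"""Exception hierarchy shared across finecomp modules."""


class FinecompError(Exception):
    """Base class for all finecomp errors."""


class ParseError(FinecompError):
    """A text input file could not be parsed; message names the line."""


class CoordinateError(FinecompError):
    """A genomic coordinate is inconsistent with the bin table."""


class DegenerateMatrixError(FinecompError):
    """Fewer than two columns survive the zero-variance filter."""


class DegenerateSpectrumError(FinecompError):
    """lambda_1 == lambda_2: the eigenvector error bound is undefined."""


class EmptyDomainError(FinecompError):
    """A summary was requested over an empty set (no eligible bins/rows/intervals)."""


class OrientationError(FinecompError):
    """The reference track cannot orient an eigenvector (zero variance)."""
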