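"""Exception hierarchy shared by all pipeline stages."""


class CrossCellError(Exception):
    """Base class for all crosscell errors."""


class FormatError(CrossCellError):
    """A file does not conform to the expected text format."""


class AnnotationError(CrossCellError):
    """Sample annotations are missing or inconsistent with the matrix."""


class DataError(CrossCellError):
    """Input values violate a contract (negative intensity, zero ratio denominator...)."""


class ParameterError(CrossCellError):
    """An operation was called with invalid parameters."""


class PipelineError(CrossCellError):
    """A pipeline stage produced an empty or inconsistent intermediate result."""
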