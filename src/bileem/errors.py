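"""Exception hierarchy for the bileem pipeline."""


class BileemError(Exception):
    """Base class for all bileem errors."""


class FormatError(BileemError):
    """A delimited EEM or manifest file violates the expected layout."""


class AlignmentError(BileemError):
    """Wavelength grids or tensor shapes do not match."""


class InsufficientDataError(BileemError):
    """Too few measurements for the requested operation."""


class NoSignalError(BileemError):
    """A curve or surface carries no usable fluorescence signal."""


class DegenerateModelError(BileemError):
    """A fitted model is numerically degenerate (e.g. singular loadings)."""


class OutOfRangeError(BileemError):
    """A requested level or wavelength is not bracketed by the data."""


class PipelineError(BileemError):
    """A pipeline stage failed; carries the stage name and offending sample."""

    def __init__(self, stage: str, message: str, sample_id: str | None = None):
        self.stage = stage
        self.sample_id = sample_id
        prefix = f"[{stage}]" + (f" sample {sample_id!r}:" if sample_id else "")
        super().__init__(f"{prefix} {message}")
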