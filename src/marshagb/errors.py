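"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration field is missing, malformed, or out of range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


class OutOfExtentError(ValueError):
    """A point falls outside the raster extent."""


class EmptyRegionError(ValueError):
    """A regional statistic was requested over zero pixels."""

    def __init__(self, region: str):
        self.region = region
        super().__init__(f"region {region!r} contains no masked pixels")


class ModelSelectionError(RuntimeError):
    """No candidate regression model could be fitted."""


class AlignmentError(ValueError):
    """Two time series or stacks disagree on their year axis."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
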