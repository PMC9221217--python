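"""Exception hierarchy shared across the pipeline stages."""


class AtlasFusionError(Exception):
    """Base class for all package-specific errors."""


class AtlasFormatError(AtlasFusionError):
    """Label image is not a valid integer parcellation."""


class EmptyAtlasError(AtlasFusionError):
    """No regions remain after applying exclusions."""


class GridMismatchError(AtlasFusionError):
    """Voxel grids of two images do not agree (after any resampling)."""


class DegenerateSeriesError(AtlasFusionError):
    """Time series carries no usable variance (e.g. constant)."""


class PipelineError(AtlasFusionError):
    """A whole processing stage produced no usable output."""


class AlignmentError(AtlasFusionError):
    """Subjects or labels of two feature tables do not line up."""


class ConfigurationError(AtlasFusionError):
    """Run manifest or strategy specification is invalid or incomplete."""
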