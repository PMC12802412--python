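"""Exception hierarchy shared across the toolkit."""


class RseiError(Exception):
    """Base class for all toolkit errors."""


class RasterFormatError(RseiError):
    """A file could not be read or written as a single-band GeoTIFF."""


class AlignmentError(RseiError):
    """Grids that must share geometry do not."""


class DegenerateLayerError(RseiError):
    """A layer or statistic is degenerate (constant range, empty domain...)."""


class PipelineError(RseiError):
    """A pipeline stage failed; the message names the stage and layer."""
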