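"""Exception hierarchy shared by all specalib modules."""


class SpecalibError(Exception):
    """Base class for all errors raised by specalib."""


class DegenerateInputError(SpecalibError, ValueError):
    """Input is structurally valid but carries no usable signal
    (zero vectors, empty masks, uniform images for edge-based methods)."""


class DimensionError(SpecalibError, ValueError):
    """Shapes or grids of two inputs do not match."""


class ConfigurationError(SpecalibError, ValueError):
    """A parameter is outside its legal range or a required setting is missing."""


class NoHighlightsError(SpecalibError, RuntimeError):
    """No valid highlight pixel exists; the caller should try another exposure."""


class FormatError(SpecalibError, ValueError):
    """A file on disk does not conform to the expected format."""
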