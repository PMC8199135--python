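"""Exception hierarchy for the gaitdtw pipeline."""


class GaitDtwError(Exception):
    """Base class for all gaitdtw errors."""


class FormatError(GaitDtwError):
    """Input file does not match the expected recording schema."""


class SamplingError(GaitDtwError):
    """Time column is not uniformly sampled within tolerance."""


class EmptyRecordingError(GaitDtwError):
    """Recording has fewer than two samples."""


class ConfigError(GaitDtwError):
    """A pipeline or generator parameter is out of its valid range."""


class NoStridesError(GaitDtwError):
    """Fewer than two heel-strikes detected; no stride can be extracted."""


class ChannelError(GaitDtwError):
    """Requested channel is not present in the recording."""


class DegenerateSignalError(GaitDtwError):
    """Standardization requested on a constant (zero-variance) signal."""


class GridError(GaitDtwError):
    """Cycle grids of two normalized strides do not match."""


class EmptySequenceError(GaitDtwError):
    """DTW requested on an empty sequence."""


class DomainError(GaitDtwError):
    """Symmetry index requested on a non-positive value."""


class EmptyGroupError(GaitDtwError):
    """Statistical comparison requested on an empty group."""
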