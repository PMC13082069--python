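"""Exception hierarchy shared across the toolkit."""


class ChannelMDError(Exception):
    """Base class for all package errors."""


class ParseError(ChannelMDError):
    """A structure or trajectory file violated its format contract."""


class EmptyInputError(ChannelMDError):
    """An input contained no usable records."""


class ShapeError(ChannelMDError):
    """Array/frame dimensions disagree with the roster."""


class LookupError_(ChannelMDError):
    """A named entity (element, subunit, atom) could not be resolved."""


class SelectionError(ChannelMDError):
    """A selection did not resolve as required by an operation."""


class SpecError(ChannelMDError):
    """A generator specification violated its invariants."""


class GeometryError(ChannelMDError):
    """Degenerate geometry (coincident/collinear points, closed pore...)."""


class FitError(ChannelMDError):
    """An axis or superposition fit is degenerate."""


class OutOfRangeError(ChannelMDError):
    """A requested coordinate lies outside the structure."""


class DegenerateDataError(ChannelMDError):
    """Zero-variance or otherwise degenerate statistical input."""


class AlignmentError(ChannelMDError):
    """Scalar traces could not be aligned onto a common frame grid."""


class PoolingError(ChannelMDError):
    """Replicate correlation inputs are incompatible."""


class ContrastError(ChannelMDError):
    """Two correlation reports cannot be contrasted."""


class ConfigError(ChannelMDError):
    """Pipeline configuration failed validation."""


class StageError(ChannelMDError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
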