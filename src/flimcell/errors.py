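"""Exception hierarchy for the flimcell pipeline."""


class FlimError(Exception):
    """Base class for all flimcell errors."""


class InvalidConfigError(FlimError):
    """An acquisition/pipeline configuration violates its invariants."""


class PlacementError(FlimError):
    """Phantom cells could not be placed without overlap."""


class ShapeMismatchError(FlimError):
    """Two images/masks that must share a pixel grid do not."""


class UnknownROIError(FlimError):
    """Requested label is absent from the mask."""


class EmptyROIError(FlimError):
    """ROI selects zero pixels; an aggregated decay would be meaningless."""


class InsufficientSignalError(FlimError):
    """Too few photons in the decay curve for the requested fit."""


class DegenerateFitError(FlimError):
    """Goodness-of-fit undefined (e.g. every bin excluded)."""


class UndefinedMeanError(FlimError):
    """Amplitude-weighted mean lifetime undefined (a1 + a2 = 0)."""


class AmbiguousPairingError(FlimError):
    """A nucleus straddles two cells with no majority owner."""


class TooFewObservationsError(FlimError):
    """Statistical operation requires more values than supplied."""


class UnsupportedSampleSizeError(FlimError):
    """Sample size outside the supported range of the test."""


class DegenerateDataError(FlimError):
    """Statistic undefined on this input (e.g. a constant sample)."""


class ConstantChannelError(FlimError):
    """Pearson correlation undefined: a channel is constant within the mask."""
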