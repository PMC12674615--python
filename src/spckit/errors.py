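"""Exception hierarchy shared across the toolkit."""


class SpckitError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(SpckitError, ValueError):
    """A builder or operation received an out-of-contract parameter."""


class OutOfRangeError(SpckitError, ValueError):
    """A time point or window falls outside the data it indexes."""


class ParseError(SpckitError, ValueError):
    """An input file does not conform to the expected dialect."""


class UnusableTrackError(SpckitError, ValueError):
    """A pose track has no frames confident enough to locate the animal."""


class TooShortError(SpckitError, ValueError):
    """A series is too short for the requested operation."""


class DegenerateFitError(SpckitError, ValueError):
    """A regression or test cannot be computed (constant input, zero variance)."""


class InvalidBaselineError(SpckitError, ValueError):
    """The fitted isosbestic baseline is non-positive somewhere."""


class EmptyPETHError(SpckitError, ValueError):
    """No usable event onsets remain for peri-event extraction."""


class AlignmentError(SpckitError, ValueError):
    """Two series that must share a clock have incompatible lengths."""


class PairingError(SpckitError, ValueError):
    """TTL trains on the two clocks cannot be paired one-to-one."""


class UndefinedEpochError(SpckitError, ValueError):
    """An epoch contains no frame pairs, so a percentage is undefined."""
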