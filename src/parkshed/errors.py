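"""Exception hierarchy for the parkshed pipeline."""


class ParkshedError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(ParkshedError, ValueError):
    """A configuration parameter is invalid; the message names the field."""


class ConfigError(ParkshedError, ValueError):
    """One or more configuration problems; collects every message, not just the first."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class PlacementError(ParkshedError, RuntimeError):
    """Could not place the requested number of protected-area footprints."""

    def __init__(self, requested, placed):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"placed only {placed} of {requested} protected areas within the retry budget"
        )


class AlignmentError(ParkshedError, ValueError):
    """Two rasters do not share shape or geotransform."""


class FormatError(ParkshedError, ValueError):
    """A file does not conform to the expected format or is missing a property."""


class UndefinedRateError(ParkshedError, ValueError):
    """A disturbance rate was requested for a unit with no land pixels."""


class UndefinedCorrelationError(ParkshedError, ValueError):
    """Pearson correlation requested for a vector with zero variance."""


class UndefinedStatisticError(ParkshedError, ValueError):
    """A summary statistic is undefined for the given input (e.g. empty unit list)."""


class PairingError(ParkshedError, ValueError):
    """Paired vectors have mismatched lengths."""


class PreconditionError(ParkshedError, ValueError):
    """An operation's precondition was violated."""
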