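"""Exception hierarchy for pairedni."""


class PairedNIError(Exception):
    """Base class for all pairedni errors."""


class BothMissingError(PairedNIError):
    """A pair with both outcomes missing was encountered at ingestion."""


class UndefinedEstimateError(PairedNIError):
    """An estimator's denominator is zero (no usable pairs)."""


class NoInformationError(PairedNIError):
    """The data carry no information about the parameter (e.g. zero
    restricted variance in a fully concordant table)."""


class InvalidParameterError(PairedNIError, ValueError):
    """A parameter combination is outside its admissible range."""


class SeparationError(PairedNIError):
    """A (quasi-)separated or constant-outcome configuration prevents a
    maximum-likelihood or GEE fit."""


class NotAchievableError(PairedNIError):
    """A sample-size search exhausted its grid without meeting the target
    power; carries the maximum power observed."""

    def __init__(self, message: str, max_power: float | None = None):
        super().__init__(message)
        self.max_power = max_power
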