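"""Exception hierarchy shared across the pipeline."""


class WavebeatError(Exception):
    """Base class for all package errors."""


class ReadError(WavebeatError):
    """A record, annotation or feature file could not be read."""


class ChannelError(WavebeatError):
    """The requested lead does not exist in the record."""


class BoundaryError(WavebeatError):
    """A beat window would extend past the record extent."""


class DepthError(WavebeatError):
    """The segment is too short for the requested decomposition depth."""


class DataError(WavebeatError):
    """Input data violates a numeric precondition (non-finite, empty...)."""


class FitError(WavebeatError):
    """A model could not be fitted from the given training data."""


class SelectionError(WavebeatError):
    """The requested cumulative-variance threshold is unattainable."""


class ProjectionError(WavebeatError):
    """Feature dimension does not match the fitted model."""


class TrainingError(WavebeatError):
    """Classifier training preconditions violated (e.g. empty class)."""


class PredictionError(WavebeatError):
    """Sample dimension does not match the trained classifier."""


class LabelError(WavebeatError):
    """A label is outside the declared class set."""


class ConfigError(WavebeatError):
    """A configuration value is invalid or inconsistent."""
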