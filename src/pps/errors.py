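"""Exception hierarchy for the pipeline."""


class PPSError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(PPSError, ValueError):
    """Invalid cohort / effect / sampler configuration."""


class GenerationError(PPSError, ValueError):
    """Synthetic data cannot be generated under the requested parameters."""


class DataError(PPSError, ValueError):
    """Input data violate a precondition."""


class MarkerError(DataError):
    """Stimulus-onset markers are inconsistent with the audio."""


class DesignError(DataError):
    """Required design cells are empty or unbalanced."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class DegenerateSignalError(DataError):
    """A physiological trace carries no usable variability."""
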