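"""Package-wide exception types."""


class ThermorampError(Exception):
    """Base class for thermoramp errors."""


class ConfigurationError(ThermorampError, ValueError):
    """A protocol or cohort configuration is internally inconsistent."""


class SimulationError(ThermorampError, RuntimeError):
    """A synthetic trial cannot be realised (e.g. chamber O2 driven below zero)."""


class AnalysisError(ThermorampError, ValueError):
    """An analysis stage received data it cannot process."""


class NoBeatsError(AnalysisError):
    """Beat detection found no usable pulses (flat or zero-amplitude signal)."""


class FitError(AnalysisError):
    """A model fit is degenerate (e.g. no response variation for a dose curve)."""
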