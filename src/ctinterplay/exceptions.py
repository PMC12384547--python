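"""Exception hierarchy for ctinterplay."""


class CTInterplayError(Exception):
    """Base class for all package errors."""


class InvalidWaveformError(CTInterplayError, ValueError):
    """Breathing waveform parameters are physically invalid."""


class InvalidProtocolError(CTInterplayError, ValueError):
    """Scan protocol parameters are physically invalid."""


class TargetNotCapturedError(CTInterplayError):
    """The moving sphere never intersected an acquisition plane."""


class ConfigError(CTInterplayError, ValueError):
    """Invalid run configuration."""


class AggregationError(CTInterplayError, ValueError):
    """Alignment records from mixed conditions were aggregated."""


class InsufficientDataError(CTInterplayError, ValueError):
    """Fewer records than the statistic requires."""


class ProtocolViolationError(CTInterplayError):
    """Clinical imaging procedure violated (e.g. a fourth image)."""


class SchemaError(CTInterplayError, ValueError):
    """Tabular input does not match the expected schema."""
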