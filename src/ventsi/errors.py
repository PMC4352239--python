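"""Exception hierarchy for ventsi."""


class VentsiError(Exception):
    """Base class for all ventsi errors."""


class ConfigurationError(VentsiError):
    """A parameter or configuration value is out of its admissible range."""


class TimingError(VentsiError):
    """Ventilator settings imply an impossible breath timing."""


class ConstantFlowError(VentsiError):
    """No constant-flow portion could be located in a breath."""


class FitError(VentsiError):
    """The power-law fit of the pressure-time curve did not converge."""


class UndefinedComplianceError(VentsiError):
    """A compliance is undefined because its pressure denominator is <= 0."""


class TruncatedTraceError(VentsiError):
    """A breath record does not contain the phase an analysis requires."""


class TitrationError(VentsiError):
    """The decremental PEEP trial found no interior compliance maximum."""


class TraceFormatError(VentsiError):
    """A trace or waveform file does not conform to the documented dialect."""
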