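"""Exception hierarchy."""


class MemstdpError(Exception):
    """Base class for package errors."""


class ConfigurationError(MemstdpError):
    """Invalid configuration value or structure."""


class ProtocolError(MemstdpError):
    """Spike-protocol invariant violated (e.g. overlapping pulses on one row)."""


class TuningError(MemstdpError):
    """Conductance tuning failed (unreachable target or iteration cap)."""
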