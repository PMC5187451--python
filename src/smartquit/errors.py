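"""Exception hierarchy for smartquit."""


class SmartQuitError(Exception):
    """Base class for all package errors."""


class ConfigError(SmartQuitError):
    """Malformed or invalid study configuration."""


class BankError(SmartQuitError):
    """Message bank fails validation (missing slot, duplicate id, bad row)."""


class EventLogError(SmartQuitError):
    """Event log cannot be parsed or violates record invariants."""


class SchedulingError(SmartQuitError):
    """A prompt schedule cannot be built under the given constraints."""


class PeriodError(SmartQuitError):
    """An event was registered in the wrong study phase (prequit vs postquit)."""
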