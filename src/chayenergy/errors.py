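"""Exception hierarchy for the simulator."""


class ChayError(Exception):
    """Base class for all package errors."""


class InputError(ChayError, ValueError):
    """A numerical input was invalid (non-finite, out of range)."""


class ConfigurationError(ChayError, ValueError):
    """A parameter set, protocol or integration setting was inconsistent."""


class DivergenceError(ChayError, RuntimeError):
    """The integration left the physically plausible voltage range."""
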