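"""Exception hierarchy.

All framework-raised errors derive from :class:`PipebenchError` so callers can
distinguish configuration/contract problems from errors raised inside
registered methods (which are captured per-row, never propagated).
"""


class PipebenchError(Exception):
    """Base class for all errors raised by the framework itself."""


class ValidationError(PipebenchError, ValueError):
    """A dataset or table violates a structural invariant."""


class RegistrationError(PipebenchError, ValueError):
    """A method list was constructed with invalid entries."""


class UndefinedMetricError(PipebenchError, ValueError):
    """A metric is mathematically undefined for the given input."""


class ConfigError(PipebenchError, ValueError):
    """A benchmark configuration file is invalid."""
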