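"""Exception hierarchy used across the package."""


class ReplidynError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ReplidynError, ValueError):
    """A table is missing mandatory columns or has malformed headers."""


class TrajectoryFormatError(ReplidynError, ValueError):
    """A trajectory table violates structural rules (e.g., non-monotone frames)."""


class ValidationError(ReplidynError, ValueError):
    """Input values violate a documented precondition or invariant."""


class ConfigError(ReplidynError, ValueError):
    """A run configuration or option value is not understood."""


class NoSteadyStateError(ReplidynError, ValueError):
    """The transport model has no finite steady state (degradation rate is zero)."""


class UnimodalError(ReplidynError, ValueError):
    """Pixel intensities do not support a two-component mixture split."""
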