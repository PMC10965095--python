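"""Exception hierarchy shared across the package."""


class SwvQuantError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SwvQuantError, ValueError):
    """A text table could not be parsed; message names the offending line."""


class InsufficientDataError(SwvQuantError, ValueError):
    """Fewer data points / rows / samples than the operation requires."""


class RangeError(SwvQuantError, ValueError):
    """A requested potential lies outside the measured sweep (no extrapolation)."""


class PairingError(SwvQuantError, ValueError):
    """Two collections that must be paired element-wise do not match."""


class DegenerateFeatureError(SwvQuantError, ValueError):
    """A training feature column has no usable variation; message names it."""


class SchemaError(SwvQuantError, ValueError):
    """Feature names at prediction time do not match the training schema."""


class LabelError(SwvQuantError, ValueError):
    """A sample that must carry a reference concentration does not."""


class ConfigError(SwvQuantError, ValueError):
    """A run configuration failed validation; message lists offending keys."""
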