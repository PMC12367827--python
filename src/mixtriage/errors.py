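"""Exception types shared across the package."""


class SchemaError(ValueError):
    """An input table violates its documented schema (missing column,
    duplicate key, out-of-range value)."""


class ConfigError(ValueError):
    """A run configuration is invalid (unknown key, infeasible value)."""


class DegenerateFitError(RuntimeError):
    """Dose-response data carry no usable signal (e.g. all responses equal)."""


class UnreachableLevelError(ValueError):
    """The requested response level is not attainable by the fitted curve,
    e.g. an EC50 when the lower asymptote sits above 50% of control."""


class ClassificationError(ValueError):
    """A mixture deviation call cannot be made (missing EC50 on either the
    predicted or the observed side)."""
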