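"""Exception types shared across the package."""


class MorphopathError(Exception):
    """Base class for all package-specific errors."""


class TPSParseError(MorphopathError):
    """A TPS record could not be parsed (malformed or inconsistent counts)."""


class SchemaError(MorphopathError):
    """A tabular input is missing required columns or has invalid values."""


class DegenerateShapeError(MorphopathError):
    """A landmark configuration is degenerate (zero centroid size / zero area)."""


class RepeatabilityError(MorphopathError):
    """Repeated measurements failed the repeatability gate (r <= 0.9).

    Carries the observed Pearson correlation as ``.r``.
    """

    def __init__(self, r: float, message: str | None = None):
        self.r = float(r)
        super().__init__(message or f"repeated measurements correlate at r={r:.4f} <= 0.9")


class NotPositiveDefiniteError(MorphopathError):
    """A matrix that must be positive definite is not. Carries ``.name``."""

    def __init__(self, name: str, message: str | None = None):
        self.name = name
        super().__init__(message or f"matrix {name!r} is not positive definite")
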