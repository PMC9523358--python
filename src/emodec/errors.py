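"""Exception hierarchy shared across the package."""


class EmodecError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EmodecError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(EmodecError, IOError):
    """A file could not be parsed in the expected on-disk format."""


class DegenerateSignalError(ValidationError):
    """A channel has zero variance where a standardized moment is required."""

    def __init__(self, channel: int, label: str | None = None):
        self.channel = channel
        self.label = label
        name = f"{channel}" if label is None else f"{channel} ({label!r})"
        super().__init__(
            f"channel {name} has zero variance; skewness/kurtosis undefined"
        )
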