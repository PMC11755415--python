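"""Exception hierarchy shared across the package."""


class PulseguardError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PulseguardError, ValueError):
    """An invalid configuration value; the message names the violated field(s)."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ShapeError(PulseguardError, ValueError):
    """Array shapes inconsistent with an operation's contract."""


class InsufficientBeatsError(PulseguardError, ValueError):
    """Fewer than two beat onsets: no complete beat interval exists."""


class InsufficientDataError(PulseguardError, ValueError):
    """Too few samples for the requested statistic."""


class EmptyInputError(PulseguardError, ValueError):
    """An operation requiring a non-empty input received an empty one."""


class CalibrationError(PulseguardError, ValueError):
    """Threshold calibration impossible (empty score vector or split)."""


class DivergenceError(PulseguardError, RuntimeError):
    """Training produced a non-finite loss; carries the epoch index."""

    def __init__(self, epoch, message=None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class UndefinedCorrelationError(PulseguardError, ValueError):
    """Pearson correlation undefined for a constant channel; names the channel."""
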