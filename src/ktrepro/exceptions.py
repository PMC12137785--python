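"""Typed errors raised across the package.

Validation failures always raise; nothing is silently coerced.
"""


class KTReproError(Exception):
    """Base class for all package errors."""


class GridError(KTReproError):
    """Grid geometry cannot accommodate the requested anatomy or k-space."""


class NormalizationError(KTReproError):
    """An operation required normalized B1+ maps but received raw ones."""


class ROIError(KTReproError):
    """Region-of-interest mask is empty, fragmented, or inconsistent."""


class DesignError(KTReproError):
    """Pulse-design inputs are inconsistent (channel counts, empty systems)."""


class GradientLimitError(DesignError):
    """A k-space displacement is unreachable under the gradient limits."""

    def __init__(self, message: str, required_duration_us: float | None = None):
        super().__init__(message)
        self.required_duration_us = required_duration_us


class SchemaError(KTReproError):
    """A file's schema/version does not match what this package writes."""


class ValidationError(KTReproError):
    """A file's payload fails structural validation (shapes, counts)."""
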