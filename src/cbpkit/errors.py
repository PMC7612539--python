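"""Exception hierarchy.

Estimator and solver failures always raise a typed error; no routine ever
returns NaN to signal failure, so downstream dataset evaluation can count
failures per subject.
"""


class CbpkitError(Exception):
    """Base class for all package errors."""


class InvalidWaveError(CbpkitError):
    """Waveform violates container invariants (non-finite samples, too short...)."""


class LandmarkNotFoundError(CbpkitError):
    """A required waveform landmark (foot, upstroke) could not be located."""


class AliasingError(CbpkitError):
    """Requested harmonic order is at or beyond the Nyquist limit."""


class InvalidPhysiologyError(CbpkitError):
    """Parameter combination is outside the physically meaningful range."""


class NonPhysicalResultError(CbpkitError):
    """A computed quantity came out non-physical (e.g. negative resistance)."""


class FitFailedError(CbpkitError):
    """An iterative fit or optimisation did not converge.

    The best incumbent (if any) is attached as ``best``.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class InapplicableMethodError(CbpkitError):
    """The requested estimation method cannot be applied to this input."""


class ConfigurationError(CbpkitError):
    """Invalid configuration or method selection."""


class EstimationStageError(CbpkitError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"estimation failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


class IncomparableWavesError(CbpkitError):
    """Two waves cannot be compared (e.g. period mismatch)."""


class WaveIOError(CbpkitError):
    """Malformed wave file."""
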