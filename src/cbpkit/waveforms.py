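"""Single-cycle waveform container, landmarks and signal utilities.

All modules in the package operate on :class:`UniformWave`: one cardiac cycle
of a uniformly sampled pressure (mmHg) or flow (mL/s) signal. The wave spans
exactly one period ``T = n * dt``; the sample at ``t0 + T`` (which equals the
first sample for a periodic signal) is *not* stored.

Canonical units throughout the package are mmHg, mL and s, so resistances and
impedances are mmHg.s/mL and compliances mL/mmHg. SI quantities (blood
density, areas, PWV) are converted at the boundary using
``1 Pa.s/m^3 = 7.5006e-9 mmHg.s/mL``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .errors import AliasingError, InvalidWaveError, LandmarkNotFoundError

#: default sampling interval for generated waves (s); 1 kHz keeps the
#: discretisation error of cycle means well below 0.1 mmHg
DEFAULT_DT = 1.0e-3

#: minimum number of samples for a valid single-cycle wave
MIN_SAMPLES = 32

#: 1 mmHg in Pa
MMHG_PA = 133.322

#: 1 Pa.s/m^3 expressed in mmHg.s/mL
PA_S_PER_M3_TO_MMHG_S_PER_ML = 7.5006e-9

WaveKind = Literal["pressure", "flow"]


@dataclass(frozen=True)
class UniformWave:
    """One cardiac cycle of a uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample (s).
    dt : float
        Sampling interval (s), strictly positive.
    values : numpy.ndarray
        Samples in mmHg (pressure) or mL/s (flow). At least ``MIN_SAMPLES``
        finite values.
    kind : {"pressure", "flow"}
    """

    t0: float
    dt: float
    values: np.ndarray
    kind: WaveKind = "pressure"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.t0) or not np.isfinite(self.dt) or self.dt <= 0:
            raise InvalidWaveError(f"dt must be positive and finite, got {self.dt}")
        if vals.ndim != 1 or vals.size < MIN_SAMPLES:
            raise InvalidWaveError(
                f"wave needs >= {MIN_SAMPLES} samples in one cycle, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidWaveError("wave contains non-finite samples")
        if self.kind not in ("pressure", "flow"):
            raise InvalidWaveError(f"unknown wave kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def period(self) -> float:
        """Cycle duration T = n * dt (s)."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def shifted(self, delta: float) -> "UniformWave":
        """Same samples with the time axis shifted by ``delta`` seconds."""
        return UniformWave(self.t0 + delta, self.dt, self.values, self.kind)

    def value_at(self, t, period_extend: bool = True):
        """Periodic linear interpolation of the wave at time(s) ``t``."""
        tt = np.asarray(t, dtype=float) - self.t0
        if period_extend:
            tt = np.mod(tt, self.period)
        te = self.dt * np.arange(self.n + 1)
        ve = np.append(self.values, self.values[0])
        return np.interp(tt, te, ve)


@dataclass(frozen=True)
class WaveStats:
    """Scalar summary of one cycle.

    ``vmean`` is the cycle mean via trapezoidal quadrature with periodic
    closure, which for a uniform grid reduces to the arithmetic mean.
    """

    vmin: float
    vmax: float
    vmean: float
    period: float
    kind: WaveKind

    # pressure-style aliases
    @property
    def dbp(self) -> float:
        return self.vmin

    @property
    def sbp(self) -> float:
        return self.vmax

    @property
    def mbp(self) -> float:
        return self.vmean

    @property
    def pp(self) -> float:
        return self.vmax - self.vmin

    # flow-style aliases
    @property
    def q_mean(self) -> float:
        return self.vmean

    @property
    def q_max(self) -> float:
        return self.vmax

    @property
    def sv(self) -> float:
        """Stroke volume (mL) = integral of flow over the cycle."""
        return self.vmean * self.period


def wave_stats(w: UniformWave) -> WaveStats:
    """Min/max/mean (and derived PP, SV) of one cycle."""
    v = w.values
    return WaveStats(
        vmin=float(v.min()),
        vmax=float(v.max()),
        vmean=float(v.mean()),
        period=w.period,
        kind=w.kind,
    )


def _smooth_periodic(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average with periodic (circular) boundary handling."""
    if window <= 1:
        return values
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def differentiate(w: UniformWave) -> UniformWave:
    """Central-difference derivative with periodic end handling.

    Returns a wave of the same length and kind whose samples carry the units
    of the input per second.
    """
    v = w.values
    d = (np.roll(v, -1) - np.roll(v, 1)) / (2.0 * w.dt)
    return UniformWave(w.t0, w.dt, d, w.kind)


def detect_foot(w: UniformWave, smooth_window_s: float = 0.005) -> float:
    """Foot (onset of the systolic upstroke) by the intersecting-tangent rule.

    The tangent at the point of maximum first derivative on the upstroke is
    intersected with the pre-upstroke baseline: the diastolic minimum for
    pressure waves, zero for flow waves. A light moving average (default 5 ms)
    is applied before differentiation so that measurement noise does not
    dislodge the max-slope point; on noise-free piecewise-linear signals the
    rule is exact. Tie-break: the earliest sample attaining the maximum slope.

    Returns the foot time on the wave's own time axis (t0-based).
    """
    v = w.values
    rng = float(v.max() - v.min())
    if rng <= 0:
        raise LandmarkNotFoundError("flat wave has no upstroke")
    window = max(1, int(round(smooth_window_s / w.dt)))
    vs = _smooth_periodic(v, window)
    d = (np.roll(vs, -1) - np.roll(vs, 1)) / (2.0 * w.dt)
    i = int(np.argmax(d))
    slope = d[i]
    if slope <= rng / w.period * 1e-6:
        raise LandmarkNotFoundError("no rising upstroke found")
    baseline = 0.0 if w.kind == "flow" else float(vs.min())
    t_foot = w.t0 + i * w.dt - (vs[i] - baseline) / slope
    return float(t_foot)


def detect_dicrotic_notch(p: UniformWave) -> Optional[float]:
    """Dicrotic notch: first local minimum after the systolic peak that is
    followed by a local maximum (second peak) before the end of the cycle.

    Returns the notch time, or ``None`` when the wave has no second systolic
    peak (e.g. pressures generated by a lumped Windkessel model, whose
    diastolic decay is monotone).
    """
    v = p.values
    i_peak = int(np.argmax(v))
    seg = v[i_peak:]
    if seg.size < 3:
        return None
    interior = seg[1:-1]
    is_min = (interior <= seg[:-2]) & (interior <= seg[2:]) & (
        (interior < seg[:-2]) | (interior < seg[2:])
    )
    is_max = (interior >= seg[:-2]) & (interior >= seg[2:]) & (
        (interior > seg[:-2]) | (interior > seg[2:])
    )
    min_idx = np.nonzero(is_min)[0] + 1
    max_idx = np.nonzero(is_max)[0] + 1
    for im in min_idx:
        if np.any(max_idx > im):
            return float(p.t0 + (i_peak + im) * p.dt)
    return None


def harmonics(w: UniformWave, k_max: int) -> np.ndarray:
    """Complex Fourier coefficients of harmonics 0..k_max.

    Coefficient ``k`` corresponds to frequency ``k / T``. The amplitude
    convention is such that coefficient 0 equals the cycle mean and a pure
    ``cos(2*pi*k*t/T)`` wave has ``|c_k| = 1``.
    """
    n = w.n
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    if k_max >= n / 2:
        raise AliasingError(f"k_max={k_max} at or beyond Nyquist for n={n} samples")
    c = np.fft.rfft(w.values) / n
    c[1:] *= 2.0
    return c[: k_max + 1]


def synthesize(coeffs: np.ndarray, n: int, t0: float = 0.0, dt: float = DEFAULT_DT,
               kind: WaveKind = "pressure") -> UniformWave:
    """Inverse of :func:`harmonics`: rebuild a wave from its coefficients."""
    k = np.arange(len(coeffs))
    j = np.arange(n)
    phases = np.exp(2j * np.pi * np.outer(j, k) / n)
    v = np.real(phases[:, 0] * coeffs[0] + phases[:, 1:] @ coeffs[1:])
    return UniformWave(t0, dt, v, kind)


def resample(w: UniformWave, dt_new: float) -> UniformWave:
    """Resample onto a uniform grid of spacing ~``dt_new`` by periodic linear
    interpolation, keeping the period exact (the realised dt is ``T / n_new``).
    """
    if dt_new <= 0:
        raise ValueError("dt_new must be positive")
    if dt_new == w.dt:
        return w
    T = w.period
    n_new = max(MIN_SAMPLES, int(round(T / dt_new)))
    t_new = w.t0 + T / n_new * np.arange(n_new)
    return UniformWave(w.t0, T / n_new, w.value_at(t_new), w.kind)
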