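"""Lumped (0-D) Windkessel forward models and the optimized 3-element fit.

The two-element model treats the arterial tree as a single compliance C_T
filled through a resistance-free inlet and drained through the total
peripheral resistance R_T towards an outflow pressure P_out:

    dP/dt + (P - P_out) / (R_T C_T) = Q_in / C_T

The three-element model adds a proximal (characteristic) impedance Z_0 in
series, with R = R_T - Z_0:

    dP/dt + (P - P_out) / (R C_T) = Z_0 dQ_in/dt + (Z_0 + R) Q_in / (R C_T)

Both admit an integrating-factor solution

    P(t) = P_out + (P_0 - P_out - Z_0 Q_0) e^{-t/tau} + Z_0 Q_in(t)
           + (1/C_T) int_0^t Q_in(t') e^{-(t - t')/tau} dt',   tau = R C_T

(Z_0 = 0 recovers the two-element case). The exponentially weighted
convolution is evaluated with the weight assembled *inside* each step,
which is numerically stable for small tau, and the per-step quadrature is
exact for piecewise-linear inflow, so the discrete solution is the exact
solution of the ODE driven by the linear interpolant of the flow samples.

Periodic steady state does not require cycle iteration: the one-cycle map
P_0 -> P(T) is affine with slope e^{-T/tau} < 1, so its unique fixed point
is available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter

from .errors import FitFailedError, IncomparableWavesError, InvalidPhysiologyError
from .waveforms import UniformWave, resample

#: fixed seed for the multi-start optimizer (derivative-free local search)
FIT_SEED = 20200241


@dataclass(frozen=True)
class WindkesselParams:
    """Lumped-model parameters in clinical units.

    r_t : total arterial resistance (mmHg.s/mL)
    c_t : total arterial compliance (mL/mmHg)
    z_0 : characteristic impedance (mmHg.s/mL); 0 for the 2-element model
    p_out : outflow (asymptotic) pressure (mmHg)
    """

    r_t: float
    c_t: float
    z_0: float = 0.0
    p_out: float = 0.0

    def __post_init__(self):
        if not (self.r_t > 0):
            raise InvalidPhysiologyError(f"R_T must be positive, got {self.r_t}")
        if not (self.c_t > 0):
            raise InvalidPhysiologyError(f"C_T must be positive, got {self.c_t}")
        if not (0 <= self.z_0 < self.r_t):
            raise InvalidPhysiologyError(
                f"Z_0 must satisfy 0 <= Z_0 < R_T, got Z_0={self.z_0}, R_T={self.r_t}"
            )
        if self.p_out < 0:
            raise InvalidPhysiologyError(f"P_out must be >= 0, got {self.p_out}")

    @property
    def r(self) -> float:
        """Distal resistance R = R_T - Z_0 (mmHg.s/mL)."""
        return self.r_t - self.z_0


@dataclass(frozen=True)
class SolveSettings:
    """How to solve for the pressure cycle.

    mode "periodic" returns the unique cycle with P(0) = P(T) (closed form);
    mode "transient" starts from ``p_0`` and iterates cycles until the cycle
    start changes by less than ``tol`` mmHg (at most ``max_cycles`` cycles).
    """

    mode: str = "periodic"
    p_0: Optional[float] = None
    tol: float = 1e-6
    max_cycles: int = 200

    def __post_init__(self):
        if self.mode not in ("periodic", "transient"):
            raise ValueError(f"unknown solve mode {self.mode!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


def _exp_convolution(q_ext: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """I_k = int_0^{t_k} q(t') e^{-(t_k - t')/tau} dt' for piecewise-linear q.

    Per-step recursion I_k = a I_{k-1} + b_k with a = e^{-dt/tau} and b_k the
    exact integral of the linear segment times the exponential weight; the
    recursion is evaluated by a first-order IIR filter.
    """
    a = np.exp(-dt / tau)
    # exact weights for a linear segment: int_0^dt [(1-s/dt) q0 + (s/dt) q1] e^{-(dt-s)/tau} ds
    w_total = tau * (1.0 - a)
    w1 = tau - tau * tau / dt * (1.0 - a)  # weight of the right endpoint
    w0 = w_total - w1
    b = np.empty_like(q_ext)
    b[0] = 0.0
    b[1:] = w0 * q_ext[:-1] + w1 * q_ext[1:]
    return lfilter([1.0], [1.0, -a], b)


def _solve_cycle(q: UniformWave, params: WindkesselParams, p_0: float) -> np.ndarray:
    """One cycle of the closed-form solution from initial pressure p_0.

    Returns n+1 samples covering t = 0..T inclusive (the flow is extended
    periodically with Q(T) = Q(0))."""
    tau = params.r * params.c_t
    q_ext = np.append(q.values, q.values[0])
    t_ext = q.dt * np.arange(q.n + 1)
    conv = _exp_convolution(q_ext, q.dt, tau)
    decay = np.exp(-t_ext / tau)
    homog = (p_0 - params.p_out - params.z_0 * q_ext[0]) * decay
    return params.p_out + homog + params.z_0 * q_ext + conv / params.c_t


def _periodic_p0(q: UniformWave, params: WindkesselParams) -> float:
    """Closed-form fixed point of the affine one-cycle map P_0 -> P(T)."""
    tau = params.r * params.c_t
    q_ext = np.append(q.values, q.values[0])
    conv_T = _exp_convolution(q_ext, q.dt, tau)[-1]
    a_T = np.exp(-q.period / tau)
    return float(params.p_out + params.z_0 * q_ext[0] + conv_T / params.c_t / (1.0 - a_T))


def solve_3wk(q: UniformWave, params: WindkesselParams,
              settings: SolveSettings = SolveSettings()) -> UniformWave:
    """Pressure cycle of the three-element Windkessel driven by flow ``q``.

    The Z_0 dQ/dt forcing is handled analytically through the Z_0 Q_in(t)
    term of the integrating-factor solution; no numerical differentiation of
    the flow is performed.
    """
    if q.kind != "flow":
        raise InvalidPhysiologyError("inflow wave must have kind 'flow'")
    if settings.mode == "periodic":
        p_0 = _periodic_p0(q, params)
        p = _solve_cycle(q, params, p_0)
    else:
        if settings.p_0 is None:
            raise ValueError("transient mode requires an initial pressure p_0")
        p_0 = float(settings.p_0)
        for _ in range(settings.max_cycles):
            p = _solve_cycle(q, params, p_0)
            if abs(p[-1] - p_0) < settings.tol:
                break
            p_0 = float(p[-1])
        else:
            raise FitFailedError(
                f"transient iteration did not converge within {settings.max_cycles} cycles",
                best=float(p[-1]),
            )
    return UniformWave(q.t0, q.dt, p[:-1], "pressure")


def solve_2wk(q: UniformWave, params: WindkesselParams,
              settings: SolveSettings = SolveSettings()) -> UniformWave:
    """Pressure cycle of the two-element Windkessel (Z_0 ignored / zero)."""
    p2 = WindkesselParams(r_t=params.r_t, c_t=params.c_t, z_0=0.0, p_out=params.p_out)
    return solve_3wk(q, p2, settings)


def diastolic_decay_constant(params: WindkesselParams) -> float:
    """Diastolic time constant tau = (R_T - Z_0) * C_T (s).

    With zero inflow both models reduce to a pure exponential decay of
    P - P_out with this constant (Z_0 = 0 gives the two-element R_T * C_T).
    """
    return params.r * params.c_t


@dataclass(frozen=True)
class Wk3Fit:
    """Result of the optimized three-element Windkessel fit."""

    z_0: float
    c_t: float
    rmse: float
    n_eval: int = 0


def fit_3wk_optimized(p: UniformWave, q: UniformWave, r_t: float, p_out: float,
                      n_starts: int = 4, seed: int = FIT_SEED,
                      z0_frac_bounds: tuple = (1e-4, 0.5),
                      c_t_bounds: tuple = (0.05, 10.0)) -> Wk3Fit:
    """Least-squares (Z_0, C_T) such that the periodic three-element solution
    driven by ``q`` best matches the measured pressure cycle ``p``.

    R_T and P_out are held fixed (supplied from an upstream estimate or known
    truth). The search is a bounded derivative-free local optimization
    (Nelder-Mead) from ``n_starts`` starting points (one nominal, the rest
    drawn uniformly inside the bounds with a fixed seed); the whole-cycle
    unweighted RMSE is the objective. A start that reaches RMSE below 1e-7
    mmHg terminates the multi-start early (exact-recovery short-circuit).
    """
    if abs(p.period - q.period) > 1e-3 * p.period:
        raise IncomparableWavesError(
            f"pressure and flow periods differ: {p.period} vs {q.period}"
        )
    if q.n != p.n:
        q = resample(q, p.dt)
        if q.n != p.n:  # rounding mismatch: force common length via pressure grid
            q = UniformWave(q.t0, p.dt, q.value_at(p.times), "flow")
    p_meas = p.values
    n_ev = 0

    lo = np.array([z0_frac_bounds[0] * r_t, c_t_bounds[0]])
    hi = np.array([z0_frac_bounds[1] * r_t, c_t_bounds[1]])

    def objective(x):
        nonlocal n_ev
        n_ev += 1
        z0, ct = x
        z0 = min(max(z0, lo[0]), hi[0])
        ct = min(max(ct, lo[1]), hi[1])
        params = WindkesselParams(r_t=r_t, c_t=ct, z_0=z0, p_out=p_out)
        model = solve_3wk(q, params)
        return float(np.sqrt(np.mean((model.values - p_meas) ** 2)))

    rng = np.random.default_rng(seed)
    starts = [np.array([0.05 * r_t, 1.3])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(lo + (hi - lo) * rng.random(2))

    best = None
    failures = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = minimize(
                objective, x0, method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(exc)
            continue
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-7:
            break
    if best is None:
        raise FitFailedError("optimized 3-Wk fit failed on all starts", best=failures)
    z0, ct = np.clip(best.x, lo, hi)
    return Wk3Fit(z_0=float(z0), c_t=float(ct), rmse=float(best.fun), n_eval=n_ev)
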