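"""Cardiovascular parameter estimators, selectable by method code.

Six families of estimators, one per parameter:

* LVET (left ventricular ejection time): LV1-LV4
* P_out (outflow / asymptotic pressure): OP1-OP4
* R_T (total arterial resistance): AR1-AR2
* C_T (total arterial compliance): AC1-AC9
* PWV (pulse wave velocity): PV1-PV5
* Z_0 (characteristic impedance): Z1-Z6

Each estimator consumes an :class:`EstimatorInput` (waves and/or scalar
peripheral pressures plus optional geometry) and returns an
:class:`EstimateResult` carrying the value in canonical units, the method
code and fit diagnostics. Failures always raise a typed error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import (
    FitFailedError,
    InapplicableMethodError,
    NonPhysicalResultError,
)
from .waveforms import (
    MMHG_PA,
    PA_S_PER_M3_TO_MMHG_S_PER_ML,
    UniformWave,
    detect_dicrotic_notch,
    detect_foot,
    differentiate,
    harmonics,
    resample,
    wave_stats,
)
from .windkessel import SolveSettings, WindkesselParams, fit_3wk_optimized, solve_2wk

#: default blood density (kg/m^3)
DEFAULT_RHO = 1060.0

#: LV4 end-of-ejection threshold as a fraction of peak flow
DEFAULT_Q_TH = 0.02

#: harmonic range used by the frequency-domain impedance method Z1
Z1_HARMONICS = (4, 10)


@dataclass
class EstimatorInput:
    """Everything an estimator might need; methods use the subset they require.

    p_wave : peripheral/central pressure wave (mmHg), optional
    dbp, sbp : scalar peripheral pressures (mmHg), optional
    q_wave : aortic root flow wave (mL/s)
    q_distal : descending-aorta flow wave (for transit-time PWV)
    p_pair : (proximal, distal) pressure wave pair, e.g. carotid-femoral
    dx, dx_aorta : path lengths (m) for the pressure pair / aortic flow pair
    area : aortic root cross-sectional area (m^2)
    rho : blood density (kg/m^3)
    """

    p_wave: Optional[UniformWave] = None
    dbp: Optional[float] = None
    sbp: Optional[float] = None
    q_wave: Optional[UniformWave] = None
    q_distal: Optional[UniformWave] = None
    p_pair: Optional[Tuple[UniformWave, UniformWave]] = None
    dx: Optional[float] = None
    dx_aorta: Optional[float] = None
    area: Optional[float] = None
    rho: float = DEFAULT_RHO

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise InapplicableMethodError(f"estimator requires {name!r}")

    def dbp_value(self) -> float:
        if self.dbp is not None:
            return float(self.dbp)
        self.require("p_wave")
        return wave_stats(self.p_wave).dbp

    def sbp_value(self) -> float:
        if self.sbp is not None:
            return float(self.sbp)
        self.require("p_wave")
        return wave_stats(self.p_wave).sbp


@dataclass(frozen=True)
class EstimateResult:
    """A single parameter estimate in canonical units plus diagnostics."""

    value: float
    method_code: str
    diagnostics: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise NonPhysicalResultError(
                f"{self.method_code} produced non-finite value {self.value}"
            )


# ---------------------------------------------------------------------------
# diastolic window helpers
# ---------------------------------------------------------------------------

def _diastole_start(p: UniformWave, lvet: float) -> float:
    """End of systole on the pressure wave's own clock: foot + LVET."""
    return detect_foot(p) + lvet


def _fit_exp_decay(p: UniformWave, t_start: float, t_end: float
                   ) -> Tuple[float, float, float]:
    """Three-parameter exponential fit P(t) = P_out + B e^{-(t-t1)/tau} over
    [t_start, t_end]; returns (P_out, B, tau).

    Initial values come from a crude two-point time constant; the fit is an
    unbounded Levenberg-Marquardt least squares.
    """
    t = p.times
    mask = (t >= t_start) & (t <= t_end)
    tt = t[mask]
    vv = p.values[mask]
    if tt.size < 5:
        raise FitFailedError(
            f"diastolic window [{t_start:.3f}, {t_end:.3f}] has {tt.size} samples"
        )
    t1 = tt[0]
    p_out0 = 0.5 * vv.min()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (vv[0] - p_out0) / max(vv[-1] - p_out0, 1e-9)
    tau0 = (tt[-1] - t1) / np.log(ratio) if ratio > 1 else 1.0
    tau0 = float(np.clip(tau0, 1e-2, 20.0))

    def model(t_, p_out, b, tau):
        return p_out + b * np.exp(-(t_ - t1) / tau)

    try:
        popt, _ = curve_fit(
            model, tt, vv, p0=[p_out0, vv[0] - p_out0, tau0], maxfev=10000
        )
    except RuntimeError as exc:
        raise FitFailedError(f"exponential diastolic fit did not converge: {exc}")
    p_out, b, tau = (float(x) for x in popt)
    if tau <= 0 or b <= 0:
        raise FitFailedError(
            f"exponential fit non-physical: B={b:.3g}, tau={tau:.3g}"
        )
    return p_out, b, tau


# ---------------------------------------------------------------------------
# LVET
# ---------------------------------------------------------------------------

def estimate_lvet(inp: EstimatorInput, method: str = "LV4",
                  q_th: float = DEFAULT_Q_TH,
                  weissler_sqrt: bool = False) -> EstimateResult:
    """Left ventricular ejection time (s).

    LV1: dicrotic-notch time minus pressure foot (fails on notchless waves).
    LV2: time of the global minimum of dP/dt after the systolic peak, minus
         the pressure foot.
    LV3: 0.37 * T (literal fixed fraction of the cycle; with
         ``weissler_sqrt`` the Weissler-style 0.37 * sqrt(T) is used instead).
    LV4: flow-derived ejection window, from the flow foot to the first time
         after peak flow at which Q drops to ``q_th`` of its peak (or the
         first local minimum, whichever comes first).
    """
    if method == "LV1":
        inp.require("p_wave")
        notch = detect_dicrotic_notch(inp.p_wave)
        if notch is None:
            raise InapplicableMethodError(
                "LV1 needs a dicrotic notch / second systolic peak; none found"
            )
        foot = detect_foot(inp.p_wave)
        return EstimateResult(notch - foot, "LV1", {"notch": notch, "foot": foot})
    if method == "LV2":
        inp.require("p_wave")
        p = inp.p_wave
        foot = detect_foot(p)
        dpdt = differentiate(p).values
        i_peak = int(np.argmax(p.values))
        if i_peak >= p.n - 2:
            raise InapplicableMethodError("LV2: systolic peak at end of cycle")
        i_min = i_peak + 1 + int(np.argmin(dpdt[i_peak + 1:]))
        t_min = p.t0 + i_min * p.dt
        return EstimateResult(t_min - foot, "LV2", {"t_dpdt_min": t_min, "foot": foot})
    if method == "LV3":
        w = inp.p_wave if inp.p_wave is not None else inp.q_wave
        if w is None:
            raise InapplicableMethodError("LV3 needs a wave to read the period from")
        T = w.period
        value = 0.37 * np.sqrt(T) if weissler_sqrt else 0.37 * T
        return EstimateResult(value, "LV3", {"period": T})
    if method == "LV4":
        inp.require("q_wave")
        q = inp.q_wave
        foot = detect_foot(q)
        v = q.values
        i_peak = int(np.argmax(v))
        q_max = v[i_peak]
        thresh = q_th * q_max
        t_end = None
        # first sub-threshold crossing after the peak, sub-sample interpolated
        after = v[i_peak:]
        below = np.nonzero(after <= thresh)[0]
        if below.size:
            j = below[0]
            if j > 0 and after[j - 1] > thresh:
                frac = (after[j - 1] - thresh) / (after[j - 1] - after[j])
                t_end = q.t0 + (i_peak + j - 1 + frac) * q.dt
            else:
                t_end = q.t0 + (i_peak + j) * q.dt
        # first strict local minimum after the peak
        seg = v[i_peak:]
        mins = np.nonzero(
            (seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])
        )[0]
        if mins.size:
            t_lmin = q.t0 + (i_peak + 1 + mins[0]) * q.dt
            t_end = t_lmin if t_end is None else min(t_end, t_lmin)
        if t_end is None:
            raise InapplicableMethodError("LV4: flow never falls off after its peak")
        return EstimateResult(t_end - foot, "LV4", {"foot": foot, "t_end": t_end})
    raise InapplicableMethodError(f"unknown LVET method {method!r}")


# ---------------------------------------------------------------------------
# P_out
# ---------------------------------------------------------------------------

def estimate_pout(inp: EstimatorInput, lvet: Optional[float] = None,
                  method: str = "OP1") -> EstimateResult:
    """Outflow (asymptotic) pressure P_out (mmHg).

    OP1 / OP2: asymptote of the three-parameter exponential fit to the
    diastolic decay; OP1 fits from 20 ms after end of systole to the end of
    the cycle, OP2 only the final two-thirds of diastole. OP3 = 0.5 * DBP,
    OP4 = 0.7 * DBP.
    """
    if method in ("OP1", "OP2"):
        inp.require("p_wave")
        if lvet is None:
            raise InapplicableMethodError(f"{method} needs an LVET estimate")
        p = inp.p_wave
        t_d = _diastole_start(p, lvet)
        t_end = p.t0 + (p.n - 1) * p.dt
        t_start = t_d + 0.02 if method == "OP1" else t_d + (t_end - t_d) / 3.0
        p_out, b, tau = _fit_exp_decay(p, t_start, t_end)
        if p_out < 0:
            raise FitFailedError(f"{method}: fitted P_out negative ({p_out:.2f} mmHg)")
        return EstimateResult(p_out, method, {"tau": tau, "b": b, "window": (t_start, t_end)})
    if method == "OP3":
        return EstimateResult(0.5 * inp.dbp_value(), "OP3")
    if method == "OP4":
        return EstimateResult(0.7 * inp.dbp_value(), "OP4")
    raise InapplicableMethodError(f"unknown P_out method {method!r}")


# ---------------------------------------------------------------------------
# R_T
# ---------------------------------------------------------------------------

def estimate_rt(inp: EstimatorInput, p_out: float,
                method: str = "AR1") -> EstimateResult:
    """Total arterial resistance R_T (mmHg.s/mL).

    AR1 = (MBP - P_out) / Q_mean using the full pressure wave;
    AR2 = (DBP + 0.4 PP - P_out) / Q_mean using scalar peripheral pressures
    (DBP + 0.4 PP is the classic MBP surrogate).
    """
    inp.require("q_wave")
    q_mean = wave_stats(inp.q_wave).q_mean
    if q_mean <= 0:
        raise NonPhysicalResultError(f"mean flow must be positive, got {q_mean}")
    if method == "AR1":
        inp.require("p_wave")
        mbp = wave_stats(inp.p_wave).mbp
        num = mbp - p_out
    elif method == "AR2":
        dbp, sbp = inp.dbp_value(), inp.sbp_value()
        num = dbp + 0.4 * (sbp - dbp) - p_out
    else:
        raise InapplicableMethodError(f"unknown R_T method {method!r}")
    if num <= 0:
        raise NonPhysicalResultError(
            f"{method}: driving pressure {num:.2f} mmHg is not positive"
        )
    return EstimateResult(num / q_mean, method, {"q_mean": q_mean})


# ---------------------------------------------------------------------------
# C_T
# ---------------------------------------------------------------------------

def _window_integral(p: UniformWave, t1: float, t2: float, p_out: float) -> float:
    """Trapezoidal integral of (P - P_out) over [t1, t2] with interpolated
    endpoints."""
    t = p.times
    inner = (t > t1) & (t < t2)
    ts = np.concatenate([[t1], t[inner], [t2]])
    vs = np.concatenate([[float(p.value_at(t1))], p.values[inner], [float(p.value_at(t2))]])
    return float(np.trapezoid(vs - p_out, ts))


def estimate_ct(inp: EstimatorInput, r_t: float, p_out: float,
                z_0: Optional[float] = None, lvet: Optional[float] = None,
                method: str = "AC9") -> EstimateResult:
    """Total arterial compliance C_T (mL/mmHg).

    Decay-constant methods (AC1-AC4) measure the diastolic time constant tau
    and return tau / R_T; when ``z_0`` is supplied they divide by R_T - Z_0
    instead (tau = (R_T - Z_0) C_T in the three-element model). AC5 is the
    two-area method (joint linear solve for C_T and a refitted 1/R). AC6/AC7
    root-find the compliance at which the periodic two-element model matches
    measured DBP / PP. AC8 = SV / PP. AC9 takes C_T from the optimized
    three-element fit.
    """
    r_eff = r_t - z_0 if z_0 is not None else r_t
    if r_eff <= 0:
        raise NonPhysicalResultError(f"effective resistance {r_eff} not positive")

    if method in ("AC1", "AC4"):
        inp.require("p_wave")
        if lvet is None:
            raise InapplicableMethodError(f"{method} needs an LVET estimate")
        p = inp.p_wave
        t1 = _diastole_start(p, lvet) + 0.05
        t2 = p.t0 + (p.n - 1) * p.dt
        if t2 - t1 < 5 * p.dt:
            raise FitFailedError(f"{method}: diastolic window too short")
        p1 = float(p.value_at(t1)) - p_out
        p2 = float(p.value_at(t2)) - p_out
        if method == "AC1":
            if p1 <= 0 or p2 <= 0 or p1 <= p2:
                raise NonPhysicalResultError(
                    "AC1: diastolic pressures do not decay towards P_out"
                )
            tau = (t2 - t1) / np.log(p1 / p2)
        else:  # AC4, area method
            if p1 <= p2:
                raise NonPhysicalResultError("AC4: no diastolic decay over the window")
            tau = _window_integral(p, t1, t2, p_out) / (p1 - p2)
        return EstimateResult(tau / r_eff, method, {"tau": tau, "window": (t1, t2)})

    if method in ("AC2", "AC3"):
        inp.require("p_wave")
        if lvet is None:
            raise InapplicableMethodError(f"{method} needs an LVET estimate")
        p = inp.p_wave
        t_d = _diastole_start(p, lvet)
        t_end = p.t0 + (p.n - 1) * p.dt
        t_start = t_d + 0.02 if method == "AC2" else t_d + (t_end - t_d) / 3.0
        _, _, tau = _fit_exp_decay(p, t_start, t_end)
        return EstimateResult(tau / r_eff, method, {"tau": tau, "window": (t_start, t_end)})

    if method == "AC5":
        inp.require("p_wave", "q_wave")
        if lvet is None:
            raise InapplicableMethodError("AC5 needs an LVET estimate")
        p, q = inp.p_wave, inp.q_wave
        foot = detect_foot(p)
        t_s = foot + lvet
        t_end = p.t0 + (p.n - 1) * p.dt
        rows, rhs = [], []
        for a, b in ((foot, t_s), (t_s, t_end)):
            dp = float(p.value_at(b)) - float(p.value_at(a))
            area_p = _window_integral(p, a, b, p_out)
            area_q = _window_integral(q, a, b, 0.0)
            rows.append([dp, area_p])
            rhs.append(area_q)
        A = np.array(rows)
        if abs(np.linalg.det(A)) < 1e-12 * max(1.0, np.abs(A).max() ** 2):
            raise FitFailedError("AC5: singular two-area system")
        c_t, g = np.linalg.solve(A, rhs)  # g = 1 / R refitted
        if c_t <= 0:
            raise NonPhysicalResultError(f"AC5: non-positive compliance {c_t:.3g}")
        return EstimateResult(float(c_t), "AC5", {"r_refit": 1.0 / g if g else np.inf})

    if method in ("AC6", "AC7"):
        inp.require("q_wave")
        q = inp.q_wave
        if method == "AC6":
            target = inp.dbp_value()
            def metric(st):
                return st.dbp
        else:
            target = inp.sbp_value() - inp.dbp_value()
            def metric(st):
                return st.pp

        def g(c):
            params = WindkesselParams(r_t=r_t, c_t=c, z_0=0.0, p_out=p_out)
            return metric(wave_stats(solve_2wk(q, params))) - target

        lo, hi = 0.05, 10.0
        try:
            g_lo, g_hi = g(lo), g(hi)
            if g_lo * g_hi > 0:
                raise FitFailedError(
                    f"{method}: target not bracketed in C_T in [{lo}, {hi}] "
                    f"(g({lo})={g_lo:.3g}, g({hi})={g_hi:.3g})"
                )
            c = brentq(g, lo, hi, xtol=1e-10, rtol=1e-12)
        except ValueError as exc:
            raise FitFailedError(f"{method}: root finding failed: {exc}")
        return EstimateResult(float(c), method, {"target": target})

    if method == "AC8":
        inp.require("q_wave")
        sv = wave_stats(inp.q_wave).sv
        pp = inp.sbp_value() - inp.dbp_value()
        if pp <= 0:
            raise NonPhysicalResultError("AC8: pulse pressure must be positive")
        return EstimateResult(sv / pp, "AC8", {"sv": sv, "pp": pp})

    if method == "AC9":
        inp.require("p_wave", "q_wave")
        fit = fit_3wk_optimized(inp.p_wave, inp.q_wave, r_t=r_t, p_out=p_out)
        return EstimateResult(fit.c_t, "AC9", {"z_0": fit.z_0, "rmse": fit.rmse})

    raise InapplicableMethodError(f"unknown C_T method {method!r}")


# ---------------------------------------------------------------------------
# PWV
# ---------------------------------------------------------------------------

def _ls_transit_time(w_prox: UniformWave, w_dist: UniformWave) -> float:
    """Least-squares transit time: the shift s minimising the sum of squared
    differences between the proximal upstroke and the shifted distal wave,
    refined to sub-sample resolution by parabolic interpolation."""
    if abs(w_prox.period - w_dist.period) > 0.1 * w_prox.period:
        raise NonPhysicalResultError("wave pair periods differ by more than 10%")
    dt = w_prox.dt
    foot = detect_foot(w_prox)
    i_foot = int(np.floor((foot - w_prox.t0) / dt))
    i_peak = int(np.argmax(w_prox.values))
    if i_peak <= i_foot:
        i_peak = i_foot + max(5, (w_prox.n // 10))
    idx = np.arange(max(i_foot, 0), min(i_peak + 1, w_prox.n))
    t_win = w_prox.t0 + idx * dt
    prox = w_prox.values[idx]
    max_lag = w_prox.n // 2
    sse = np.empty(max_lag)
    for k in range(max_lag):
        dist = w_dist.value_at(t_win + k * dt - (w_dist.t0 - w_prox.t0))
        sse[k] = np.sum((prox - dist) ** 2)
    k0 = int(np.argmin(sse))
    s = k0 * dt
    if 0 < k0 < max_lag - 1:
        y0, y1, y2 = sse[k0 - 1], sse[k0], sse[k0 + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            s += dt * 0.5 * (y0 - y2) / denom
    return s


def estimate_pwv(inp: EstimatorInput, method: str = "PV1") -> EstimateResult:
    """Aortic pulse wave velocity (m/s).

    PV1 / PV2: foot-to-foot transit time over the path length, on the
    ascending/descending flow pair (PV1) or a pressure pair (PV2).
    PV3 / PV4: least-squares upstroke alignment on the same pairs.
    PV5: sum-of-squares (water-hammer) estimate
    sqrt(sum dP^2 / sum dU^2) / rho from co-located pressure and velocity.
    """
    if method in ("PV1", "PV3"):
        inp.require("q_wave", "q_distal", "dx_aorta")
        prox, dist, dx = inp.q_wave, inp.q_distal, inp.dx_aorta
    elif method in ("PV2", "PV4"):
        inp.require("p_pair", "dx")
        (prox, dist), dx = inp.p_pair, inp.dx
    elif method == "PV5":
        inp.require("p_wave", "q_wave", "area")
        p, q = inp.p_wave, inp.q_wave
        if q.n != p.n:
            q = UniformWave(q.t0, p.dt, q.value_at(p.times), "flow")
        u = q.values * 1e-6 / inp.area  # m/s
        dp = np.diff(p.values) * MMHG_PA  # Pa
        du = np.diff(u)
        if np.sum(du ** 2) <= 0:
            raise NonPhysicalResultError("PV5: velocity wave has zero variation")
        pwv = np.sqrt(np.sum(dp ** 2) / np.sum(du ** 2)) / inp.rho
        return EstimateResult(float(pwv), "PV5")
    else:
        raise InapplicableMethodError(f"unknown PWV method {method!r}")

    if dx <= 0:
        raise NonPhysicalResultError("path length must be positive")
    if method in ("PV1", "PV2"):
        tt = detect_foot(dist) - detect_foot(prox)
        diag = {"transit_time": tt, "kind": "foot-to-foot"}
    else:
        tt = _ls_transit_time(prox, dist)
        diag = {"transit_time": tt, "kind": "least-squares"}
    if tt <= 0:
        raise NonPhysicalResultError(f"{method}: non-positive transit time {tt:.4f} s")
    return EstimateResult(dx / tt, method, diag)


# ---------------------------------------------------------------------------
# Z_0
# ---------------------------------------------------------------------------

def estimate_z0(inp: EstimatorInput, r_t: Optional[float] = None,
                pwv: Optional[float] = None, method: str = "Z2",
                harmonic_range: Tuple[int, int] = Z1_HARMONICS) -> EstimateResult:
    """Characteristic impedance Z_0 (mmHg.s/mL).

    Z1: mean modulus of the input impedance P_k / Q_k over harmonics 4-10
        (configurable), where the high-frequency impedance plateaus at Z_0.
    Z2: PQ-loop slope, least-squares slope of P against Q over early systole
        (flow foot to 95% of peak flow).
    Z3: 0.05 * R_T.   Z4: (MBP - DBP) / Q_max.
    Z5: water-hammer rho * PWV / A, converted to clinical units.
    Z6: Z_0 from the optimized three-element Windkessel fit.
    """
    if method == "Z1":
        inp.require("p_wave", "q_wave")
        p, q = inp.p_wave, inp.q_wave
        if q.n != p.n:
            q = UniformWave(q.t0, p.dt, q.value_at(p.times), "flow")
        k_lo, k_hi = harmonic_range
        cp = harmonics(p, k_hi)
        cq = harmonics(q, k_hi)
        mods = []
        q0 = abs(cq[0])
        for k in range(k_lo, k_hi + 1):
            if abs(cq[k]) > 1e-9 * q0:
                mods.append(abs(cp[k]) / abs(cq[k]))
        if not mods:
            raise NonPhysicalResultError(
                f"Z1: flow harmonics {k_lo}-{k_hi} all below threshold"
            )
        return EstimateResult(float(np.mean(mods)), "Z1", {"n_harmonics": len(mods)})
    if method == "Z2":
        inp.require("p_wave", "q_wave")
        p, q = inp.p_wave, inp.q_wave
        foot = detect_foot(q)
        i0 = max(0, int(np.floor((foot - q.t0) / q.dt)))
        qmax = q.values.max()
        after = np.nonzero(q.values[i0:] >= 0.95 * qmax)[0]
        if after.size == 0:
            raise NonPhysicalResultError("Z2: flow never reaches 95% of peak")
        i1 = i0 + after[0]
        if i1 - i0 + 1 < 5:
            raise NonPhysicalResultError(
                f"Z2: early-systolic window has {i1 - i0 + 1} samples (< 5)"
            )
        t_win = q.t0 + np.arange(i0, i1 + 1) * q.dt
        qq = q.values[i0:i1 + 1]
        pp = np.asarray(p.value_at(t_win))
        slope = float(np.polyfit(qq, pp, 1)[0])
        if slope <= 0:
            raise NonPhysicalResultError(f"Z2: non-positive PQ slope {slope:.4g}")
        return EstimateResult(slope, "Z2", {"window": (t_win[0], t_win[-1])})
    if method == "Z3":
        if r_t is None:
            raise InapplicableMethodError("Z3 needs an R_T estimate")
        return EstimateResult(0.05 * r_t, "Z3")
    if method == "Z4":
        inp.require("q_wave")
        q_max = wave_stats(inp.q_wave).q_max
        if inp.p_wave is not None:
            st = wave_stats(inp.p_wave)
            mbp, dbp = st.mbp, st.dbp
        else:
            dbp, sbp = inp.dbp_value(), inp.sbp_value()
            mbp = dbp + 0.4 * (sbp - dbp)
        if q_max <= 0:
            raise NonPhysicalResultError("Z4: peak flow must be positive")
        return EstimateResult((mbp - dbp) / q_max, "Z4", {"mbp": mbp, "dbp": dbp})
    if method == "Z5":
        if pwv is None:
            raise InapplicableMethodError("Z5 needs a PWV estimate")
        inp.require("area")
        z_si = inp.rho * pwv / inp.area  # Pa.s/m^3
        return EstimateResult(z_si * PA_S_PER_M3_TO_MMHG_S_PER_ML, "Z5",
                              {"z_si": z_si})
    if method == "Z6":
        raise InapplicableMethodError(
            "Z6 needs R_T and P_out; use estimate_z0_optimized(inp, r_t, p_out)"
        )
    raise InapplicableMethodError(f"unknown Z_0 method {method!r}")


def estimate_z0_optimized(inp: EstimatorInput, r_t: float, p_out: float) -> EstimateResult:
    """Z6: characteristic impedance from the optimized three-element fit."""
    inp.require("p_wave", "q_wave")
    fit = fit_3wk_optimized(inp.p_wave, inp.q_wave, r_t=r_t, p_out=p_out)
    return EstimateResult(fit.z_0, "Z6", {"c_t": fit.c_t, "rmse": fit.rmse})
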