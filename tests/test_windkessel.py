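import numpy as np
import pytest
from scipy.signal import lfilter

from cbpkit import (
    SolveSettings,
    UniformWave,
    WindkesselParams,
    diastolic_decay_constant,
    fit_3wk_optimized,
    solve_2wk,
    solve_3wk,
    wave_stats,
)
from cbpkit.errors import InvalidPhysiologyError

from conftest import half_sine_flow


# ---------------------------------------------------------------------------
# independent oracle: classic fixed-step RK4 on the governing ODE
#   dP/dt = -(P - P_out)/(R C) + Z0 dQ/dt + (Z0 + R) Q / (R C)
# with the analytic half-sine inflow (not the sampled interpolant). For this
# linear ODE each RK4 step is affine, P_{k+1} = A P_k + B_k, so the classic
# RK4 weights can be applied exactly and the recursion evaluated by lfilter;
# the periodic cycle is the fixed point of the (affine) one-cycle map.
# ---------------------------------------------------------------------------

def rk4_periodic(params: WindkesselParams, peak, lvet, T, dt_out, h=1e-5):
    tau = params.r * params.c_t

    def qf(t):
        tt = np.mod(t, T)
        return np.where(tt < lvet, peak * np.sin(np.pi * tt / lvet), 0.0)

    def qdot(t):
        tt = np.mod(t, T)
        return np.where(
            tt < lvet, peak * np.pi / lvet * np.cos(np.pi * tt / lvet), 0.0)

    def beta(t):
        return (params.p_out / tau + params.z_0 * qdot(t)
                + params.r_t * qf(t) / (params.r * params.c_t))

    n = int(round(T / h))
    tk = h * np.arange(n)
    a = -h / tau
    A = 1 + a + a**2 / 2 + a**3 / 6 + a**4 / 24
    w1 = (h / 6) * (1 + a + a**2 / 2 + a**3 / 4)
    w2 = (h / 6) * (4 + 2 * a + a**2 / 2)
    w3 = h / 6
    B = w1 * beta(tk) + w2 * beta(tk + h / 2) + w3 * beta(tk + h)
    # one-cycle affine map P0 -> alpha + A^n P0; alpha from a run with P0 = 0
    steps = lfilter([1.0], [1.0, -A], np.concatenate([[0.0], B]))
    alpha = steps[-1]
    p0 = alpha / (1.0 - A**n)
    p = steps + p0 * A ** np.arange(n + 1)
    stride = int(round(dt_out / h))
    return p[:-1:stride]


def sampled_half_sine(peak, lvet, T, dt=1e-3):
    return half_sine_flow(peak=peak, lvet=lvet, T=T, dt=dt)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(r_t=-1, c_t=1), dict(r_t=1, c_t=0),
        dict(r_t=1, c_t=1, z_0=1.5), dict(r_t=1, c_t=1, p_out=-5),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidPhysiologyError):
            WindkesselParams(**kwargs)

    def test_derived_distal_resistance(self):
        p = WindkesselParams(r_t=0.5, c_t=1.5, z_0=0.05)
        assert p.r == pytest.approx(0.45)


class TestClosedForm:
    def test_zero_inflow_stays_at_outflow_pressure(self):
        q = UniformWave(0.0, 1e-3, np.zeros(870), "flow")
        params = WindkesselParams(r_t=0.5, c_t=1.5, p_out=32.0)
        p = solve_2wk(q, params, SolveSettings(mode="transient", p_0=32.0))
        assert np.allclose(p.values, 32.0, atol=1e-12)

    @pytest.mark.parametrize("solver", [solve_2wk, solve_3wk])
    def test_constant_inflow_steady_state(self, solver):
        q = UniformWave(0.0, 1e-3, np.full(870, 90.0), "flow")
        params = WindkesselParams(r_t=0.5, c_t=1.5, z_0=0.02, p_out=32.0)
        p = solver(q, params)
        expected = 32.0 + 0.5 * 90.0
        assert np.allclose(p.values, expected, atol=1e-9)

    def test_3wk_reduces_to_2wk_at_zero_impedance(self):
        q = sampled_half_sine(300.0, 0.26, 0.87)
        params = WindkesselParams(r_t=0.5, c_t=1.5, z_0=0.0, p_out=32.0)
        p2 = solve_2wk(q, params)
        p3 = solve_3wk(q, params)
        assert np.max(np.abs(p2.values - p3.values)) < 1e-9

    def test_2wk_against_rk4_oracle(self):
        peak, lvet, T = 300.0, 0.26, 0.87
        params = WindkesselParams(r_t=0.5, c_t=1.5, p_out=32.0)
        q = sampled_half_sine(peak, lvet, T)
        p = solve_2wk(q, params)
        oracle = rk4_periodic(params, peak, lvet, T, dt_out=q.dt)
        assert np.max(np.abs(p.values - oracle)) < 0.05

    def test_3wk_against_rk4_oracle(self):
        peak, lvet, T = 300.0, 0.26, 0.87
        params = WindkesselParams(r_t=0.5, c_t=1.5, z_0=0.05 * 0.5, p_out=32.0)
        q = sampled_half_sine(peak, lvet, T)
        p = solve_3wk(q, params)
        oracle = rk4_periodic(params, peak, lvet, T, dt_out=q.dt)
        assert np.max(np.abs(p.values - oracle)) < 0.05

    def test_periodic_mean_identity(self):
        q = sampled_half_sine(420.0, 0.26, 0.87)
        params = WindkesselParams(r_t=0.51, c_t=1.3, z_0=0.0255, p_out=32.3)
        p = solve_3wk(q, params)
        st_p, st_q = wave_stats(p), wave_stats(q)
        assert st_p.mbp == pytest.approx(32.3 + 0.51 * st_q.q_mean, abs=0.1)

    def test_pressure_bounded_below_by_outflow_pressure(self):
        q = sampled_half_sine(300.0, 0.26, 0.87)
        params = WindkesselParams(r_t=0.5, c_t=1.5, z_0=0.02, p_out=32.0)
        p = solve_3wk(q, params)
        assert np.all(p.values >= 32.0)

    def test_transient_converges_geometrically(self):
        q = sampled_half_sine(300.0, 0.26, 0.87)
        params = WindkesselParams(r_t=0.5, c_t=1.5, p_out=32.0)
        target = solve_2wk(q, params).values[0]
        tau = diastolic_decay_constant(params)
        ratio = np.exp(-q.period / tau)
        # one-cycle map contracts the start-of-cycle error by e^{-T/tau}
        from cbpkit.windkessel import _solve_cycle
        p0 = target + 10.0
        errs = []
        for _ in range(3):
            cycle = _solve_cycle(q, params, p0)
            p0 = cycle[-1]
            errs.append(abs(p0 - target))
        assert errs[0] / 10.0 == pytest.approx(ratio, rel=1e-6)
        assert errs[1] / errs[0] == pytest.approx(ratio, rel=1e-6)


class TestDecayConstant:
    def test_two_element(self):
        assert diastolic_decay_constant(
            WindkesselParams(0.5, 1.5)) == pytest.approx(0.75)

    def test_three_element(self):
        assert diastolic_decay_constant(
            WindkesselParams(0.5, 1.5, z_0=0.025)) == pytest.approx(0.7125)

    def test_simulated_diastole_log_slope(self):
        q = sampled_half_sine(300.0, 0.26, 0.87)
        params = WindkesselParams(r_t=0.5, c_t=1.5, z_0=0.025, p_out=32.0)
        p = solve_3wk(q, params)
        t = p.times
        mask = (t > 0.30) & (t < 0.86)  # flow is zero here
        slope = np.polyfit(t[mask], np.log(p.values[mask] - 32.0), 1)[0]
        tau = diastolic_decay_constant(params)
        assert -1.0 / slope == pytest.approx(tau, rel=5e-3)


class TestOptimizedFit:
    def test_exact_recovery(self, baseline_subject):
        q, p, tr = baseline_subject
        fit = fit_3wk_optimized(p, q, r_t=tr["r_t"], p_out=tr["p_out"])
        assert fit.z_0 == pytest.approx(tr["z_0"], rel=1e-3)
        assert fit.c_t == pytest.approx(tr["c_t"], rel=1e-3)
        assert fit.rmse < 0.05

    def test_matches_brute_force_grid(self, baseline_subject):
        q, p, tr = baseline_subject
        fit = fit_3wk_optimized(p, q, r_t=tr["r_t"], p_out=tr["p_out"])
        z_grid = np.geomspace(1e-4 * tr["r_t"], 0.5 * tr["r_t"], 40)
        c_grid = np.geomspace(0.05, 10.0, 40)
        best = (np.inf, None, None)
        for z in z_grid:
            for c in c_grid:
                params = WindkesselParams(tr["r_t"], c, z_0=z, p_out=tr["p_out"])
                rmse = np.sqrt(np.mean((solve_3wk(q, params).values - p.values) ** 2))
                if rmse < best[0]:
                    best = (rmse, z, c)
        # optimizer must land within one grid cell of the brute-force minimum
        assert abs(np.log(fit.z_0 / best[1])) < np.log(z_grid[1] / z_grid[0]) * 1.5
        assert abs(np.log(fit.c_t / best[2])) < np.log(c_grid[1] / c_grid[0]) * 1.5
        assert fit.rmse <= best[0] + 1e-9
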