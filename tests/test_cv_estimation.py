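import numpy as np
import pytest

from cbpkit import (
    EstimatorInput,
    UniformWave,
    WindkesselParams,
    estimate_ct,
    estimate_lvet,
    estimate_pout,
    estimate_pwv,
    estimate_rt,
    estimate_z0,
    estimate_z0_optimized,
    solve_2wk,
    wave_stats,
)
from cbpkit.errors import (
    InapplicableMethodError,
    NonPhysicalResultError,
)

from conftest import half_sine_flow


@pytest.fixture(scope="module")
def inp(baseline_subject):
    q, p, tr = baseline_subject
    return EstimatorInput(p_wave=p, q_wave=q)


class TestLVET:
    def test_fixed_fraction_rule(self):
        q = half_sine_flow(T=1.0)
        assert estimate_lvet(EstimatorInput(q_wave=q), "LV3").value == pytest.approx(0.37)

    def test_weissler_sqrt_variant(self):
        q = half_sine_flow(T=0.81)
        est = estimate_lvet(EstimatorInput(q_wave=q), "LV3", weissler_sqrt=True)
        assert est.value == pytest.approx(0.37 * 0.9)

    def test_flow_based_matches_generator(self, baseline_subject):
        q, _, tr = baseline_subject
        est = estimate_lvet(EstimatorInput(q_wave=q), "LV4")
        assert abs(est.value - tr["lvet"]) <= 2 * q.dt

    def test_dpdt_method_underestimates_on_windkessel_pressure(self, inp, baseline_subject):
        _, _, tr = baseline_subject
        est = estimate_lvet(inp, "LV2")
        assert est.value < tr["lvet"]

    def test_notch_method_fails_on_notchless_wave(self, inp):
        with pytest.raises(InapplicableMethodError):
            estimate_lvet(inp, "LV1")

    def test_notch_method_on_wave_with_second_peak(self):
        dt = 1e-3
        t = dt * np.arange(900)
        v = 70 + 40 * np.exp(-t / 0.4) * np.maximum(np.sin(np.pi * t / 0.35), 0) \
            + 6 * np.exp(-((t - 0.42) / 0.04) ** 2)
        p = UniformWave(0.0, dt, v + 0.001 * t, "pressure")
        est = estimate_lvet(EstimatorInput(p_wave=p), "LV1")
        assert 0.2 < est.value < 0.5


class TestPout:
    def test_half_dbp_rule(self):
        assert estimate_pout(EstimatorInput(dbp=64.6), method="OP3").value == \
            pytest.approx(32.3)

    def test_seventy_percent_dbp_rule(self):
        assert estimate_pout(EstimatorInput(dbp=64.6), method="OP4").value == \
            pytest.approx(0.7 * 64.6)

    @pytest.mark.parametrize("method", ["OP1", "OP2"])
    def test_exponential_fit_recovers_truth(self, inp, baseline_subject, method):
        _, _, tr = baseline_subject
        est = estimate_pout(inp, lvet=tr["lvet"], method=method)
        assert est.value == pytest.approx(tr["p_out"], rel=1e-3)
        assert est.diagnostics["tau"] == pytest.approx(
            (tr["r_t"] - tr["z_0"]) * tr["c_t"], rel=1e-3)

    def test_fit_needs_lvet(self, inp):
        with pytest.raises(InapplicableMethodError):
            estimate_pout(inp, method="OP1")


class TestRt:
    def test_arithmetic_from_wave(self):
        p = UniformWave(0.0, 1e-3, np.full(1000, 100.0), "pressure")
        q = UniformWave(0.0, 1e-3, np.full(1000, 100.0), "flow")
        est = estimate_rt(EstimatorInput(p_wave=p, q_wave=q), p_out=30.0, method="AR1")
        assert est.value == pytest.approx(0.70)

    def test_arithmetic_from_scalars(self):
        q = UniformWave(0.0, 1e-3, np.full(1000, 90.0), "flow")
        est = estimate_rt(EstimatorInput(dbp=80, sbp=120, q_wave=q),
                          p_out=33.0, method="AR2")
        assert est.value == pytest.approx(0.70)

    def test_exact_on_generated_subject(self, inp, baseline_subject):
        _, _, tr = baseline_subject
        est = estimate_rt(inp, p_out=tr["p_out"], method="AR1")
        assert est.value == pytest.approx(tr["r_t"], rel=1e-6)

    def test_nonphysical_numerator_raises(self, inp):
        with pytest.raises(NonPhysicalResultError):
            estimate_rt(inp, p_out=500.0, method="AR1")


class TestCt:
    @pytest.mark.parametrize("method,tol", [
        ("AC1", 1e-3), ("AC2", 1e-4), ("AC3", 1e-4), ("AC4", 1e-3), ("AC5", 1e-2),
    ])
    def test_decay_and_area_methods_recover_truth(self, inp, baseline_subject,
                                                  method, tol):
        _, _, tr = baseline_subject
        est = estimate_ct(inp, r_t=tr["r_t"], p_out=tr["p_out"], z_0=tr["z_0"],
                          lvet=tr["lvet"], method=method)
        assert est.value == pytest.approx(tr["c_t"], rel=tol)

    def test_decay_method_bias_without_impedance_correction(self, inp, baseline_subject):
        # dividing tau by R_T instead of R_T - Z_0 biases C_T by -Z_0/R_T
        _, _, tr = baseline_subject
        est = estimate_ct(inp, r_t=tr["r_t"], p_out=tr["p_out"],
                          lvet=tr["lvet"], method="AC2")
        expected_bias = -tr["z_0"] / tr["r_t"]
        assert (est.value / tr["c_t"] - 1) == pytest.approx(expected_bias, rel=1e-2)

    @pytest.mark.parametrize("method", ["AC6", "AC7"])
    def test_pressure_matching_methods_invert_two_element_model(self, method):
        q, _ = __import__("cbpkit").generate_flow_wave(68.8, 88.4)
        params = WindkesselParams(0.51, 1.3, 0.0, 32.3)
        p = solve_2wk(q, params)
        st = wave_stats(p)
        inp2 = EstimatorInput(p_wave=p, q_wave=q, dbp=st.dbp, sbp=st.sbp)
        est = estimate_ct(inp2, r_t=0.51, p_out=32.3, lvet=0.293 * q.period,
                          method=method)
        assert est.value == pytest.approx(1.3, rel=1e-6)

    def test_stroke_volume_over_pulse_pressure(self):
        q, _ = __import__("cbpkit").generate_flow_wave(68.8, 88.4)
        inp8 = EstimatorInput(q_wave=q, dbp=64.6, sbp=64.6 + 52.9)
        est = estimate_ct(inp8, r_t=0.51, p_out=32.3, method="AC8")
        assert est.value == pytest.approx(88.4 / 52.9, rel=1e-3)

    def test_optimized_fit_method(self, inp, baseline_subject):
        _, _, tr = baseline_subject
        est = estimate_ct(inp, r_t=tr["r_t"], p_out=tr["p_out"], method="AC9")
        assert est.value == pytest.approx(tr["c_t"], rel=1e-3)

    def test_scale_equivariance(self, baseline_subject):
        # doubling all pressures (P_out included) at fixed flow halves C_T
        q, p, tr = baseline_subject
        p2 = UniformWave(p.t0, p.dt, 2 * p.values, "pressure")
        a = estimate_ct(EstimatorInput(p_wave=p, q_wave=q), r_t=tr["r_t"],
                        p_out=tr["p_out"], lvet=tr["lvet"], method="AC2").value
        b = estimate_ct(EstimatorInput(p_wave=p2, q_wave=q), r_t=2 * tr["r_t"],
                        p_out=2 * tr["p_out"], lvet=tr["lvet"], method="AC2").value
        assert b == pytest.approx(a / 2, rel=1e-6)


class TestPwv:
    def test_foot_to_foot_transit(self):
        q = half_sine_flow(peak=300, lvet=0.26, T=0.87)
        shifted = UniformWave(q.t0, q.dt, np.roll(q.values, 40), "flow")
        est = estimate_pwv(EstimatorInput(q_wave=q, q_distal=shifted, dx_aorta=0.2),
                           "PV1")
        assert est.value == pytest.approx(0.2 / 0.04, rel=1e-3)

    def test_least_squares_shift_recovery(self):
        q = half_sine_flow(peak=300, lvet=0.26, T=0.87)
        shifted = UniformWave(q.t0, q.dt, np.roll(q.values, 30), "flow")
        est = estimate_pwv(EstimatorInput(q_wave=q, q_distal=shifted, dx_aorta=0.15),
                           "PV3")
        assert est.value == pytest.approx(5.0, rel=1e-3)

    def test_pressure_pair_variant(self, baseline_subject):
        _, p, _ = baseline_subject
        shifted = UniformWave(p.t0, p.dt, np.roll(p.values, 35), "pressure")
        est = estimate_pwv(EstimatorInput(p_pair=(p, shifted), dx=0.35), "PV2")
        assert est.value == pytest.approx(0.35 / 0.035, rel=2e-2)

    def test_sum_of_squares_water_hammer(self):
        rho, c, area = 1060.0, 6.0, 5e-4
        q = half_sine_flow(peak=400, lvet=0.26, T=0.87)
        u = q.values * 1e-6 / area
        p = UniformWave(q.t0, q.dt, 80.0 + rho * c * u / 133.322, "pressure")
        est = estimate_pwv(EstimatorInput(p_wave=p, q_wave=q, area=area, rho=rho),
                           "PV5")
        assert est.value == pytest.approx(6.0, abs=0.01)

    def test_nonpositive_transit_rejected(self):
        q = half_sine_flow()
        with pytest.raises(NonPhysicalResultError):
            estimate_pwv(EstimatorInput(q_wave=q, q_distal=q, dx_aorta=0.2), "PV1")


class TestZ0:
    def test_fraction_of_resistance(self):
        assert estimate_z0(EstimatorInput(), r_t=0.70, method="Z3").value == \
            pytest.approx(0.035)

    def test_pressure_flow_amplitude_ratio(self):
        q = half_sine_flow(peak=450.0, lvet=0.3, T=1.0)
        inp = EstimatorInput(dbp=75.0, sbp=120.0, q_wave=q)
        est = estimate_z0(inp, method="Z4")
        mbp = 75 + 0.4 * 45
        assert est.value == pytest.approx((mbp - 75) / 450.0)

    def test_water_hammer_unit_conversion(self):
        est = estimate_z0(EstimatorInput(area=5e-4, rho=1060.0), pwv=5.0, method="Z5")
        assert est.diagnostics["z_si"] == pytest.approx(1.06e7)
        assert est.value == pytest.approx(0.0795, rel=1e-3)

    def test_frequency_method_near_truth(self, inp, baseline_subject):
        _, _, tr = baseline_subject
        est = estimate_z0(inp, method="Z1")
        assert est.value == pytest.approx(tr["z_0"], rel=0.3)

    def test_frequency_modulus_decreases_toward_z0(self, baseline_subject):
        from cbpkit.waveforms import harmonics
        q, p, tr = baseline_subject
        cp, cq = harmonics(p, 15), harmonics(q, 15)
        mods = np.array([abs(cp[k]) / abs(cq[k]) for k in range(2, 16)])
        assert np.all(np.diff(mods) < 0)
        assert mods[-1] == pytest.approx(tr["z_0"], rel=0.1)

    def test_pq_loop_slope_positive(self, inp):
        assert estimate_z0(inp, method="Z2").value > 0

    def test_optimized_fit_method(self, inp, baseline_subject):
        _, _, tr = baseline_subject
        est = estimate_z0_optimized(inp, r_t=tr["r_t"], p_out=tr["p_out"])
        assert est.value == pytest.approx(tr["z_0"], rel=1e-3)

    def test_scale_equivariance(self, baseline_subject):
        q, p, tr = baseline_subject
        p2 = UniformWave(p.t0, p.dt, 2 * p.values, "pressure")
        a = estimate_z0(EstimatorInput(p_wave=p, q_wave=q), method="Z1").value
        b = estimate_z0(EstimatorInput(p_wave=p2, q_wave=q), method="Z1").value
        assert b == pytest.approx(2 * a, rel=1e-9)
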