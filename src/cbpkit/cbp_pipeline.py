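"""Two-stage central blood pressure estimation.

Stage 1 estimates the cardiovascular parameters from the available clinical
inputs (an aortic flow wave plus either a peripheral pressure wave,
"carotid+", or only brachial DBP/SBP scalars, "carotid-"), running one
estimator per parameter in dependency order LVET -> P_out -> R_T -> C_T ->
PWV -> Z_0. Stage 2 feeds the parameters and the flow wave into the periodic
two- or three-element Windkessel model to simulate the central pressure wave.

The default method selections per scenario reproduce the published optima;
they are overridable, subject to scenario compatibility (wave-based methods
cannot run when only DBP/SBP scalars are available).

The module also builds outlet boundary parameters for an external 1-D
arterial-network solver (distributing the total resistance and compliance
over the outlets), ending at a validated config artifact; the 1-D solver
itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    EstimationStageError,
    NonPhysicalResultError,
)
from .cv_estimation import (
    EstimateResult,
    EstimatorInput,
    estimate_ct,
    estimate_lvet,
    estimate_pout,
    estimate_pwv,
    estimate_rt,
    estimate_z0,
    estimate_z0_optimized,
)
from .waveforms import (
    PA_S_PER_M3_TO_MMHG_S_PER_ML,
    UniformWave,
    wave_stats,
)
from .windkessel import SolveSettings, WindkesselParams, solve_2wk, solve_3wk

#: methods that need a full pressure wave and are thus carotid+ only
WAVE_ONLY_METHODS = frozenset(
    {"LV1", "LV2", "OP1", "OP2", "AR1", "AC1", "AC2", "AC3", "AC4", "AC5",
     "AC9", "Z1", "Z2", "Z6", "PV5"}
)


@dataclass(frozen=True)
class MethodSelection:
    """One estimation method code per CV parameter."""

    lvet: str = "LV4"
    p_out: str = "OP1"
    r_t: str = "AR1"
    c_t: str = "AC9"
    pwv: Optional[str] = "PV1"
    z_0: str = "Z2"

    def codes(self) -> Dict[str, Optional[str]]:
        return asdict(self)


#: published optimal selections per (dataset profile, scenario)
_SELECTION_TABLE = {
    ("0d", "carotid+"): MethodSelection("LV4", "OP1", "AR1", "AC2", None, "Z6"),
    ("0d", "carotid-"): MethodSelection("LV4", "OP3", "AR2", "AC7", None, "Z3"),
    ("1d", "carotid+"): MethodSelection("LV4", "OP1", "AR1", "AC9", "PV1", "Z2"),
    ("1d", "carotid-"): MethodSelection("LV4", "OP3", "AR2", "AC8", "PV1", "Z4"),
}


def select_methods(scenario: str, dataset_profile: str = "1d",
                   overrides: Optional[Dict[str, str]] = None) -> MethodSelection:
    """Optimal method selection for a clinical scenario.

    ``scenario`` is "carotid+" (peripheral pressure wave available) or
    "carotid-" (only DBP/SBP scalars). ``dataset_profile`` picks the row
    tuned on the lumped ("0d") or distributed ("1d") virtual dataset; the
    "1d" row is the default used on clinical data. ``overrides`` replaces
    individual codes, and every resulting method must be runnable under the
    scenario."""
    if scenario not in ("carotid+", "carotid-"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    key = (dataset_profile.lower(), scenario)
    if key not in _SELECTION_TABLE:
        raise ConfigurationError(f"unknown dataset profile {dataset_profile!r}")
    sel = _SELECTION_TABLE[key]
    if overrides:
        fields = sel.codes()
        for k, v in overrides.items():
            if k not in fields:
                raise ConfigurationError(f"unknown CV parameter {k!r} in override")
            fields[k] = v
        sel = MethodSelection(**fields)
    if scenario == "carotid-":
        for param, code in sel.codes().items():
            if code in WAVE_ONLY_METHODS:
                raise ConfigurationError(
                    f"method {code} for {param} needs a pressure wave, "
                    f"unavailable under carotid-"
                )
    return sel


def estimate_cv_params(inp: EstimatorInput, sel: MethodSelection) -> Dict[str, EstimateResult]:
    """Stage 1: run the selected estimators in dependency order.

    Returns a dict keyed by parameter name; each value carries its method
    code and diagnostics. When the compliance and impedance methods are both
    the optimized three-element fit (AC9 + Z6) the fit is run once and
    shared. Any estimator failure aborts with an error naming the stage."""
    results: Dict[str, EstimateResult] = {}

    def stage(name, fn):
        try:
            results[name] = fn()
        except Exception as exc:
            raise EstimationStageError(name, exc) from exc

    stage("lvet", lambda: estimate_lvet(inp, method=sel.lvet))
    lvet = results["lvet"].value
    stage("p_out", lambda: estimate_pout(inp, lvet=lvet, method=sel.p_out))
    p_out = results["p_out"].value
    stage("r_t", lambda: estimate_rt(inp, p_out=p_out, method=sel.r_t))
    r_t = results["r_t"].value

    shared_fit = sel.c_t == "AC9" and sel.z_0 == "Z6"
    stage("c_t", lambda: estimate_ct(
        inp, r_t=r_t, p_out=p_out, lvet=lvet, method=sel.c_t))
    if sel.pwv is not None:
        stage("pwv", lambda: estimate_pwv(inp, method=sel.pwv))
    pwv = results["pwv"].value if "pwv" in results else None

    if sel.z_0 == "Z6":
        if shared_fit:
            diag = results["c_t"].diagnostics
            results["z_0"] = EstimateResult(diag["z_0"], "Z6",
                                            {"c_t": results["c_t"].value,
                                             "rmse": diag["rmse"]})
        else:
            stage("z_0", lambda: estimate_z0_optimized(inp, r_t=r_t, p_out=p_out))
    else:
        stage("z_0", lambda: estimate_z0(inp, r_t=r_t, pwv=pwv, method=sel.z_0))
    return results


def estimate_cbp(q_in: UniformWave, params, model: str = "3wk") -> Dict:
    """Stage 2: simulate the central pressure wave from the aortic flow.

    ``params`` is a :class:`WindkesselParams`, or a mapping with keys
    r_t/c_t/z_0/p_out whose values are floats or :class:`EstimateResult`.
    Returns the periodic pressure wave plus its derived cDBP/cSBP/cMBP/cPP.
    """
    if not isinstance(params, WindkesselParams):
        def val(k, default=None):
            v = params.get(k, default)
            return v.value if isinstance(v, EstimateResult) else v
        params = WindkesselParams(
            r_t=val("r_t"), c_t=val("c_t"),
            z_0=val("z_0", 0.0) if model == "3wk" else 0.0,
            p_out=val("p_out"),
        )
    solver = solve_3wk if model == "3wk" else solve_2wk
    if model not in ("2wk", "3wk"):
        raise ConfigurationError(f"unknown model {model!r}")
    cbp = solver(q_in, params, SolveSettings(mode="periodic"))
    st = wave_stats(cbp)
    return {
        "cbp": cbp,
        "cdbp": st.dbp,
        "csbp": st.sbp,
        "cmbp": st.mbp,
        "cpp": st.pp,
        "params": params,
    }


def run_pipeline(inp: EstimatorInput, scenario: str, model: str = "3wk",
                 dataset_profile: str = "1d",
                 overrides: Optional[Dict[str, str]] = None) -> Dict:
    """Convenience wrapper: select methods, estimate parameters, simulate cBP."""
    sel = select_methods(scenario, dataset_profile, overrides)
    est = estimate_cv_params(inp, sel)
    out = estimate_cbp(inp.q_wave, est, model=model)
    out["estimates"] = est
    out["selection"] = sel
    return out


# ---------------------------------------------------------------------------
# outlet parameters for an external 1-D solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutletParams:
    """Windkessel outlet boundary parameters for a 1-D arterial model.

    Per outlet j: characteristic impedance z0_wk (mmHg.s/mL), peripheral
    resistance r_wk (mmHg.s/mL), compliance c_wk (mL/mmHg) and the outflow
    distribution fraction od. ``c_t_art`` is the compliance of the 1-D
    segments themselves (mL/mmHg), subtracted from the total before
    distribution."""

    z0_wk: List[float]
    r_wk: List[float]
    c_wk: List[float]
    od: List[float]
    c_t_art: float

    def to_config(self) -> Dict:
        return {
            "c_t_art_ml_per_mmhg": self.c_t_art,
            "outlets": [
                {"z0_wk": z, "r_wk": r, "c_wk": c, "od": o}
                for z, r, c, o in zip(self.z0_wk, self.r_wk, self.c_wk, self.od)
            ],
        }


def build_1d_outlet_params(q_mean_in: float, q_mean_out: float,
                           outlet_areas: Sequence[float],
                           r_t: float, c_t: float, p_out: float, pwv: float,
                           segments: Sequence[Dict[str, float]],
                           outlet_flows: Optional[Sequence[float]] = None,
                           rho: float = 1060.0) -> OutletParams:
    """Distribute total resistance and compliance over 1-D model outlets.

    Inputs mix units as they arise in practice: flows in mL/s, resistances
    and compliances in clinical units, geometry (areas m^2, lengths m),
    density kg/m^3 and PWV m/s in SI. Per outlet j with outflow fraction
    OD_j = Qbar_j / Qbar_in:

        Z0_j = rho PWV / A_j          (converted to mmHg.s/mL)
        R_j  = R_T / OD_j - Z0_j
        C_j  = (C_T - C_art) R_T / R_j

    where C_art = sum_k Abar_k L_k / (rho PWV^2) is the compliance stored in
    the 1-D segments themselves. When per-outlet flows are not measured, the
    inflow-outflow difference is split over the outlets proportionally to
    their areas.
    """
    areas = np.asarray(outlet_areas, dtype=float)
    if areas.size == 0 or np.any(areas <= 0):
        raise NonPhysicalResultError("outlet areas must be positive")
    if outlet_flows is not None:
        flows = np.asarray(outlet_flows, dtype=float)
        if flows.size != areas.size:
            raise ConfigurationError("outlet_flows length must match outlet_areas")
    else:
        if q_mean_in <= q_mean_out:
            raise NonPhysicalResultError(
                "area-based split needs mean inflow above mean outflow"
            )
        flows = (q_mean_in - q_mean_out) * areas / areas.sum()
    od = flows / q_mean_in
    if np.any(od <= 0):
        raise NonPhysicalResultError("every outflow fraction must be positive")
    if od.sum() > 1.0 + 1e-9:
        raise NonPhysicalResultError(f"outflow fractions sum to {od.sum():.3f} > 1")

    c_t_art_si = sum(seg["area"] * seg["length"] for seg in segments) / (rho * pwv ** 2)
    # m^3/Pa -> mL/mmHg: x 1e6 mL/m^3 x 133.322 Pa/mmHg
    c_t_art = c_t_art_si * 1e6 * 133.322
    if c_t_art >= c_t:
        raise NonPhysicalResultError(
            f"segment compliance {c_t_art:.3f} mL/mmHg >= total {c_t:.3f}"
        )
    z0 = rho * pwv / areas * PA_S_PER_M3_TO_MMHG_S_PER_ML
    r_wk = r_t / od - z0
    if np.any(r_wk <= 0):
        raise NonPhysicalResultError("a distributed outlet resistance came out <= 0")
    c_wk = (c_t - c_t_art) * r_t / r_wk
    return OutletParams(
        z0_wk=list(map(float, z0)),
        r_wk=list(map(float, r_wk)),
        c_wk=list(map(float, c_wk)),
        od=list(map(float, od)),
        c_t_art=float(c_t_art),
    )
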