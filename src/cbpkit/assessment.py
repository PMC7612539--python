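"""Error metrics and method-comparison statistics.

Conventions: percentage errors are 100 * (estimated - reference) / reference
with the reference in the denominator; the spread sigma is the sample
standard deviation (n-1) of the signed percentage errors; Bland-Altman
limits of agreement are bias +/- 1.96 SD of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IncomparableWavesError, InapplicableMethodError, CbpkitError
from .cv_estimation import (
    EstimatorInput,
    estimate_ct,
    estimate_lvet,
    estimate_pout,
    estimate_rt,
    estimate_z0,
    estimate_z0_optimized,
)
from .virtual_population import Dataset, VirtualSubject
from .waveforms import UniformWave, detect_foot, wave_stats


def mpe_sigma(est: Sequence[float], ref: Sequence[float]) -> Dict[str, float]:
    """Mean percentage error and its sample SD between paired estimates and
    references."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must have equal length")
    if np.any(ref == 0):
        raise ValueError("reference values must be nonzero for percentage errors")
    pe = 100.0 * (est - ref) / ref
    sigma = float(np.std(pe, ddof=1)) if pe.size > 1 else 0.0
    return {"mpe": float(np.mean(pe)), "sigma": sigma}


def bland_altman(est: Sequence[float], ref: Sequence[float]) -> Dict[str, float]:
    """Bias and 95% limits of agreement of paired differences est - ref."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must have equal length")
    if est.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(np.std(diff, ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def r_squared(est: Sequence[float], ref: Sequence[float]) -> float:
    """Squared Pearson correlation of paired values."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.std() == 0 or ref.std() == 0:
        raise ValueError("r_squared undefined for zero-variance input")
    return float(np.corrcoef(est, ref)[0, 1] ** 2)


def rmse_waves(est: UniformWave, ref: UniformWave, dt: float = 1e-3) -> float:
    """RMSE (mmHg) between two single-cycle pressure waves.

    The waves are aligned at their feet (clinical recordings share no clock),
    resampled onto a common grid spanning the shorter period, and compared
    pointwise. Periods differing by more than 10% are not comparable."""
    T1, T2 = est.period, ref.period
    if abs(T1 - T2) > 0.1 * min(T1, T2):
        raise IncomparableWavesError(
            f"wave periods differ by more than 10%: {T1:.3f} vs {T2:.3f} s"
        )
    T = min(T1, T2)
    n = max(2, int(round(T / dt)))
    tt = T / n * np.arange(n)
    ve = est.value_at(detect_foot(est) + tt)
    vr = ref.value_at(detect_foot(ref) + tt)
    return float(np.sqrt(np.mean((ve - vr) ** 2)))


@dataclass(frozen=True)
class ErrorReport:
    """One row of a method-assessment table."""

    label: str
    mpe: Optional[float] = None
    sigma: Optional[float] = None
    bias: Optional[float] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None
    rmse: Optional[float] = None
    r2: Optional[float] = None
    n: int = 0
    n_failed: int = 0

    def to_dict(self) -> Dict:
        return asdict(self)


#: which truth key each estimator family is compared against
_PARAM_TRUTH_KEY = {
    "lvet": "lvet", "p_out": "p_out", "r_t": "r_t", "c_t": "c_t", "z_0": "z_0",
}


def _run_estimator(param: str, code: str, subject: VirtualSubject,
                   ct_use_true_z0: bool = False) -> float:
    """Apply one estimator to a virtual subject, feeding true auxiliary
    parameters (the reference-style evaluation: each method is judged in
    isolation, with its other inputs taken from ground truth)."""
    tr = subject.truth
    inp = EstimatorInput(p_wave=subject.cbp, q_wave=subject.q_in)
    if param == "lvet":
        return estimate_lvet(inp, method=code).value
    if param == "p_out":
        return estimate_pout(inp, lvet=tr["lvet"], method=code).value
    if param == "r_t":
        return estimate_rt(inp, p_out=tr["p_out"], method=code).value
    if param == "c_t":
        z0 = tr["z_0"] if ct_use_true_z0 else None
        return estimate_ct(inp, r_t=tr["r_t"], p_out=tr["p_out"], z_0=z0,
                           lvet=tr["lvet"], method=code).value
    if param == "z_0":
        if code == "Z6":
            return estimate_z0_optimized(inp, r_t=tr["r_t"], p_out=tr["p_out"]).value
        return estimate_z0(inp, r_t=tr["r_t"], method=code).value
    raise InapplicableMethodError(f"unknown parameter {param!r}")


def evaluate_estimators(dataset: Dataset, methods: Dict[str, str],
                        subjects: Optional[Sequence[VirtualSubject]] = None,
                        ct_use_true_z0: bool = False) -> pd.DataFrame:
    """Per-method error table over a virtual population.

    ``methods`` maps parameter name (lvet, p_out, r_t, c_t, z_0) to a method
    code. Estimation failures are counted per method, never silently
    dropped. Returns a DataFrame with MPE, sigma, Bland-Altman bias/LoA and
    counts per method."""
    subs = list(subjects) if subjects is not None else dataset.retained
    rows = []
    for param, code in methods.items():
        key = _PARAM_TRUTH_KEY[param]
        est, ref = [], []
        n_failed = 0
        for s in subs:
            try:
                est.append(_run_estimator(param, code, s, ct_use_true_z0))
                ref.append(s.truth[key])
            except CbpkitError:
                n_failed += 1
        if len(est) >= 2:
            ms = mpe_sigma(est, ref)
            ba = bland_altman(est, ref)
            rows.append(ErrorReport(label=f"{param}:{code}", mpe=ms["mpe"],
                                    sigma=ms["sigma"], bias=ba["bias"],
                                    loa_low=ba["loa_low"], loa_high=ba["loa_high"],
                                    r2=None, n=len(est), n_failed=n_failed))
        else:
            rows.append(ErrorReport(label=f"{param}:{code}", n=len(est),
                                    n_failed=n_failed))
    if not rows:
        raise ValueError("empty evaluation: no methods given")
    return pd.DataFrame([r.to_dict() for r in rows])


def evaluate_pipeline(dataset: Dataset, pipeline: Callable[[VirtualSubject], Dict],
                      subjects: Optional[Sequence[VirtualSubject]] = None
                      ) -> pd.DataFrame:
    """Algorithm-level error table: run a cBP pipeline per subject and
    compare the simulated wave and its cDBP/cSBP to the subject's reference.

    ``pipeline`` maps a subject to the dict returned by
    :func:`cbpkit.cbp_pipeline.estimate_cbp`."""
    subs = list(subjects) if subjects is not None else dataset.retained
    if not subs:
        raise ValueError("empty dataset")
    recs = {"cdbp": ([], []), "csbp": ([], [])}
    rmses = []
    n_failed = 0
    for s in subs:
        try:
            out = pipeline(s)
        except CbpkitError:
            n_failed += 1
            continue
        ref_st = wave_stats(s.cbp)
        recs["cdbp"][0].append(out["cdbp"])
        recs["cdbp"][1].append(ref_st.dbp)
        recs["csbp"][0].append(out["csbp"])
        recs["csbp"][1].append(ref_st.sbp)
        rmses.append(rmse_waves(out["cbp"], s.cbp))
    rows = []
    for label, (est, ref) in recs.items():
        if len(est) >= 2:
            ba = bland_altman(est, ref)
            diffs = np.asarray(est) - np.asarray(ref)
            rows.append(ErrorReport(
                label=label, bias=ba["bias"], sigma=float(np.std(diffs, ddof=1)),
                loa_low=ba["loa_low"], loa_high=ba["loa_high"],
                r2=r_squared(est, ref) if np.std(ref) > 0 and np.std(est) > 0 else None,
                n=len(est), n_failed=n_failed))
    rows.append(ErrorReport(label="wave_rmse",
                            bias=float(np.mean(rmses)) if rmses else None,
                            sigma=float(np.std(rmses, ddof=1)) if len(rmses) > 1 else None,
                            n=len(rmses), n_failed=n_failed))
    return pd.DataFrame([r.to_dict() for r in rows])


def bland_altman_plot(est: Sequence[float], ref: Sequence[float], path) -> None:
    """Write a Bland-Altman scatter (mean vs difference) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ba = bland_altman(est, ref)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((est + ref) / 2, est - ref, s=8, alpha=0.5)
    for y, style in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of estimate and reference")
    ax.set_ylabel("estimate - reference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
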