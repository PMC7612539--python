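"""Virtual-subject generation: factorial grid, synthetic aortic flow waves,
and three-element Windkessel central pressure simulation.

A virtual subject is a set of six cardiovascular parameters — heart rate HR,
stroke volume SV, total resistance R_T, total compliance C_T, characteristic
impedance Z_0 and outflow pressure P_out — together with a synthetic aortic
root flow wave and the periodic three-element Windkessel pressure it drives.
Five levels per parameter (mu, mu +/- 0.5 sigma, mu +/- sigma) crossed over
all six parameters give the full factorial dataset of 5^6 = 15,625 subjects,
from which non-physiological pressures are excluded (strict bounds
cSBP > 220, cDBP < 44, cPP < 18 or cPP > 109 mmHg).

The default means and spreads target a healthy adult population; they are
approximate literature-scale values chosen once (see docs/methods.md) and
are fully configurable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from . import __version__ as _pkg_version
from .errors import ConfigurationError, InvalidPhysiologyError
from .waveforms import DEFAULT_DT, UniformWave, wave_stats
from .windkessel import SolveSettings, WindkesselParams, solve_3wk

#: canonical parameter ordering for the factorial grid
PARAM_ORDER: Tuple[str, ...] = ("hr", "sv", "r_t", "c_t", "z_0", "p_out")

#: grid level multipliers applied to sigma
LEVELS: Tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass(frozen=True)
class CVParameterSpec:
    """Mean and spread of each CV parameter, as (mu, sigma) pairs.

    Units: hr beats/min; sv mL; r_t and z_0 mmHg.s/mL; c_t mL/mmHg;
    p_out mmHg. Grid levels are mu + {-1, -0.5, 0, 0.5, 1} * sigma, so the
    dataset-level SD of each parameter is sigma * sqrt(0.5).
    """

    hr: Tuple[float, float] = (68.8, 16.0)
    sv: Tuple[float, float] = (88.4, 17.3)
    r_t: Tuple[float, float] = (0.51, 0.12)
    c_t: Tuple[float, float] = (1.3, 0.4)
    z_0: Tuple[float, float] = (0.0255, 0.008)
    p_out: Tuple[float, float] = (32.3, 8.0)

    def __post_init__(self):
        for name in PARAM_ORDER:
            mu, sigma = getattr(self, name)
            if sigma < 0:
                raise ConfigurationError(f"sigma for {name} must be >= 0, got {sigma}")
            if mu <= 0:
                raise ConfigurationError(f"mu for {name} must be positive, got {mu}")

    def levels(self, name: str) -> np.ndarray:
        mu, sigma = getattr(self, name)
        return mu + sigma * np.asarray(LEVELS)

    def to_dict(self) -> Dict[str, Tuple[float, float]]:
        return {name: tuple(getattr(self, name)) for name in PARAM_ORDER}


@dataclass(frozen=True)
class FlowShape:
    """Shape settings of the synthetic aortic flow wave.

    The ejection profile is Q(t) = Q_max * sin(pi * (t/LVET)^skew)^m on
    [0, LVET] and zero in diastole; ``skew`` > 1 moves the peak towards late
    systole. Q_max is scaled so that the trapezoidal cycle integral equals SV
    exactly. LVET = k_lvet * T; the default systolic fraction 0.293 places
    flow-independent LVET estimators at their documented biases.
    """

    dt: float = DEFAULT_DT
    k_lvet: float = 0.293
    m: float = 1.0
    skew: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.m <= 0 or self.skew <= 0:
            raise ConfigurationError("dt, m and skew must be positive")
        if not (0 < self.k_lvet < 1):
            raise ConfigurationError("k_lvet must be in (0, 1)")


@dataclass(frozen=True)
class ExclusionBounds:
    """Physiological bounds on the simulated central pressure (mmHg).

    Violations are strict inequalities: a subject sitting exactly on a bound
    is retained.
    """

    csbp_max: float = 220.0
    cdbp_min: float = 44.0
    cpp_min: float = 18.0
    cpp_max: float = 109.0


@dataclass
class VirtualSubject:
    """One generated subject: ground truth, flow wave, simulated cBP wave."""

    id: int
    truth: Dict[str, float]
    q_in: UniformWave
    cbp: Optional[UniformWave] = None
    excluded: bool = False
    exclusion_reasons: List[str] = field(default_factory=list)


@dataclass
class Dataset:
    """A generated virtual population plus its provenance manifest."""

    subjects: List[VirtualSubject]
    manifest: Dict

    @property
    def retained(self) -> List[VirtualSubject]:
        return [s for s in self.subjects if not s.excluded]


def generate_flow_wave(hr: float, sv: float,
                       shape: FlowShape = FlowShape()) -> Tuple[UniformWave, float]:
    """Synthetic single-cycle aortic root flow wave for a given heart rate
    (beats/min) and stroke volume (mL).

    Returns the flow wave and the ejection time LVET (s). The realised
    sampling interval is T / round(T / dt) so the cycle length is exact.
    """
    if not (30.0 <= hr <= 200.0):
        raise InvalidPhysiologyError(f"HR {hr} outside [30, 200] beats/min")
    if not (10.0 <= sv <= 200.0):
        raise InvalidPhysiologyError(f"SV {sv} outside [10, 200] mL")
    T = 60.0 / hr
    lvet = shape.k_lvet * T
    if lvet >= T:
        raise InvalidPhysiologyError(f"LVET {lvet} >= cycle duration {T}")
    n = max(64, int(round(T / shape.dt)))
    dt = T / n
    t = dt * np.arange(n)
    u = t / lvet
    profile = np.zeros(n)
    sys_mask = u < 1.0
    profile[sys_mask] = np.sin(np.pi * u[sys_mask] ** shape.skew) ** shape.m
    integral = dt * profile.sum()  # periodic trapezoid = plain sum * dt
    if integral <= 0:
        raise InvalidPhysiologyError("flow profile has zero integral")
    q = UniformWave(0.0, dt, profile * (sv / integral), "flow")
    return q, lvet


def build_grid(spec: CVParameterSpec = CVParameterSpec()) -> List[Dict[str, float]]:
    """Full factorial crossing of the five levels of each of the six
    parameters, in deterministic order (lexicographic by parameter, then
    level, with the last parameter varying fastest)."""
    level_sets = []
    for name in PARAM_ORDER:
        vals = spec.levels(name)
        bad = vals <= 0 if name != "z_0" else vals < 0
        if np.any(bad):
            raise ConfigurationError(
                f"grid for {name!r} contains non-positive value {vals[bad][0]:.4g}"
            )
        level_sets.append(vals)
    return [
        dict(zip(PARAM_ORDER, combo))
        for combo in itertools.product(*level_sets)
    ]


def apply_exclusions(subjects: Iterable[VirtualSubject],
                     bounds: ExclusionBounds = ExclusionBounds()) -> List[VirtualSubject]:
    """Flag subjects whose simulated central pressure violates any bound.

    Bounds are strict inequalities, evaluated on the simulated cBP wave.
    Returns the same subject objects with ``excluded``/``exclusion_reasons``
    set."""
    out = []
    for s in subjects:
        reasons = []
        if s.cbp is not None:
            st = wave_stats(s.cbp)
            if st.sbp > bounds.csbp_max:
                reasons.append(f"cSBP {st.sbp:.1f} > {bounds.csbp_max:g}")
            if st.dbp < bounds.cdbp_min:
                reasons.append(f"cDBP {st.dbp:.1f} < {bounds.cdbp_min:g}")
            if st.pp < bounds.cpp_min:
                reasons.append(f"cPP {st.pp:.1f} < {bounds.cpp_min:g}")
            if st.pp > bounds.cpp_max:
                reasons.append(f"cPP {st.pp:.1f} > {bounds.cpp_max:g}")
        s.excluded = bool(reasons)
        s.exclusion_reasons = reasons
        out.append(s)
    return out


def make_subject(idx: int, combo: Dict[str, float],
                 shape: FlowShape = FlowShape()) -> VirtualSubject:
    """Generate one subject: flow wave plus periodic 3-element pressure."""
    q, lvet = generate_flow_wave(combo["hr"], combo["sv"], shape)
    params = WindkesselParams(
        r_t=combo["r_t"], c_t=combo["c_t"], z_0=combo["z_0"], p_out=combo["p_out"]
    )
    cbp = solve_3wk(q, params, SolveSettings(mode="periodic"))
    truth = dict(combo)
    truth["lvet"] = lvet
    truth["period"] = q.period
    return VirtualSubject(id=idx, truth=truth, q_in=q, cbp=cbp)


def generate_dataset(spec: CVParameterSpec = CVParameterSpec(),
                     shape: FlowShape = FlowShape(),
                     bounds: ExclusionBounds = ExclusionBounds(),
                     limit: Optional[int] = None,
                     progress: bool = False) -> Dataset:
    """Generate the full factorial virtual population.

    ``limit`` truncates the grid (first N combinations) for quick runs. The
    manifest records the spec, shape and bounds settings, the counts and the
    package version; regeneration with identical settings yields an identical
    manifest hash. Generation is fully deterministic (no randomness).
    """
    grid = build_grid(spec)
    if limit is not None:
        grid = grid[:limit]
    iterator = enumerate(grid)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(list(iterator), desc="subjects")
        except ImportError:
            pass
    subjects = []
    n_failed = 0
    for idx, combo in iterator:
        try:
            subjects.append(make_subject(idx, combo, shape))
        except InvalidPhysiologyError as exc:
            n_failed += 1
            s = VirtualSubject(id=idx, truth=dict(combo), q_in=None)  # type: ignore
            s.excluded = True
            s.exclusion_reasons = [f"generation failed: {exc}"]
            subjects.append(s)
    apply_exclusions([s for s in subjects if s.cbp is not None], bounds)
    manifest = _manifest(spec, shape, bounds, limit, subjects, n_failed)
    return Dataset(subjects=subjects, manifest=manifest)


def _manifest(spec, shape, bounds, limit, subjects, n_failed) -> Dict:
    settings = {
        "spec": spec.to_dict(),
        "shape": asdict(shape),
        "bounds": asdict(bounds),
        "limit": limit,
    }
    counts = {
        "n_subjects": len(subjects),
        "n_excluded": sum(s.excluded for s in subjects),
        "n_failed": n_failed,
    }
    payload = json.dumps({"settings": settings, "counts": counts}, sort_keys=True)
    return {
        "settings": settings,
        "counts": counts,
        "version": _pkg_version,
        "hash": hashlib.sha256(payload.encode()).hexdigest(),
    }
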