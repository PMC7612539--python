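import numpy as np
import pytest
from hypothesis import settings

from cbpkit import (
    UniformWave,
    WindkesselParams,
    generate_dataset,
    generate_flow_wave,
    solve_3wk,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: baseline (grid-centre) subject parameters
BASELINE = dict(hr=68.8, sv=88.4, r_t=0.51, c_t=1.3, z_0=0.0255, p_out=32.3)


@pytest.fixture(scope="session")
def baseline_subject():
    """Flow wave, truth dict and simulated central pressure at the grid centre."""
    q, lvet = generate_flow_wave(BASELINE["hr"], BASELINE["sv"])
    params = WindkesselParams(
        r_t=BASELINE["r_t"], c_t=BASELINE["c_t"],
        z_0=BASELINE["z_0"], p_out=BASELINE["p_out"],
    )
    p = solve_3wk(q, params)
    truth = dict(BASELINE, lvet=lvet, period=q.period)
    return q, p, truth


@pytest.fixture(scope="session")
def small_dataset():
    """First 150 subjects of the default factorial grid (deterministic)."""
    return generate_dataset(limit=150)


def half_sine_flow(peak=100.0, lvet=0.3, T=1.0, dt=1e-3):
    """Half-sine systolic inflow, zero diastole (no SV normalisation)."""
    n = int(round(T / dt))
    t = dt * np.arange(n)
    v = np.where(t < lvet, peak * np.sin(np.pi * np.minimum(t / lvet, 1.0)), 0.0)
    return UniformWave(0.0, dt, v, "flow")
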