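"""Shared fixtures: expensive simulations and rendered movies, built once."""

from __future__ import annotations

import numpy as np
import pytest

from mpresolve.mp_detection import detect_frame, detect_movie
from mpresolve.synthetic_imaging import (ImagingConfig, render_benchmark,
                                         simulate_then_render)
from mpresolve.vesicle_model import make_scenario, simulate


@pytest.fixture(scope="session")
def wt_trajectory():
    return simulate(make_scenario("WT"))


@pytest.fixture(scope="session")
def scenario_endpoints():
    """End-state (volume fraction, pH) for every named intervention preset."""
    out = {}
    for name, overrides in [
        ("WT", None),
        ("WT_ASOR_x10", {"g_ASOR": 2000.0}),
        ("TMEM206_KO", None),
        ("low_luminal_Cl", None),
        ("low_luminal_Cl_KO", None),
        ("bafilomycin", None),
        ("TMEM206_KO_baf", None),
        ("R87C", None),
        ("gating_removed", None),
        ("CLC_only", None),
        ("NH4Cl", None),
    ]:
        base = {"WT_ASOR_x10": "WT",
                "low_luminal_Cl_KO": "low_luminal_Cl",
                "TMEM206_KO_baf": "TMEM206_KO"}.get(name, name)
        if name == "low_luminal_Cl_KO":
            overrides = {"g_ASOR": 0.0}
        elif name == "TMEM206_KO_baf":
            overrides = {"J_pump_max": 0.0}
        tr = simulate(make_scenario(base, param_overrides=overrides))
        out[name] = (float(tr.volume_fraction[-1]), float(tr.pH[-1]))
    return out


@pytest.fixture(scope="session")
def benchmark_frame():
    """Single-frame 20-vesicle SNR-5 benchmark plus its detections."""
    tl, truth, config = render_benchmark(20, 5.0, seed=7)
    detections = detect_frame(tl.data[0])
    return tl, truth, config, detections


@pytest.fixture(scope="session")
def wt_movie():
    """11-frame WT simulate-then-render movie with detections and truth."""
    config = ImagingConfig(shape=(300, 300), n_frames=11, rng_seed=5,
                           background_level=100.0, cell_cytoplasm_level=100.0)
    tl, truth, traj = simulate_then_render(
        make_scenario("WT"), config, n_vesicles=28, r0_px=16.0, snr=8.0)
    detections = detect_movie(tl.data)
    return tl, truth, traj, detections


@pytest.fixture(scope="session")
def noise_free_config():
    return ImagingConfig(shape=(160, 160), n_frames=1, rng_seed=0,
                         background_level=0.0, cell_cytoplasm_level=0.0,
                         poisson_gain=0.0, read_noise_sd=0.0)
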