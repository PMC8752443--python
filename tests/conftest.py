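"""Shared fixtures.

The heavy reduced-scale run ensembles are produced once per session and
shared between the module property tests and the acceptance tests; every
ensemble is fully seeded, so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from voxclone import (
    SimulationConfig,
    composition,
    default_panel,
    detectable_clones,
    run_surviving,
)
from voxclone.spatial_analysis import (
    hotspots_and_distances,
    make_slice,
    microdiversity_map,
)
from voxclone.temporal_analysis import time_course

# reduced-scale study conditions (saturated s = 1 via AdvantageModel defaults)
REDUCED = dict(L=60, stop_size=20_000, max_steps=5000, p_driver=6e-4)
NECROSIS_SCALE = dict(L=96, stop_size=100_000, max_steps=5000, p_driver=6e-4)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def pooled_plane_hotspot_distances(state, min_clones: int = 5) -> list[float]:
    """Hotspot normalised distances pooled over every z-plane of a run.

    At reduced tumour sizes a single central slice rarely holds a hotspot,
    so the desk-scale protocol treats every plane as an observation slice."""
    L = state.L
    lab3 = state.clone.reshape(L, L, L)
    ds: list[float] = []
    for z in range(L):
        plane = lab3[:, :, z]
        if (plane >= 0).sum() < 9:
            continue
        sl = make_slice(plane, registry=state.registry, panel=state.panel, z0=z)
        for h in hotspots_and_distances(microdiversity_map(sl), sl, min_clones):
            ds.append(h.d)
    return ds


@pytest.fixture(scope="session")
def paired_ensemble():
    """20 paired reduced runs per growth mode (seeds 0..19, p_driver 6e-4,
    saturated s = 1): detectable counts, pooled hotspot distances, run
    lengths and slice time-courses."""
    out = {}
    for mode in ("surface", "volume"):
        runs = []
        for seed in range(20):
            cfg = SimulationConfig(
                growth_mode=mode, seed=seed, snapshot_every=15, **REDUCED
            )
            state, snaps = run_surviving(cfg)
            tc = time_course(snaps)
            runs.append(
                {
                    "seed": seed,
                    "steps": state.step_count,
                    "n_detectable": len(detectable_clones(composition(state))),
                    "max_detectable_tc": int(tc["n_subclones"].max()),
                    "mean_drivers_series": tc["mean_drivers"].to_numpy(),
                    "slice_area_series": tc["slice_area_mm2"].to_numpy(),
                    "d_values": pooled_plane_hotspot_distances(state),
                }
            )
        out[mode] = runs
    return out


@pytest.fixture(scope="session")
def necrosis_ensemble():
    """10 paired Surface-Growth runs with and without necrosis at a scale
    where the necrotic core (depth > 15 mm) is active for most of the run."""
    from voxclone.spatial_analysis import extract_slice, fitness_gradient

    out = {}
    for nec in (False, True):
        central = []
        for seed in range(10):
            cfg = SimulationConfig(
                growth_mode="surface", seed=seed, necrosis_enabled=nec,
                **NECROSIS_SCALE,
            )
            state, _ = run_surviving(cfg)
            fg = fitness_gradient(extract_slice(state), seed=seed)
            central.append(fg.central_mean)
        out[nec] = np.array(central)
    return out


@pytest.fixture(scope="session")
def growth_law_ensemble():
    """Driver-free reduced runs (10 seeds per mode) for growth-law fits."""
    out = {}
    for mode in ("surface", "volume"):
        series = []
        for seed in range(10):
            cfg = SimulationConfig(
                growth_mode=mode, seed=seed,
                L=60, stop_size=20_000, max_steps=5000, p_driver=0.0,
            )
            state, _ = run_surviving(cfg)
            series.append(np.array([r["n_voxels"] for r in state.step_log], float))
        out[mode] = series
    return out


def linear_fit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R² of y on x."""
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
    return float(coef[0]), float(r2)
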