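"""Time-course statistics over snapshot series.

Per-snapshot slice metrics (equivalent diameter, detectable subclone count,
mean driver burden, mean fitness, circularity), Gaussian-kernel density of
(diameter, subclone count) points across runs, evolutionary flow fields in
the (subclone count, mean drivers) plane, and replay-divergence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clonal_accounting import (
    composition,
    detectable_clones,
    mean_drivers,
    shannon_index,
    tumour_fitness,
)
from .engine import LatticeState, Snapshot
from .spatial_analysis import circularity, make_slice


def slice_equivalent_diameter_mm(area_mm2: float) -> float:
    """Diameter of a circle with the slice's area: 2·sqrt(A/π)."""
    return float(2.0 * np.sqrt(area_mm2 / np.pi))


def _snapshot_slice(snap: Snapshot, z: int | None = None):
    from .engine import CloneRegistry

    L = snap.config.L
    z0 = L // 2 if z is None else z
    in_plane = snap.z == z0
    labels2d = np.full((L, L), -1, dtype=np.int32)
    birth2d = np.full((L, L), -1, dtype=np.int32)
    labels2d[snap.x[in_plane], snap.y[in_plane]] = snap.clone_id[in_plane]
    birth2d[snap.x[in_plane], snap.y[in_plane]] = snap.birth_step[in_plane]
    from .driver_panel import default_panel

    panel = default_panel()
    registry = CloneRegistry.from_records(snap.registry_records, panel, snap.config)
    return make_slice(labels2d, birth2d, z0=z0, registry=registry, panel=panel)


def time_course(
    snapshots: list[Snapshot],
    z: int | None = None,
    detect_threshold: float = 0.01,
) -> pd.DataFrame:
    """Slice-level metrics for every snapshot of a run.

    Columns: step, n_voxels (whole tumour), slice_area_mm2, diameter_mm,
    n_subclones (detectable on the slice), mean_drivers, mean_fitness,
    shannon, circularity (NaN for degenerate contours).  Driver burden is
    non-decreasing over time because drivers are never lost."""
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    rows = []
    for snap in snapshots:
        try:
            sl = _snapshot_slice(snap, z)
        except ValueError:
            # a very small tumour can momentarily vacate the analysis plane
            continue
        comp = composition(sl.occupied_labels(), scope="slice")
        try:
            circ = circularity(sl)
        except ValueError:
            circ = np.nan
        rows.append(
            {
                "step": snap.step,
                "n_voxels": snap.n_voxels,
                "slice_area_mm2": sl.area_mm2,
                "diameter_mm": slice_equivalent_diameter_mm(sl.area_mm2),
                "n_subclones": len(detectable_clones(comp, detect_threshold)),
                "mean_drivers": mean_drivers(sl.occupied_labels(), sl.registry),
                "mean_fitness": tumour_fitness(sl.occupied_labels(), sl.registry),
                "shannon": shannon_index(comp),
                "circularity": circ,
            }
        )
    df = pd.DataFrame(rows).sort_values("step").reset_index(drop=True)
    return df


# ----------------------------------------------------------------------
# kernel density estimation
# ----------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Gaussian-KDE density over the (diameter, subclone count) plane."""

    xx: np.ndarray
    yy: np.ndarray
    density: np.ndarray
    level_90: float  # density threshold whose superlevel set holds 90% mass

    def mass_above(self, level: float) -> float:
        cell = (self.xx[0, 1] - self.xx[0, 0]) * (self.yy[1, 0] - self.yy[0, 0])
        return float(self.density[self.density >= level].sum() * cell)


def kde_diversity_size(
    diameters: np.ndarray,
    counts: np.ndarray,
    bandwidth: str | float = "scott",
    gridsize: int = 128,
    pad_factor: float = 0.25,
) -> DensityGrid:
    """Gaussian-kernel density of (slice diameter, subclone count) points.

    Returns the evaluated grid and the density level whose superlevel set
    encloses 90% of the probability mass (the '90% probability contour')."""
    x = np.asarray(diameters, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 points for a density estimate")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate input: all points identical")
    # a singular covariance (constant or collinear axes) gets a minuscule
    # deterministic jitter so the Gaussian kernel stays well defined
    cov = np.cov(np.vstack([x, y]))
    if np.linalg.det(cov) <= 1e-12 * (cov[0, 0] * cov[1, 1] + 1e-300):
        jit = np.random.Generator(np.random.PCG64(0))
        x = x + jit.normal(0, max(np.ptp(x), 1.0) * 1e-6, len(x))
        y = y + jit.normal(0, max(np.ptp(y), 1.0) * 1e-6, len(y))
    kde = stats.gaussian_kde(np.vstack([x, y]), bw_method=bandwidth)
    px = pad_factor * max(np.ptp(x), 1.0)
    py = pad_factor * max(np.ptp(y), 1.0)
    gx = np.linspace(x.min() - px, x.max() + px, gridsize)
    gy = np.linspace(y.min() - py, y.max() + py, gridsize)
    xx, yy = np.meshgrid(gx, gy)
    zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    order = np.sort(zz.ravel())[::-1]
    cum = np.cumsum(order) * cell
    total = cum[-1]
    k = int(np.searchsorted(cum, 0.9 * total))
    level = float(order[min(k, len(order) - 1)])
    return DensityGrid(xx=xx, yy=yy, density=zz, level_90=level)


# ----------------------------------------------------------------------
# evolutionary flow fields
# ----------------------------------------------------------------------

@dataclass
class FlowField:
    """Mean per-step displacement in (subclone count, mean drivers) space."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    u: np.ndarray  # mean displacement along subclone-count axis (masked = nan)
    v: np.ndarray  # mean displacement along mean-drivers axis
    counts: np.ndarray
    min_observations: int


def flow_field(
    trajectories: list[pd.DataFrame],
    x_col: str = "n_subclones",
    y_col: str = "mean_drivers",
    bins: int | tuple = 10,
    min_observations: int = 3,
) -> FlowField:
    """Bin consecutive-snapshot displacements of many runs into a vector map.

    Each trajectory contributes (Δx, Δy) vectors anchored at the earlier
    point; bins with fewer than ``min_observations`` vectors are masked
    (NaN).  The mean-drivers component is non-negative in every populated
    bin because drivers are never lost."""
    xs, ys, us, vs = [], [], [], []
    for tr in trajectories:
        if len(tr) < 2:
            continue
        x = tr[x_col].to_numpy(dtype=float)
        y = tr[y_col].to_numpy(dtype=float)
        xs.append(x[:-1])
        ys.append(y[:-1])
        us.append(np.diff(x))
        vs.append(np.diff(y))
    if not xs:
        raise ValueError("need at least one trajectory with >= 2 points")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    if isinstance(bins, int):
        x_edges = np.linspace(x.min(), x.max() + 1e-9, bins + 1)
        y_edges = np.linspace(y.min(), y.max() + 1e-9, bins + 1)
    else:
        x_edges, y_edges = bins
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    sum_u, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=u)
    sum_v, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=v)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(counts >= min_observations, sum_u / counts, np.nan)
        mv = np.where(counts >= min_observations, sum_v / counts, np.nan)
    return FlowField(
        x_edges=x_edges,
        y_edges=y_edges,
        u=mu,
        v=mv,
        counts=counts.astype(int),
        min_observations=min_observations,
    )


# ----------------------------------------------------------------------
# replay divergence
# ----------------------------------------------------------------------

def _genotype_distribution(state: LatticeState) -> dict[int, float]:
    """Clone-frequency distribution keyed by driver-set genotype bits.

    Parallel events hitting the same genes collapse onto the same key, so
    replicates that reach the same driver composition by different alleles
    compare as equivalent outcomes."""
    comp = composition(state)
    dist: dict[int, float] = {}
    for cid, f in zip(comp.clone_ids, comp.ccf):
        key = state.registry.genotype_bits[int(cid)]
        dist[key] = dist.get(key, 0.0) + float(f)
    return dist


def jensen_shannon(p: dict, q: dict) -> float:
    """Jensen–Shannon divergence (natural log; maximal value ln 2)."""
    keys = sorted(set(p) | set(q), key=str)
    pv = np.array([p.get(k, 0.0) for k in keys])
    qv = np.array([q.get(k, 0.0) for k in keys])
    pv = pv / pv.sum()
    qv = qv / qv.sum()
    m = 0.5 * (pv + qv)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * _kl(pv, m) + 0.5 * _kl(qv, m)


@dataclass
class ReplayDivergence:
    """Pairwise divergence of replicate outcomes; lower = more repeatable."""

    matrix: np.ndarray
    mean_pairwise: float


def replay_divergence(replicates: list[LatticeState]) -> ReplayDivergence:
    """Pairwise Jensen–Shannon divergence between the final clone-frequency
    distributions of replay replicates, keyed by driver-set genotype."""
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates")
    dists = [_genotype_distribution(s) for s in replicates]
    n = len(dists)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jensen_shannon(dists[i], dists[j])
    iu = np.triu_indices(n, k=1)
    return ReplayDivergence(matrix=mat, mean_pairwise=float(mat[iu].mean()))
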