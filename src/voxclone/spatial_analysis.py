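"""Spatial analyses on 2D tumour slices.

Covers slice extraction with Moore contour tracing and smoothing, spatially
uniform biopsy sampling, microdiversity mapping with a sliding 3×3 mm²
window, hotspot normalised-distance statistics and bootstrap power-law
fitting of their cumulative distribution, spatial homogenisation controls,
youngest-subclone distances, contour circularity, and centre-vs-margin
fitness gradients.

Distances use the slice centroid as the tumour centre and the traced outer
contour as the margin.  The normalised hotspot distance is
``d = d1/(d1+d2)`` with ``d1`` the distance to the centre and ``d2`` the
distance to the nearest contour point; for locations uniform in a disc the
cumulative law is P(D ≤ d) = d², i.e. a power-law exponent of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .driver_panel import AdvantageModel, DriverPanel
from .engine import CloneRegistry, LatticeState

# clockwise Moore neighbourhood starting from west (row, col)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


# ----------------------------------------------------------------------
# slices and contours
# ----------------------------------------------------------------------

@dataclass
class TumourSlice:
    """All tumour voxels in the plane z = z0, with traced contour."""

    z0: int
    occ2d: np.ndarray  # (L, L) bool
    labels2d: np.ndarray  # (L, L) int32, -1 empty
    birth2d: np.ndarray  # (L, L) int32, -1 empty
    centroid: tuple[float, float]
    contour_raw: np.ndarray  # (M, 2) int, ordered boundary sites
    contour_smooth: np.ndarray  # (M, 2) float
    registry: CloneRegistry | None = None
    panel: DriverPanel | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.occ2d.sum())

    @property
    def area_mm2(self) -> float:
        """Occupied-site count; each site is 1 mm²."""
        return float(self.occ2d.sum())

    def occupied_coords(self) -> np.ndarray:
        return np.argwhere(self.occ2d)

    def occupied_labels(self) -> np.ndarray:
        return self.labels2d[self.occ2d]

    def perimeter_mm(self) -> float:
        """Closed polyline length of the smoothed contour."""
        pts = self.contour_smooth
        if len(pts) < 2:
            return 0.0
        closed = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def _largest_component(occ2d: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(occ2d, structure=np.ones((3, 3), int))
    if n <= 1:
        return occ2d
    sizes = ndimage.sum(occ2d, lab, index=range(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def trace_contour(occ2d: np.ndarray) -> np.ndarray:
    """Ordered outer boundary of the largest connected component.

    Moore boundary following on 8-connectivity; every returned point is an
    occupied site with at least one empty 8-neighbour.  A single occupied
    site yields a one-point contour."""
    mask = _largest_component(occ2d.astype(bool))
    pts = np.argwhere(mask)
    if len(pts) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    if len(pts) == 1:
        return pts.astype(np.int64)
    pad = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask
    r0, c0 = pts[0] + 1  # first in scan order: all earlier sites empty
    start = (int(r0), int(c0))
    b_init = (start[0], start[1] - 1)
    contour = [start]
    p, b = start, b_init
    guard = 4 * pad.size
    while guard > 0:
        guard -= 1
        i = _MOORE.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(i + k) % 8]
            q = (p[0] + dr, p[1] + dc)
            if pad[q]:
                nxt = q
                pr, pc = _MOORE[(i + k - 1) % 8]
                b = (p[0] + pr, p[1] + pc)
                break
        if nxt is None:  # isolated pixel
            break
        p = nxt
        if p == start and b == b_init:
            break
        contour.append(p)
    return np.array(contour, dtype=np.int64) - 1


def smooth_contour(contour: np.ndarray, window: int = 5) -> np.ndarray:
    """Cyclic moving average of the contour point sequence.

    Each point is replaced by the mean position of itself and its
    ``(window-1)//2`` neighbours on either side along the contour; the point
    count is preserved.  The default window suppresses the lattice staircase
    so that a digital disc's smoothed perimeter approaches 2πr."""
    m = len(contour)
    if m <= 2:
        return contour.astype(float)
    half = min((window - 1) // 2, (m - 1) // 2)
    out = np.empty((m, 2), dtype=float)
    idx = np.arange(-half, half + 1)
    for i in range(m):
        out[i] = contour[(i + idx) % m].mean(axis=0)
    return out


def make_slice(
    labels2d: np.ndarray,
    birth2d: np.ndarray | None = None,
    z0: int = 0,
    registry: CloneRegistry | None = None,
    panel: DriverPanel | None = None,
    smooth_window: int = 5,
) -> TumourSlice:
    """Build a TumourSlice from a 2D label field (-1 = empty)."""
    labels2d = np.asarray(labels2d, dtype=np.int32)
    occ = labels2d >= 0
    if not occ.any():
        raise ValueError("slice plane contains no tumour voxels")
    if birth2d is None:
        birth2d = np.where(occ, 0, -1).astype(np.int32)
    coords = np.argwhere(occ)
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    raw = trace_contour(occ)
    return TumourSlice(
        z0=z0,
        occ2d=occ,
        labels2d=labels2d,
        birth2d=np.asarray(birth2d, dtype=np.int32),
        centroid=centroid,
        contour_raw=raw,
        contour_smooth=smooth_contour(raw, smooth_window),
        registry=registry,
        panel=panel,
    )


def extract_slice(state: LatticeState, z: int | None = None) -> TumourSlice:
    """The tumour slice at plane z (default: the central plane z0)."""
    L = state.L
    z0 = L // 2 if z is None else int(z)
    labels2d = state.clone.reshape(L, L, L)[:, :, z0]
    birth2d = state.birth.reshape(L, L, L)[:, :, z0]
    return make_slice(
        labels2d, birth2d, z0=z0, registry=state.registry, panel=state.panel
    )


def circularity(sl: TumourSlice) -> float:
    """Isoperimetric contour circularity, 4π·Area/Perimeter².

    Equals 1 for a circle and decreases as the contour grows lobes or
    elongates.  Area is the occupied-site count (mm²), the perimeter the
    smoothed-contour length (mm)."""
    if len(sl.contour_raw) < 3:
        raise ValueError("degenerate contour: fewer than 3 contour points")
    per = sl.perimeter_mm()
    if per <= 0:
        raise ValueError("degenerate contour: zero perimeter")
    return float(4.0 * np.pi * sl.area_mm2 / per**2)


def homogenise(sl: TumourSlice, seed: int) -> TumourSlice:
    """Spatial homogenisation control: permute clone labels uniformly at
    random across occupied sites.  The label multiset (hence the clonal
    composition) and the geometry are preserved exactly."""
    rng = np.random.Generator(np.random.PCG64(seed))
    labels = sl.labels2d.copy()
    occ_idx = np.argwhere(sl.occ2d)
    vals = labels[sl.occ2d]
    labels[occ_idx[:, 0], occ_idx[:, 1]] = rng.permutation(vals)
    return TumourSlice(
        z0=sl.z0,
        occ2d=sl.occ2d.copy(),
        labels2d=labels,
        birth2d=sl.birth2d.copy(),
        centroid=sl.centroid,
        contour_raw=sl.contour_raw.copy(),
        contour_smooth=sl.contour_smooth.copy(),
        registry=sl.registry,
        panel=sl.panel,
    )


# ----------------------------------------------------------------------
# biopsies
# ----------------------------------------------------------------------

@dataclass
class Biopsy:
    """Circular regional biopsy: all voxels within ``radius`` of the centre."""

    centre: tuple[float, float]
    radius: float
    member_coords: np.ndarray  # (m, 2) int
    labels: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.labels)


def sample_biopsies(
    sl: TumourSlice, spacing: float = 20.0, radius: float = 5.0
) -> list[Biopsy]:
    """Spatially uniform biopsy sampling.

    Candidate centres form a square grid with the given spacing (anchored at
    spacing/2 from the lattice origin); each biopsy collects the occupied
    sites within ``radius`` mm of its centre, and biopsies with no tumour
    voxel are dropped.  On the 200 mm lattice the defaults give 100
    candidate centres."""
    L = sl.occ2d.shape[0]
    ticks = np.arange(spacing / 2.0, L, spacing)
    coords = sl.occupied_coords()
    tree = cKDTree(coords)
    out = []
    for cx in ticks:
        for cy in ticks:
            members = tree.query_ball_point([cx, cy], r=radius)
            if not members:
                continue
            mc = coords[members]
            out.append(
                Biopsy(
                    centre=(float(cx), float(cy)),
                    radius=radius,
                    member_coords=mc,
                    labels=sl.labels2d[mc[:, 0], mc[:, 1]],
                )
            )
    return out


# ----------------------------------------------------------------------
# microdiversity
# ----------------------------------------------------------------------

@dataclass
class MicrodiversityMap:
    """Subclone counts of every 3×3 mm² window position (stride 1 mm).

    ``counts[i, j]`` is the microdiversity of the window whose top-left
    corner is (i, j); windows containing no tumour voxel hold -1."""

    counts: np.ndarray
    window: int
    counting: str = "nested"

    def occupied_windows(self) -> np.ndarray:
        return np.argwhere(self.counts >= 0)


def _label_count_map(labels: np.ndarray, window: int) -> np.ndarray:
    sw = sliding_window_view(labels, (window, window))
    flat = np.sort(sw.reshape(sw.shape[0], sw.shape[1], -1), axis=-1)
    occupied = flat[..., -1] >= 0
    distinct = (flat[..., 0] >= 0).astype(np.int32)
    for k in range(1, flat.shape[-1]):
        distinct += ((flat[..., k] != flat[..., k - 1]) & (flat[..., k] >= 0)).astype(
            np.int32
        )
    return np.where(occupied, distinct, -1)


def _nested_count_map(
    labels: np.ndarray, registry: CloneRegistry, window: int
) -> np.ndarray:
    """Count distinct subclones intersecting each window under nested
    membership: a voxel belongs to its most-derived subclone and to every
    ancestral subclone; the parental clone is not a subclone."""
    present = np.unique(labels[labels >= 0])
    anc: dict[int, set[int]] = {}
    universe: set[int] = set()
    for lab in present:
        chain = set()
        c = int(lab)
        while c > 0:  # clone 0 is the parental root
            chain.add(c)
            c = registry.parent[c]
        anc[int(lab)] = chain
        universe |= chain
    order = {c: i for i, c in enumerate(sorted(universe))}
    n_sub = len(order)
    lut = np.zeros((int(labels.max()) + 2, n_sub), dtype=bool)
    for lab, chain in anc.items():
        for c in chain:
            lut[lab, order[c]] = True
    member = lut[np.where(labels >= 0, labels, -1)]  # (H, W, n_sub)
    member[labels < 0] = False
    H, W = labels.shape
    h, w = H - window + 1, W - window + 1
    union = np.zeros((h, w, n_sub), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)
    occ = labels >= 0
    for dx in range(window):
        for dy in range(window):
            union |= member[dx : dx + h, dy : dy + w]
            occupied |= occ[dx : dx + h, dy : dy + w]
    counts = union.sum(axis=-1).astype(np.int32)
    return np.where(occupied, counts, -1)


def microdiversity_map(
    sl: TumourSlice, window: int = 3, counting: str = "nested"
) -> MicrodiversityMap:
    """Slide a window across the slice and count subclones.

    ``counting="nested"`` (default) counts the distinct subclones whose
    voxel population intersects the window, where a voxel belongs to its
    own subclone and every ancestor; the parental clone does not count.
    This mirrors how multi-region sequencing counts subclones in a region.
    ``counting="labels"`` counts distinct most-derived clone labels
    (parental included) instead."""
    labels = sl.labels2d
    if counting == "labels":
        counts = _label_count_map(labels, window)
    elif counting == "nested":
        if sl.registry is None:
            raise ValueError("nested counting requires a clone registry")
        counts = _nested_count_map(labels, sl.registry, window)
    else:
        raise ValueError(f"unknown counting mode {counting!r}")
    return MicrodiversityMap(counts=counts, window=window, counting=counting)


@dataclass
class Hotspot:
    """A microdiversity hotspot: a window with >= 5 distinct clones."""

    centre: tuple[float, float]
    n_clones: int
    d1: float  # mm to tumour centre (slice centroid)
    d2: float  # mm to nearest contour point
    d: float  # normalised distance d1/(d1+d2)


def hotspots_and_distances(
    mmap: MicrodiversityMap, sl: TumourSlice, min_clones: int = 5
) -> list[Hotspot]:
    """Hotspot windows with their normalised distances to the tumour centre."""
    half = (mmap.window - 1) / 2.0
    wins = np.argwhere(mmap.counts >= min_clones)
    if len(wins) == 0:
        return []
    centres = wins + half
    cx, cy = sl.centroid
    d1 = np.hypot(centres[:, 0] - cx, centres[:, 1] - cy)
    tree = cKDTree(sl.contour_raw)
    d2, _ = tree.query(centres)
    out = []
    for m in range(len(wins)):
        tot = d1[m] + d2[m]
        d = float(d1[m] / tot) if tot > 0 else 0.0
        out.append(
            Hotspot(
                centre=(float(centres[m, 0]), float(centres[m, 1])),
                n_clones=int(mmap.counts[wins[m, 0], wins[m, 1]]),
                d1=float(d1[m]),
                d2=float(d2[m]),
                d=d,
            )
        )
    return out


# ----------------------------------------------------------------------
# power-law fitting
# ----------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """Bootstrap power-law fit of P(D ≤ d) = d^k."""

    k: float
    k_samples: np.ndarray
    n_points: int
    n_boot: int
    resample: int
    degenerate: bool = False
    method: str = "curve_fit"

    @property
    def k_median(self) -> float:
        return float(np.median(self.k_samples))

    def summary(self) -> dict:
        q1, q3 = np.percentile(self.k_samples, [25, 75])
        return {
            "k": self.k,
            "k_median": self.k_median,
            "k_q1": float(q1),
            "k_q3": float(q3),
            "n_points": self.n_points,
            "n_boot": self.n_boot,
            "resample": self.resample,
            "degenerate": self.degenerate,
        }


def _fit_exponent(d: np.ndarray, method: str = "curve_fit") -> float:
    x = np.sort(d)
    n = len(x)
    ecdf = np.arange(1, n + 1) / n
    if method == "loglog":
        good = x > 0
        slope, _ = np.polyfit(np.log(x[good]), np.log(ecdf[good]), 1)
        return float(slope)
    popt, _ = optimize.curve_fit(
        lambda xx, k: xx**k, x, ecdf, p0=[1.0], bounds=(1e-9, np.inf), maxfev=10000
    )
    return float(popt[0])


def fit_power_law(
    d: np.ndarray,
    n_boot: int = 100,
    resample: int = 400,
    seed: int = 0,
    method: str = "curve_fit",
) -> PowerLawFit:
    """Fit the cumulative distribution of normalised distances to d^k.

    The empirical CDF of each of ``n_boot`` bootstrap resamples (with
    replacement, ``resample`` points each) is fitted by least squares to the
    one-parameter power law d^k; the point estimate uses all data.  Requires
    at least 10 values in (0, 1]."""
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 10:
        raise ValueError(f"need >= 10 distance values, got {len(d)}")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("normalised distances must lie in [0, 1]")
    degenerate = bool(np.ptp(d) < 1e-9)
    if degenerate:
        return PowerLawFit(
            k=np.nan,
            k_samples=np.full(n_boot, np.nan),
            n_points=len(d),
            n_boot=n_boot,
            resample=resample,
            degenerate=True,
            method=method,
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    k_hat = _fit_exponent(d, method)
    ks = np.empty(n_boot)
    for b in range(n_boot):
        ks[b] = _fit_exponent(rng.choice(d, size=resample, replace=True), method)
    return PowerLawFit(
        k=k_hat,
        k_samples=ks,
        n_points=len(d),
        n_boot=n_boot,
        resample=resample,
        method=method,
    )


def qq_against_power_law(d: np.ndarray, k: float) -> pd.DataFrame:
    """Paired empirical vs theoretical quantiles of the d^k law.

    The theoretical quantile at probability p is p^(1/k); data drawn exactly
    from the law fall on the identity line."""
    d = np.sort(np.asarray(d, dtype=float))
    n = len(d)
    probs = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"theoretical": probs ** (1.0 / k), "empirical": d, "probability": probs}
    )


# ----------------------------------------------------------------------
# youngest subclones and fitness gradients
# ----------------------------------------------------------------------

@dataclass
class YoungestSubclones:
    """The most recently founded subclones in a slice, with their distances
    from the recorded initiating position to the tumour margin."""

    table: pd.DataFrame
    mean_distance_mm: float
    truncated: bool  # True when fewer than n clones were available


def youngest_subclones(sl: TumourSlice, n: int = 100) -> YoungestSubclones:
    """The n youngest subclones present in the slice (largest birth step).

    Each clone's position is the lattice position of its initiating voxel as
    recorded by the registry (kept current under Volume-Growth pushes); the
    distance is to the nearest contour point of the slice."""
    if sl.registry is None:
        raise ValueError("slice carries no clone registry")
    reg = sl.registry
    clones = np.unique(sl.occupied_labels())
    order = sorted(
        (int(c) for c in clones),
        key=lambda c: (reg.birth_step[c], c),
        reverse=True,
    )
    truncated = len(order) < n
    chosen = order[: min(n, len(order))]
    tree = cKDTree(sl.contour_raw)
    rows = []
    for c in chosen:
        ox, oy, _oz = reg.origin[c]
        dist, _ = tree.query([ox, oy])
        rows.append(
            {
                "clone_id": c,
                "birth_step": reg.birth_step[c],
                "x": ox,
                "y": oy,
                "distance_to_margin_mm": float(dist),
            }
        )
    table = pd.DataFrame(rows)
    return YoungestSubclones(
        table=table,
        mean_distance_mm=float(table["distance_to_margin_mm"].mean()),
        truncated=truncated,
    )


@dataclass
class FitnessSample:
    """Mean fitness of centre-most, margin-most and random voxel samples."""

    central_mean: float
    marginal_mean: float
    random_mean: float
    fraction: float
    ratio_c2m: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio_c2m = self.central_mean / self.marginal_mean


def fitness_gradient(
    sl: TumourSlice,
    model: AdvantageModel | None = None,
    fraction: float = 0.10,
    seed: int = 0,
) -> FitnessSample:
    """Centre-vs-margin fitness sampling (Ratio_C2M).

    The central-most ``fraction`` of slice voxels (shortest distance to the
    slice centroid), the marginal-most fraction (shortest distance to the
    contour) and an equally sized random sample are averaged over per-voxel
    growth probability."""
    if sl.registry is None:
        raise ValueError("slice carries no clone registry")
    coords = sl.occupied_coords()
    n = len(coords)
    if n < 10:
        raise ValueError(f"slice too small for fitness sampling (n={n})")
    labels = sl.labels2d[coords[:, 0], coords[:, 1]]
    reg = sl.registry
    if model is None:
        fit = reg.growth_prob[labels]
    else:
        from .driver_panel import growth_probability_from_bits

        uniq = np.unique(labels)
        lut = {
            int(c): growth_probability_from_bits(
                reg.genotype_bits[int(c)], model, reg.panel
            )
            for c in uniq
        }
        fit = np.array([lut[int(c)] for c in labels])
    cx, cy = sl.centroid
    d_centre = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
    d_margin, _ = cKDTree(sl.contour_raw).query(coords)
    n_sel = max(1, int(round(fraction * n)))
    central = np.argsort(d_centre, kind="stable")[:n_sel]
    marginal = np.argsort(d_margin, kind="stable")[:n_sel]
    rng = np.random.Generator(np.random.PCG64(seed))
    random_sel = rng.choice(n, size=n_sel, replace=False)
    return FitnessSample(
        central_mean=float(fit[central].mean()),
        marginal_mean=float(fit[marginal].mean()),
        random_mean=float(fit[random_sel].mean()),
        fraction=fraction,
    )
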