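"""Patient-data-style analyses on multi-region tables.

Cohort inputs are delimited tables of tumour regions (coordinates in mm,
clone/subclone counts, optional event labels and clinical group labels)
plus, per tumour, either an explicit margin polygon or a flag to estimate
the margin as the convex hull of its regions.  No sequencing processing
happens here: regions harbouring subclones act as a proxy for the
simulation's microdiversity hotspots, and their normalised centre distances
feed the same bootstrap power-law machinery as the simulated slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

from .spatial_analysis import PowerLawFit, fit_power_law

REGION_COLUMNS = [
    "tumour_id",
    "region_id",
    "x_mm",
    "y_mm",
    "n_clones",
    "n_subclones",
    "events",
    "group",
]


class RegionTableError(ValueError):
    """A region table violates the schema."""


@dataclass
class RegionTable:
    """Validated cohort region table with per-tumour margin polygons.

    ``margins`` maps tumour id to an (M, 2) array of margin points (mm);
    tumours without an explicit margin use the convex hull of their
    regions when ``hull_fallback`` is set."""

    regions: pd.DataFrame
    margins: dict[object, np.ndarray] = field(default_factory=dict)
    hull_fallback: bool = True

    def __post_init__(self) -> None:
        df = self.regions
        missing = [c for c in ("tumour_id", "region_id", "x_mm", "y_mm", "n_clones") if c not in df.columns]
        if missing:
            raise RegionTableError(f"missing columns: {missing}")
        for col in ("x_mm", "y_mm"):
            bad = df.index[~np.isfinite(df[col].astype(float))].tolist()
            if bad:
                raise RegionTableError(f"non-finite {col} in rows {bad}")
        bad = df.index[df["n_clones"].astype(int) < 1].tolist()
        if bad:
            raise RegionTableError(f"n_clones < 1 in rows {bad}")
        if "n_subclones" not in df.columns:
            df["n_subclones"] = df["n_clones"].astype(int) - 1
        bad = df.index[df["n_subclones"].astype(int) < 0].tolist()
        if bad:
            raise RegionTableError(f"negative n_subclones in rows {bad}")
        dup = df.duplicated(subset=["tumour_id", "region_id"])
        if dup.any():
            raise RegionTableError(
                f"duplicate (tumour_id, region_id) in rows {df.index[dup].tolist()}"
            )

    def tumour_ids(self) -> list:
        return list(dict.fromkeys(self.regions["tumour_id"]))

    def margin_points(self, tumour_id) -> np.ndarray:
        if tumour_id in self.margins:
            return self.margins[tumour_id]
        if not self.hull_fallback:
            raise RegionTableError(f"no margin polygon for tumour {tumour_id!r}")
        sub = self.regions[self.regions["tumour_id"] == tumour_id]
        pts = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
        if len(pts) < 3:
            raise RegionTableError(
                f"tumour {tumour_id!r}: need >= 3 regions for a hull margin"
            )
        hull = ConvexHull(pts)
        return pts[hull.vertices]

    def save(self, path: str | Path) -> None:
        df = self.regions.copy()
        for col in REGION_COLUMNS:
            if col not in df.columns:
                df[col] = ""
        df[REGION_COLUMNS].to_csv(path, index=False)


def load_region_table(
    path: str | Path,
    margin_paths: dict[object, str | Path] | None = None,
    hull_fallback: bool = True,
) -> RegionTable:
    """Load and validate a cohort region table (CSV with documented header).

    ``margin_paths`` optionally maps tumour ids to per-tumour CSVs of margin
    polygon points (columns x_mm, y_mm)."""
    df = pd.read_csv(path)
    margins = {}
    for tid, mp in (margin_paths or {}).items():
        m = pd.read_csv(mp)
        margins[tid] = m[["x_mm", "y_mm"]].to_numpy(dtype=float)
    return RegionTable(regions=df, margins=margins, hull_fallback=hull_fallback)


def hotspot_proxy(table: RegionTable, min_subclones: int = 1) -> pd.DataFrame:
    """Regions acting as microdiversity-hotspot proxies.

    The default threshold (>= 1 subclone beyond the parental clone) follows
    the cohort definition; a stricter >= 2 reading is available through
    ``min_subclones``."""
    df = table.regions
    return df[df["n_subclones"].astype(int) >= min_subclones].copy()


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (shoelace); falls back to the
    vertex mean for degenerate (zero-area) rings."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _dist_to_segments(p: np.ndarray, pts: np.ndarray) -> float:
    """Distance from point p to the closed polyline through pts."""
    a = pts
    b = np.roll(pts, -1, axis=0)
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((proj - p) ** 2).sum(axis=1)).min())


def region_distances(table: RegionTable, regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Normalised centre distances d = d1/(d1+d2) for cohort regions.

    d1 is the distance to the tumour centre (margin-polygon centroid), d2
    the distance to the nearest point of the margin polygon."""
    df = table.regions if regions is None else regions
    out = df.copy()
    d1s, d2s, ds = [], [], []
    for _, row in df.iterrows():
        pts = table.margin_points(row["tumour_id"])
        if len(pts) < 3:
            raise RegionTableError(
                f"degenerate margin for tumour {row['tumour_id']!r}"
            )
        p = np.array([float(row["x_mm"]), float(row["y_mm"])])
        centre = _polygon_centroid(pts)
        d1 = float(np.hypot(*(p - centre)))
        d2 = _dist_to_segments(p, pts)
        tot = d1 + d2
        d1s.append(d1)
        d2s.append(d2)
        ds.append(d1 / tot if tot > 0 else 0.0)
    out["d1_mm"] = d1s
    out["d2_mm"] = d2s
    out["d"] = ds
    return out


@dataclass
class GroupComparison:
    """Per-group power-law fits plus a two-sided rank test on exponents."""

    fits: dict[object, PowerLawFit]
    tests: pd.DataFrame  # pairwise Wilcoxon rank-sum results on k samples


def compare_group_exponents(
    table: RegionTable,
    grouping: str = "group",
    min_subclones: int = 1,
    min_regions: int = 10,
    n_boot: int = 100,
    resample: int = 400,
    seed: int = 0,
) -> GroupComparison:
    """Bootstrap power-law fits of hotspot-proxy distances per clinical group,
    compared pairwise with the two-sided Wilcoxon rank-sum test."""
    proxies = hotspot_proxy(table, min_subclones)
    if grouping not in proxies.columns:
        raise RegionTableError(f"no grouping column {grouping!r}")
    with_d = region_distances(table, proxies)
    fits: dict[object, PowerLawFit] = {}
    for gi, (grp, sub) in enumerate(with_d.groupby(grouping, sort=True)):
        if len(sub) < min_regions:
            raise RegionTableError(
                f"group {grp!r} has {len(sub)} hotspot-proxy regions (< {min_regions})"
            )
        fits[grp] = fit_power_law(
            sub["d"].to_numpy(), n_boot=n_boot, resample=resample, seed=seed + gi
        )
    groups = list(fits)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            stat, p = stats.ranksums(fits[a].k_samples, fits[b].k_samples)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "k_median_a": fits[a].k_median,
                    "k_median_b": fits[b].k_median,
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return GroupComparison(fits=fits, tests=pd.DataFrame(rows))


def single_region_event_distances(
    table: RegionTable, reference_mm: float = 10.0
) -> pd.DataFrame:
    """Margin distances of parallel events confined to a single region.

    Events (semicolon-separated labels per region) spanning exactly one
    region get that region's distance to the tumour margin; rows also flag
    whether the distance exceeds the 10 mm reference.  Per-tumour maxima are
    marked with ``is_tumour_max``."""
    df = table.regions
    if "events" not in df.columns:
        raise RegionTableError("table has no 'events' column")
    with_d = region_distances(table)
    span: dict[tuple, list[int]] = {}
    for idx, row in with_d.iterrows():
        evs = row.get("events")
        if not isinstance(evs, str) or not evs.strip():
            continue
        for ev in (e.strip() for e in evs.split(";") if e.strip()):
            span.setdefault((row["tumour_id"], ev), []).append(idx)
    rows = []
    for (tid, ev), idxs in sorted(span.items(), key=str):
        if len(idxs) != 1:
            continue
        r = with_d.loc[idxs[0]]
        rows.append(
            {
                "tumour_id": tid,
                "event": ev,
                "region_id": r["region_id"],
                "distance_to_margin_mm": float(r["d2_mm"]),
                "exceeds_reference": bool(r["d2_mm"] > reference_mm),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "tumour_id",
            "event",
            "region_id",
            "distance_to_margin_mm",
            "exceeds_reference",
        ],
    )
    if len(out):
        out["is_tumour_max"] = out.groupby("tumour_id")[
            "distance_to_margin_mm"
        ].transform(lambda s: s == s.max())
    else:
        out["is_tumour_max"] = pd.Series(dtype=bool)
    out.attrs["reference_mm"] = reference_mm
    return out
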