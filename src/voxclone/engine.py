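"""Stochastic lattice engine: growth, death, driver acquisition, necrosis, replay.

The tumour is a set of 1 mm³ voxels on an ``L×L×L`` lattice.  Each simulation
step applies, in order:

1. **death** — every voxel dies independently with probability ``p_death``;
2. **depth refresh** — Euclidean distance of every voxel to the nearest
   non-tumour site (the "distance from the tumour surface");
3. **growth** — eligible parents, visited in a fresh random permutation,
   divide with their genotype-dependent ``p_growth``.  Under *Surface
   Growth* only voxels with an empty site among their 26 neighbours may
   divide and the daughter takes a random empty neighbour; under *Volume
   Growth* every voxel may divide: 10 of the 26 orientations are sampled,
   the one whose target site lies closest to the tumour surface is chosen,
   and the occupied run of voxels along that orientation is pushed one step
   outward to make room;
4. **driver acquisition** — each daughter tests every panel event it does
   not yet harbour: gene mutations at ``p_driver``, SCNAs at the
   genotype-dependent SCNA rate.  A daughter acquiring at least one event
   founds a new subclone;
5. **necrosis** (optional) — voxels deeper than ``d_necrosis`` = 15 mm die
   with probability ``p_necrosis`` = 0.5.

Sites freed by deaths are immediately reusable within the same step.  The
run stops once the population reaches ``stop_size`` voxels (1e6 voxels ≈ a
12 cm tumour at full scale).

Determinism: step ``t`` draws from a dedicated generator seeded by
``SeedSequence(seed, spawn_key=(t,))``, so a run is reproducible bit-for-bit
and a snapshot resumed under the same master seed continues identically to
the uninterrupted run.  Evolutionary replay restores a snapshot into ``N``
replicates and continues each under its own seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .driver_panel import (
    AdvantageModel,
    DriverPanel,
    SCNA_RATE_FACTOR,
    default_panel,
    growth_probability_from_bits,
)

SURFACE = "surface"
VOLUME = "volume"

# 26-neighbourhood offsets (Moore neighbourhood in 3D)
NEIGHBOUR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


class BoundaryError(RuntimeError):
    """The tumour reached the lattice boundary; results would be clipped."""


class MaxStepsExceeded(RuntimeError):
    """The stopping size was not reached within the step guard."""


@dataclass
class SimulationConfig:
    """All simulation parameters.  Defaults follow the full-scale study
    condition (200³ lattice, stop at 1e6 voxels); tests use reduced presets."""

    L: int = 200
    p_growth_initial: float = 0.25
    p_death: float = 0.05
    p_driver: float = 6e-4
    growth_mode: str = SURFACE
    advantage: AdvantageModel = field(default_factory=AdvantageModel)
    necrosis_enabled: bool = False
    p_necrosis: float = 0.5
    d_necrosis: float = 15.0
    stop_size: int = 1_000_000
    max_steps: int = 100_000
    seed: int = 0
    snapshot_every: int = 0  # 0 = final snapshot only
    rng_algorithm: str = "pcg64"

    def __post_init__(self) -> None:
        if self.growth_mode not in (SURFACE, VOLUME):
            raise ValueError(f"growth_mode must be surface|volume, got {self.growth_mode!r}")
        for name in ("p_growth_initial", "p_death", "p_driver", "p_necrosis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.L < 3:
            raise ValueError("lattice side L must be >= 3")
        if self.stop_size > self.L**3:
            raise ValueError("stop_size exceeds lattice capacity")
        if self.rng_algorithm != "pcg64":
            raise ValueError("only the pcg64 RNG algorithm is supported")
        if self.advantage.p_growth_initial != self.p_growth_initial:
            self.advantage = replace(
                self.advantage, p_growth_initial=self.p_growth_initial
            )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "L", "p_growth_initial", "p_death", "p_driver", "growth_mode",
            "necrosis_enabled", "p_necrosis", "d_necrosis", "stop_size",
            "max_steps", "seed", "snapshot_every", "rng_algorithm")}
        d["advantage"] = self.advantage.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "advantage" in d:
            d["advantage"] = AdvantageModel.from_dict(d["advantage"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class CloneRegistry:
    """Phylogeny of subclones.

    Clone 0 is the parental clone (VHL + 3p loss).  A new clone is founded by
    every voxel that acquires at least one new driver upon birth; its
    genotype is the parent clone's genotype plus the acquired events.
    ``origin`` tracks the current lattice position of the clone-initiating
    voxel (updated when Volume-Growth pushes displace it)."""

    def __init__(self, panel: DriverPanel, config: SimulationConfig):
        self.panel = panel
        self.config = config
        self.parent: list[int] = []
        self.birth_step: list[int] = []
        self.new_events: list[tuple[int, ...]] = []
        self.allele_ids: list[tuple[tuple[int, int], ...]] = []
        self.genotype_bits: list[int] = []
        self.origin: list[tuple[int, int, int]] = []
        self._allele_counters = np.zeros(panel.n_events, dtype=np.int64)
        self._growth_prob = np.zeros(0, dtype=np.float64)
        self._acq_rows = np.zeros((0, panel.n_events), dtype=np.float64)
        self._n_drivers = np.zeros(0, dtype=np.int64)

    @property
    def n_clones(self) -> int:
        return len(self.parent)

    def _acq_row(self, bits: int) -> np.ndarray:
        panel = self.panel
        p_driver = self.config.p_driver
        scna_rate = p_driver if bits & panel.enhancer_bits else SCNA_RATE_FACTOR * p_driver
        row = np.where(panel.gene_mask, p_driver, scna_rate)
        harboured = ((bits >> np.arange(panel.n_events)) & 1).astype(bool)
        row[harboured] = 0.0
        return row

    def add_clone(
        self,
        parent: int,
        birth_step: int,
        event_ids: Sequence[int],
        origin: tuple[int, int, int],
    ) -> int:
        """Register a clone founded by acquiring ``event_ids`` on top of
        ``parent``'s genotype; gene mutations draw fresh allele ids."""
        bits = self.genotype_bits[parent] if parent >= 0 else 0
        alleles = []
        for ev in event_ids:
            bits |= 1 << int(ev)
            if self.panel.gene_mask[ev]:
                aid = int(self._allele_counters[ev])
                self._allele_counters[ev] += 1
                alleles.append((int(ev), aid))
        cid = self.n_clones
        self.parent.append(parent)
        self.birth_step.append(birth_step)
        self.new_events.append(tuple(int(e) for e in event_ids))
        self.allele_ids.append(tuple(alleles))
        self.genotype_bits.append(bits)
        self.origin.append(tuple(int(c) for c in origin))
        self._growth_prob = np.append(
            self._growth_prob,
            growth_probability_from_bits(bits, self.config.advantage, self.panel),
        )
        self._acq_rows = np.vstack([self._acq_rows, self._acq_row(bits)])
        self._n_drivers = np.append(self._n_drivers, bits.bit_count())
        return cid

    @property
    def growth_prob(self) -> np.ndarray:
        """Per-clone growth probability under the configured advantage model."""
        return self._growth_prob

    @property
    def n_drivers(self) -> np.ndarray:
        """Per-clone total driver count (mutations + SCNAs)."""
        return self._n_drivers

    def allele_set(self, clone: int) -> frozenset[tuple[int, int]]:
        """All (gene event id, allele id) pairs along the clone's ancestry."""
        out: set[tuple[int, int]] = set()
        c = clone
        while c >= 0:
            out.update(self.allele_ids[c])
            c = self.parent[c]
        return frozenset(out)

    def copy(self) -> "CloneRegistry":
        return copy.deepcopy(self)

    def to_records(self) -> list[dict]:
        return [
            {
                "clone_id": i,
                "parent_id": self.parent[i],
                "birth_step": self.birth_step[i],
                "new_events": list(self.new_events[i]),
                "allele_ids": [list(a) for a in self.allele_ids[i]],
                "genotype": format(self.genotype_bits[i], "x"),
                "origin": list(self.origin[i]),
            }
            for i in range(self.n_clones)
        ]

    @classmethod
    def from_records(
        cls,
        records: list[dict],
        panel: DriverPanel,
        config: SimulationConfig,
    ) -> "CloneRegistry":
        reg = cls(panel, config)
        for rec in sorted(records, key=lambda r: r["clone_id"]):
            cid = reg.add_clone(
                rec["parent_id"],
                rec["birth_step"],
                rec["new_events"],
                tuple(rec["origin"]),
            )
            assert cid == rec["clone_id"]
            if format(reg.genotype_bits[cid], "x") != rec["genotype"]:
                raise ValueError(f"genotype mismatch reconstructing clone {cid}")
        return reg


class LatticeState:
    """Full simulation state over flat ``L³`` arrays.

    ``clone`` holds the most-derived clone label of each voxel (-1 = empty);
    genotypes live on the clone registry, so per-voxel genotype lookups are
    label indirections.  ``origin_marker`` marks, per site, the clone whose
    initiating voxel currently occupies it (-1 otherwise)."""

    def __init__(self, config: SimulationConfig, panel: DriverPanel | None = None):
        self.config = config
        self.panel = panel if panel is not None else default_panel()
        L = config.L
        self.L = L
        n = L**3
        self.occ = np.zeros(n, dtype=bool)
        self.clone = np.full(n, -1, dtype=np.int32)
        self.birth = np.full(n, -1, dtype=np.int32)
        self.origin_marker = np.full(n, -1, dtype=np.int32)
        self.depth = np.zeros(n, dtype=np.float64)
        self.registry = CloneRegistry(self.panel, config)
        self.step_count = 0
        self.n_voxels = 0
        self.step_log: list[dict] = []
        # flat-index deltas of the 26 neighbours
        off = NEIGHBOUR_OFFSETS
        self._neigh_delta = (off[:, 0] * L + off[:, 1]) * L + off[:, 2]

    # -- indexing helpers ---------------------------------------------

    def flat(self, x: int, y: int, z: int) -> int:
        return (x * self.L + y) * self.L + z

    def coords(self, idx: np.ndarray | int):
        L = self.L
        z = idx % L
        y = (idx // L) % L
        x = idx // (L * L)
        return x, y, z

    def occ3d(self) -> np.ndarray:
        return self.occ.reshape(self.L, self.L, self.L)

    def occupied_indices(self) -> np.ndarray:
        return np.flatnonzero(self.occ)

    def step_rng(self, phase: int = 0) -> np.random.Generator:
        """Dedicated generator for the current step (and replay phase)."""
        ss = np.random.SeedSequence(self.config.seed, spawn_key=(self.step_count, phase))
        return np.random.Generator(np.random.PCG64(ss))

    # -- mutation helpers ---------------------------------------------

    def _check_interior(self, idx: int) -> None:
        x, y, z = self.coords(idx)
        L = self.L
        if min(x, y, z) == 0 or max(x, y, z) == L - 1:
            raise BoundaryError(
                f"tumour reached lattice boundary at ({x},{y},{z}) on step "
                f"{self.step_count}; increase L or lower stop_size"
            )

    def add_voxel(self, idx: int, clone: int, birth_step: int) -> None:
        self._check_interior(idx)
        if self.occ[idx]:
            raise ValueError("site already occupied")
        self.occ[idx] = True
        self.clone[idx] = clone
        self.birth[idx] = birth_step
        self.n_voxels += 1

    def remove_voxels(self, idx: np.ndarray) -> None:
        self.occ[idx] = False
        self.clone[idx] = -1
        self.birth[idx] = -1
        self.origin_marker[idx] = -1
        self.n_voxels -= len(idx)

    def refresh_depth(self) -> None:
        """Exact Euclidean distance of each voxel to the tumour surface.

        The surface is the exterior: empty sites connected to the lattice
        border.  Internal cavities (holes opened by cell death or necrosis)
        are filled before the distance transform, so a voxel deep inside the
        tumour is deep even when a dead neighbour left an empty site next to
        it.  Computed on the tumour's bounding box for speed."""
        occ3 = self.occ3d()
        idx = np.flatnonzero(self.occ)
        self.depth = np.zeros(self.L**3, dtype=np.float64)
        if len(idx) == 0:
            return
        x, y, z = self.coords(idx)
        lo = [max(int(v.min()) - 1, 0) for v in (x, y, z)]
        hi = [min(int(v.max()) + 2, self.L) for v in (x, y, z)]
        box = occ3[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        filled = ndimage.binary_fill_holes(box)
        d = ndimage.distance_transform_edt(filled)
        full = np.zeros((self.L, self.L, self.L), dtype=np.float64)
        full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = np.where(box, d, 0.0)
        self.depth = full.ravel()

    def validate(self) -> None:
        """Internal-consistency check (used by tests)."""
        assert int(self.occ.sum()) == self.n_voxels
        assert np.all((self.clone >= 0) == self.occ)
        marked = np.flatnonzero(self.origin_marker >= 0)
        assert np.all(self.occ[marked])


def initialize(config: SimulationConfig, panel: DriverPanel | None = None) -> LatticeState:
    """A single founder voxel (VHL + 3p loss) at the lattice centre."""
    state = LatticeState(config, panel)
    c = config.L // 2
    centre = state.flat(c, c, c)
    truncal = tuple(int(i) for i in np.flatnonzero(state.panel.truncal_mask))
    cid = state.registry.add_clone(-1, 0, truncal, (c, c, c))
    state.add_voxel(centre, cid, 0)
    state.origin_marker[centre] = cid
    return state


# ----------------------------------------------------------------------
# simulation phases
# ----------------------------------------------------------------------

def death_phase(state: LatticeState, rng: np.random.Generator) -> np.ndarray:
    """Remove each living voxel independently with probability p_death."""
    idx = state.occupied_indices()
    if len(idx) == 0:
        return idx
    dying = idx[rng.random(len(idx)) < state.config.p_death]
    state.remove_voxels(dying)
    return dying


def eligible_parents(state: LatticeState, mode: str | None = None) -> np.ndarray:
    """Voxels allowed to attempt division this step.

    Surface Growth requires at least one empty site among the 26 neighbours;
    Volume Growth allows every voxel."""
    mode = mode or state.config.growth_mode
    idx = state.occupied_indices()
    if mode == VOLUME or len(idx) == 0:
        return idx
    occ3 = state.occ3d()
    interior = ndimage.binary_erosion(occ3, structure=np.ones((3, 3, 3), bool))
    return idx[~interior.ravel()[idx]]


def place_child_surface(
    state: LatticeState, parent: int, rng: np.random.Generator
) -> int | None:
    """Place a daughter at a uniformly chosen empty neighbour of ``parent``.

    Returns the child site, or None when the parent has no empty neighbour
    left (it is skipped for this step)."""
    neigh = parent + state._neigh_delta
    empty = neigh[~state.occ[neigh]]
    if len(empty) == 0:
        return None
    child = int(empty[rng.integers(len(empty))])
    state.add_voxel(child, int(state.clone[parent]), state.step_count)
    return child


def place_child_volume(
    state: LatticeState, parent: int, rng: np.random.Generator
) -> int:
    """Volume-Growth placement with outward pushing.

    Ten of the 26 orientations are sampled without replacement; the candidate
    site with the smallest distance from the tumour surface wins (ties broken
    uniformly).  The run of occupied sites along that orientation is shifted
    one step outward until the first empty site absorbs the displacement,
    then the daughter takes the site adjacent to the parent."""
    dirs = rng.permutation(26)[:10]
    cand = parent + state._neigh_delta[dirs]
    depths = state.depth[cand]
    best = np.flatnonzero(depths == depths.min())
    pick = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
    d = int(dirs[pick])
    delta = int(state._neigh_delta[d])
    dx, dy, dz = (int(v) for v in NEIGHBOUR_OFFSETS[d])
    L = state.L
    px, py, pz = (int(v) for v in state.coords(parent))

    # walk outward to the first empty site
    x, y, z = px + dx, py + dy, pz + dz
    occ = state.occ
    start = parent + delta
    end = start
    while occ[end]:
        x += dx
        y += dy
        z += dz
        if not (0 <= x < L and 0 <= y < L and 0 <= z < L):
            raise BoundaryError(
                f"volume-growth push exited the lattice at step {state.step_count}"
            )
        end += delta
    state._check_interior(end)

    # shift the occupied run one step outward (end is empty)
    clone, birth, marker = state.clone, state.birth, state.origin_marker
    reg_origin = state.registry.origin
    j = end
    while j != start:
        i = j - delta
        clone[j] = clone[i]
        birth[j] = birth[i]
        occ[j] = occ[i]
        m = marker[i]
        marker[j] = m
        if m >= 0:
            xx, yy, zz = state.coords(j)
            reg_origin[m] = (int(xx), int(yy), int(zz))
        j = i
    # the shift conserves the voxel count: `end` filled, `start` freed
    occ[start] = False
    clone[start] = -1
    birth[start] = -1
    marker[start] = -1
    # the freed adjacent site receives the daughter
    state.add_voxel(start, int(clone[parent]), state.step_count)
    return start


def driver_phase(
    state: LatticeState, daughters: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Test every daughter for acquisition of each not-yet-harboured driver.

    Gene mutations acquire at p_driver; SCNAs at 0.001·p_driver (p_driver if
    the genotype carries PBRM1 or BAP1).  A daughter acquiring one or more
    events founds a new subclone with fresh allele ids for gene events."""
    if len(daughters) == 0:
        return []
    reg = state.registry
    rows = reg._acq_rows[state.clone[daughters]]
    hits = rng.random(rows.shape) < rows
    new_clones: list[int] = []
    for k in np.flatnonzero(hits.any(axis=1)):
        site = int(daughters[k])
        events = np.flatnonzero(hits[k])
        x, y, z = (int(v) for v in state.coords(site))
        cid = reg.add_clone(
            int(state.clone[site]), state.step_count, events, (x, y, z)
        )
        state.clone[site] = cid
        state.origin_marker[site] = cid
        new_clones.append(cid)
    return new_clones


def necrosis_phase(state: LatticeState, rng: np.random.Generator) -> np.ndarray:
    """Necrotic death: voxels deeper than d_necrosis die with p_necrosis."""
    cfg = state.config
    idx = np.flatnonzero(state.occ & (state.depth > cfg.d_necrosis))
    if len(idx) == 0:
        return idx
    dying = idx[rng.random(len(idx)) < cfg.p_necrosis]
    state.remove_voxels(dying)
    return dying


def step(state: LatticeState) -> LatticeState:
    """Advance the simulation by one step (death → growth → drivers → necrosis)."""
    cfg = state.config
    rng = state.step_rng()

    dead = death_phase(state, rng)

    need_depth = cfg.growth_mode == VOLUME or cfg.necrosis_enabled
    if need_depth:
        state.refresh_depth()

    parents = eligible_parents(state)
    daughters: list[int] = []
    if len(parents) > 0:
        p_grow = state.registry.growth_prob[state.clone[parents]]
        dividers = parents[rng.random(len(parents)) < p_grow]
        dividers = rng.permutation(dividers)
        if cfg.growth_mode == SURFACE:
            for parent in dividers:
                child = place_child_surface(state, int(parent), rng)
                if child is not None:
                    daughters.append(child)
        else:
            for parent in dividers:
                daughters.append(place_child_volume(state, int(parent), rng))
    daughters_arr = np.asarray(daughters, dtype=np.int64)

    new_clones = driver_phase(state, daughters_arr, rng)

    necrotic = np.array([], dtype=np.int64)
    if cfg.necrosis_enabled:
        necrotic = necrosis_phase(state, rng)

    state.step_log.append(
        {
            "step": state.step_count,
            "n_voxels": state.n_voxels,
            "births": len(daughters),
            "deaths": len(dead),
            "necrotic_deaths": len(necrotic),
            "new_clones": len(new_clones),
        }
    )
    state.step_count += 1
    return state


# ----------------------------------------------------------------------
# snapshots
# ----------------------------------------------------------------------

@dataclass
class Snapshot:
    """Serialisable full tumour state at one time point.

    Contains the position, most-derived clone label, genotype and birth step
    of every voxel plus a copy of the clone registry — everything needed to
    restore an identical LatticeState for time-course analysis or
    evolutionary replay."""

    step: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    clone_id: np.ndarray
    birth_step: np.ndarray
    origin_marker_clone: np.ndarray  # clone whose initiating voxel is here, -1 otherwise
    registry_records: list[dict]
    config: SimulationConfig
    config_hash: str

    @classmethod
    def take(cls, state: LatticeState) -> "Snapshot":
        idx = state.occupied_indices()
        x, y, z = state.coords(idx)
        return cls(
            step=state.step_count,
            x=np.asarray(x, dtype=np.int32),
            y=np.asarray(y, dtype=np.int32),
            z=np.asarray(z, dtype=np.int32),
            clone_id=state.clone[idx].copy(),
            birth_step=state.birth[idx].copy(),
            origin_marker_clone=state.origin_marker[idx].copy(),
            registry_records=state.registry.copy().to_records(),
            config=state.config,
            config_hash=state.config.hash(),
        )

    @property
    def n_voxels(self) -> int:
        return len(self.x)

    def genotype_hex(self) -> list[str]:
        bits = {r["clone_id"]: r["genotype"] for r in self.registry_records}
        return [bits[int(c)] for c in self.clone_id]

    def restore(self, seed: int | None = None, panel: DriverPanel | None = None) -> LatticeState:
        """Rebuild a LatticeState bit-identical to the captured one.

        ``seed`` overrides the master seed for continued simulation (used by
        replay); with ``seed=None`` the original seed is kept, so continuing
        reproduces the uninterrupted run exactly."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        state = LatticeState(cfg, panel)
        state.registry = CloneRegistry.from_records(
            self.registry_records, state.panel, cfg
        )
        idx = (self.x.astype(np.int64) * state.L + self.y) * state.L + self.z
        state.occ[idx] = True
        state.clone[idx] = self.clone_id
        state.birth[idx] = self.birth_step
        state.origin_marker[idx] = self.origin_marker_clone
        state.n_voxels = len(idx)
        state.step_count = self.step
        return state

    # -- text round-trip ----------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write voxel table as TSV plus a JSON sidecar (registry + config)."""
        path = Path(path)
        geno = self.genotype_hex()
        with open(path, "w") as fh:
            fh.write("x\ty\tz\tclone_id\tbirth_step\tgenotype\n")
            for i in range(self.n_voxels):
                fh.write(
                    f"{self.x[i]}\t{self.y[i]}\t{self.z[i]}\t"
                    f"{self.clone_id[i]}\t{self.birth_step[i]}\t{geno[i]}\n"
                )
        sidecar = {
            "step": self.step,
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "origin_markers": {
                str(i): int(c)
                for i, c in enumerate(self.origin_marker_clone)
                if c >= 0
            },
            "clone_registry": self.registry_records,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Snapshot":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg = SimulationConfig.from_dict(sidecar["config"])
        with open(path) as fh:
            n_rows = sum(1 for _ in fh) - 1
        if n_rows <= 0:
            data = np.zeros((0, 6), dtype="U1")
        else:
            data = np.loadtxt(path, skiprows=1, dtype=str, delimiter="\t", ndmin=2)
        x = data[:, 0].astype(np.int32)
        markers = np.full(len(x), -1, dtype=np.int32)
        for i, c in sidecar["origin_markers"].items():
            markers[int(i)] = c
        return cls(
            step=sidecar["step"],
            x=x,
            y=data[:, 1].astype(np.int32),
            z=data[:, 2].astype(np.int32),
            clone_id=data[:, 3].astype(np.int32),
            birth_step=data[:, 4].astype(np.int32),
            origin_marker_clone=markers,
            registry_records=sidecar["clone_registry"],
            config=cfg,
            config_hash=sidecar["config_hash"],
        )


# ----------------------------------------------------------------------
# run / replay
# ----------------------------------------------------------------------

def run_state(
    state: LatticeState,
    stop_size: int | None = None,
    max_steps: int | None = None,
    snapshot_every: int | None = None,
) -> tuple[LatticeState, list[Snapshot]]:
    """Step ``state`` until the population reaches ``stop_size``."""
    cfg = state.config
    stop_size = cfg.stop_size if stop_size is None else stop_size
    max_steps = cfg.max_steps if max_steps is None else max_steps
    snap_every = cfg.snapshot_every if snapshot_every is None else snapshot_every
    snapshots: list[Snapshot] = []
    while state.n_voxels < stop_size:
        if state.step_count >= max_steps:
            raise MaxStepsExceeded(
                f"stop_size {stop_size} not reached within {max_steps} steps "
                f"(n={state.n_voxels})"
            )
        step(state)
        if state.n_voxels == 0:
            # stochastic extinction of a small tumour: report and stop
            break
        if snap_every and state.step_count % snap_every == 0:
            snapshots.append(Snapshot.take(state))
    snapshots.append(Snapshot.take(state))
    return state, snapshots


def run(
    config: SimulationConfig, panel: DriverPanel | None = None
) -> tuple[LatticeState, list[Snapshot]]:
    """Full simulation from a single founder voxel to the stopping size."""
    state = initialize(config, panel)
    return run_state(state)


def run_surviving(
    config: SimulationConfig,
    panel: DriverPanel | None = None,
    max_attempts: int = 100,
) -> tuple[LatticeState, list[Snapshot]]:
    """Run conditioned on non-extinction.

    A founder voxel dies before establishing a tumour in a fraction of runs
    (roughly p_death/p_growth); study ensembles consider tumours that reach
    the stopping size, so extinct attempts are discarded and the simulation
    retries under a seed derived deterministically from (seed, attempt)."""
    for attempt in range(max_attempts):
        seed = config.seed if attempt == 0 else int(
            np.random.SeedSequence([config.seed, attempt]).generate_state(1)[0]
            % 2**31
        )
        state, snapshots = run(replace(config, seed=seed), panel)
        if state.n_voxels >= 1:
            return state, snapshots
    raise RuntimeError(f"no surviving run in {max_attempts} attempts")


def replay(
    snapshot: Snapshot,
    seeds: Sequence[int],
    stop_size: int | None = None,
    panel: DriverPanel | None = None,
) -> list[LatticeState]:
    """Evolutionary replay: restore N replicates of a snapshot and grow each
    to the stopping size under its own unique random seed."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("replay seeds must be distinct")
    finals = []
    for seed in seeds:
        state = snapshot.restore(seed=int(seed), panel=panel)
        state, _ = run_state(state, stop_size=stop_size)
        finals.append(state)
    return finals


def equivalent_spherical_diameter_mm(n_voxels: int) -> float:
    """Diameter (mm) of a sphere with the volume of ``n_voxels`` 1 mm³ voxels."""
    return 2.0 * (3.0 * n_voxels / (4.0 * np.pi)) ** (1.0 / 3.0)
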