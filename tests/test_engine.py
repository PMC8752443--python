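"""Engine phases, determinism, snapshots and evolutionary replay."""

import numpy as np
import pytest
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from voxclone import (
    BoundaryError,
    SimulationConfig,
    Snapshot,
    equivalent_spherical_diameter_mm,
    fixture_lattice,
    initialize,
    replay,
    run,
    run_state,
    step,
)
from voxclone.engine import (
    NEIGHBOUR_OFFSETS,
    death_phase,
    driver_phase,
    eligible_parents,
    necrosis_phase,
    place_child_surface,
    place_child_volume,
)


def small_config(**kw):
    base = dict(L=20, stop_size=2000, max_steps=500, seed=0, p_driver=0.0)
    base.update(kw)
    return SimulationConfig(**base)


def rng(seed=0):
    return np.random.Generator(np.random.PCG64(seed))


class TestInitialize:
    def test_single_founder_at_centre(self):
        state = initialize(small_config())
        assert state.n_voxels == 1
        c = state.config.L // 2
        assert state.occ[state.flat(c, c, c)]

    def test_founder_genotype_is_truncal(self):
        state = initialize(small_config())
        bits = state.registry.genotype_bits[0]
        truncal = state.panel.truncal_bits
        assert bits == truncal
        # one VHL allele registered
        assert len(state.registry.allele_ids[0]) == 1

    def test_same_seed_same_stream(self):
        a = initialize(small_config(seed=5))
        b = initialize(small_config(seed=5))
        assert a.step_rng().random(4).tolist() == b.step_rng().random(4).tolist()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(L=2)
        with pytest.raises(ValueError):
            SimulationConfig(L=10, stop_size=10**6)
        with pytest.raises(ValueError):
            SimulationConfig(p_death=1.5)


class TestDeathPhase:
    def test_p_death_extremes(self):
        state = fixture_lattice("cube3")
        state.config.p_death = 0.0
        assert len(death_phase(state, rng())) == 0
        state.config.p_death = 1.0
        assert len(death_phase(state, rng())) == 27
        assert state.n_voxels == 0

    def test_binomial_removal_count(self):
        state = fixture_lattice("sphere20")
        n = state.n_voxels
        state.config.p_death = 0.05
        removed = len(death_phase(state, rng(3)))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= removed <= hi


class TestEligibility:
    def test_enclosed_centre_ineligible_in_surface_mode(self):
        state = fixture_lattice("cube3")
        c = state.L // 2
        surface = eligible_parents(state, "surface")
        assert len(surface) == 26
        assert state.flat(c, c, c) not in surface

    def test_volume_mode_all_eligible(self):
        state = fixture_lattice("cube3")
        assert len(eligible_parents(state, "volume")) == 27

    def test_single_voxel_eligible_in_both(self):
        state = initialize(small_config())
        assert len(eligible_parents(state, "surface")) == 1
        assert len(eligible_parents(state, "volume")) == 1


class TestSurfacePlacement:
    def test_sole_empty_neighbour_is_taken(self):
        state = fixture_lattice("cube3")
        c = state.L // 2
        # free exactly one neighbour of a face voxel, fill the rest around it
        parent = state.flat(c + 1, c, c)
        for off in NEIGHBOUR_OFFSETS:
            site = state.flat(c + 1 + off[0], c + off[1], c + off[2])
            if not state.occ[site]:
                state.occ[site] = True
                state.clone[site] = 0
                state.birth[site] = 0
                state.n_voxels += 1
        hole = state.flat(c + 2, c, c)
        state.remove_voxels(np.array([hole]))
        child = place_child_surface(state, parent, rng())
        assert child == hole

    def test_enclosed_parent_skips(self):
        state = fixture_lattice("cube3")
        c = state.L // 2
        assert place_child_surface(state, state.flat(c, c, c), rng()) is None

    def test_uniform_choice_over_empty_neighbours(self):
        """Each empty neighbour is chosen ~uniformly (chi-square)."""
        state = initialize(small_config(seed=1))
        c = state.config.L // 2
        parent = state.flat(c, c, c)
        counts = {}
        g = rng(7)
        for _ in range(2600):
            child = place_child_surface(state, parent, g)
            counts[child] = counts.get(child, 0) + 1
            state.remove_voxels(np.array([child]))
        assert len(counts) == 26
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.01


class TestVolumePlacement:
    def _row_state_with_labels(self):
        state = fixture_lattice("row5")
        c = state.L // 2
        for i in range(1, 5):
            state.registry.add_clone(0, i, (), (c - 2 + i, c, c))
        for i in range(5):
            state.clone[state.flat(c - 2 + i, c, c)] = i
        return state, c

    def _rng_sampling_direction(self, want_dir, max_tries=200):
        """A seed whose first permutation draw includes the wanted offset."""
        idx = int(
            np.flatnonzero((NEIGHBOUR_OFFSETS == want_dir).all(axis=1))[0]
        )
        for k in range(max_tries):
            g = np.random.Generator(np.random.PCG64(k))
            if idx in g.permutation(26)[:10]:
                return np.random.Generator(np.random.PCG64(k))
        raise AssertionError("no suitable seed found")

    def test_push_shifts_row_preserving_order(self):
        """1D push oracle: a 5-voxel row becomes 6, labels keep their order."""
        state, c = self._row_state_with_labels()
        parent = state.flat(c - 2, c, c)
        # force the +x orientation to be the unique minimal-depth candidate
        state.depth = np.full(state.L**3, 5.0)
        state.depth[state.flat(c - 1, c, c)] = 0.0
        g = self._rng_sampling_direction((1, 0, 0))
        child = place_child_volume(state, parent, g)
        assert child == state.flat(c - 1, c, c)
        labels = [state.clone[state.flat(c - 2 + i, c, c)] for i in range(6)]
        # parent, daughter (parent's clone), then the displaced 1..4 in order
        assert labels == [0, 0, 1, 2, 3, 4]
        assert state.clone[state.flat(c + 4, c, c)] == -1
        assert state.n_voxels == 6

    def test_empty_candidate_gives_zero_length_push(self):
        state = initialize(small_config())
        c = state.config.L // 2
        state.refresh_depth()
        before = state.n_voxels
        child = place_child_volume(state, state.flat(c, c, c), rng(2))
        assert state.n_voxels == before + 1
        assert not np.array_equal(child, state.flat(c, c, c))

    def test_minimal_depth_candidate_wins(self):
        state, c = self._row_state_with_labels()
        parent = state.flat(c, c, c)  # row middle: +x and -x neighbours occupied
        state.depth = np.full(state.L**3, 9.0)
        state.depth[state.flat(c + 1, c, c)] = 0.5  # strictly closest to surface
        g = self._rng_sampling_direction((1, 0, 0))
        child = place_child_volume(state, parent, g)
        assert child == state.flat(c + 1, c, c)

    def test_boundary_push_aborts(self):
        cfg = small_config(L=9, stop_size=700, growth_mode="volume", max_steps=200, p_death=0.0)
        with pytest.raises(BoundaryError):
            run(cfg)


class TestDriverPhase:
    def test_no_acquisition_when_p_driver_zero(self):
        state = initialize(small_config(p_driver=0.0))
        daughters = state.occupied_indices()
        assert driver_phase(state, daughters, rng()) == []

    def test_never_reacquire_harboured_event(self):
        state = initialize(small_config(p_driver=1.0))
        daughters = state.occupied_indices()
        new = driver_phase(state, daughters, rng())
        assert len(new) == 1
        bits = state.registry.genotype_bits[new[0]]
        # every gene mutation is certain at p_driver = 1, but the already
        # truncal VHL is never re-acquired: one VHL allele in total
        gene_bits = int(np.sum(1 << np.flatnonzero(state.panel.gene_mask)))
        assert bits & gene_bits == gene_bits
        vhl = state.panel.event_id("VHL")
        alleles = [
            a
            for cl in range(state.registry.n_clones)
            for (ev, a) in state.registry.allele_ids[cl]
            if ev == vhl
        ]
        assert alleles == [0]

    def test_parallel_acquisitions_get_distinct_alleles(self):
        state = initialize(small_config(p_driver=1.0))
        c = state.config.L // 2
        second = state.flat(c + 1, c, c)
        state.add_voxel(second, 0, 0)
        daughters = state.occupied_indices()
        new = driver_phase(state, daughters, rng(1))
        assert len(new) == 2
        pb = state.panel.event_id("PBRM1")
        alleles = {
            a
            for cl in new
            for (ev, a) in state.registry.allele_ids[cl]
            if ev == pb
        }
        assert len(alleles) == 2  # two independent clones, two alleles


class TestNecrosis:
    def test_shallow_voxels_never_removed(self):
        state = fixture_lattice("sphere20")
        state.config.p_necrosis = 1.0
        state.refresh_depth()
        shallow = state.occupied_indices()[
            state.depth[state.occupied_indices()] <= 10
        ]
        removed = necrosis_phase(state, rng())
        assert not np.intersect1d(removed, shallow).size

    def test_deep_voxels_always_removed_at_p_one(self):
        state = fixture_lattice("sphere20")
        state.config.p_necrosis = 1.0
        state.refresh_depth()
        deep = np.flatnonzero(state.occ & (state.depth > 15.0))
        removed = necrosis_phase(state, rng())
        assert np.array_equal(np.sort(removed), np.sort(deep))

    def test_necrotic_fraction_matches_geometry(self):
        """Expected removals = 0.5 x (count deeper than 15 mm) on a ball."""
        state = fixture_lattice("sphere20")
        state.refresh_depth()
        n_deep = int((state.depth[state.occupied_indices()] > 15.0).sum())
        removed = len(necrosis_phase(state, rng(5)))
        lo, hi = stats.binom.ppf([0.005, 0.995], n_deep, 0.5)
        assert lo <= removed <= hi


class TestDepthField:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_exterior_distance(self, seed):
        """Depth equals brute-force distance to the exterior empty region."""
        g = rng(seed)
        cfg = small_config(L=16, stop_size=4000)
        state = initialize(cfg)
        blob = g.random((16, 16, 16)) < 0.35
        blob[(0, -1), :, :] = blob[:, (0, -1), :] = blob[:, :, (0, -1)] = False
        idx = np.flatnonzero(blob.ravel())
        state.occ[:] = blob.ravel()
        state.clone[:] = -1
        state.clone[idx] = 0
        state.n_voxels = len(idx)
        state.refresh_depth()
        # exterior: empty sites face-connected to the lattice border
        empty = ~blob
        lab, _ = ndimage.label(empty)
        border_labels = set(np.unique(lab[0])) | set(np.unique(lab[-1]))
        border_labels |= set(np.unique(lab[:, 0])) | set(np.unique(lab[:, -1]))
        border_labels |= set(np.unique(lab[:, :, 0])) | set(np.unique(lab[:, :, -1]))
        exterior = np.isin(lab, sorted(border_labels - {0}))
        tree = cKDTree(np.argwhere(exterior))
        expect, _ = tree.query(np.argwhere(blob))
        got = state.depth[idx]
        assert np.allclose(np.sort(got), np.sort(expect))

    def test_internal_cavity_does_not_count_as_surface(self):
        state = fixture_lattice("sphere20")
        c = state.L // 2
        centre = state.flat(c, c, c)
        state.remove_voxels(np.array([centre]))  # open a cavity at the core
        state.refresh_depth()
        neighbour = state.flat(c + 1, c, c)
        assert state.depth[neighbour] > 15.0


class TestStepAndRun:
    def test_frozen_dynamics_leave_state_unchanged(self):
        cfg = small_config(p_death=0.0, p_growth_initial=1e-12)
        state = initialize(cfg)
        occ_before = state.occ.copy()
        step(state)
        assert state.step_count == 1
        assert np.array_equal(state.occ, occ_before)

    def test_step_determinism(self):
        a = initialize(small_config(seed=9, growth_mode="volume"))
        b = initialize(small_config(seed=9, growth_mode="volume"))
        for _ in range(12):
            step(a)
            step(b)
        assert np.array_equal(a.occ, b.occ)
        assert np.array_equal(a.clone, b.clone)

    def test_occupancy_conservation(self):
        state = initialize(small_config(seed=4, growth_mode="volume", p_driver=6e-4))
        for _ in range(15):
            step(state)
            state.validate()

    def test_stop_size_one_terminates_immediately(self):
        cfg = small_config(stop_size=1)
        state, snaps = run(cfg)
        assert state.step_count == 0
        assert state.n_voxels == 1
        assert len(snaps) == 1

    def test_run_reaches_stop_size(self):
        cfg = SimulationConfig(
            L=40, stop_size=3000, seed=2, growth_mode="surface", max_steps=2000,
            p_driver=6e-4,
        )
        state, _ = run(cfg)
        assert state.n_voxels >= 3000

    def test_identical_config_gives_identical_snapshots(self, tmp_path):
        cfg = SimulationConfig(
            L=30, stop_size=800, seed=11, growth_mode="volume",
            max_steps=1000, snapshot_every=5, p_driver=6e-4,
        )
        _, snaps1 = run(cfg)
        _, snaps2 = run(cfg)
        assert len(snaps1) == len(snaps2)
        for i, (a, b) in enumerate(zip(snaps1, snaps2)):
            pa, pb = tmp_path / f"a{i}.tsv", tmp_path / f"b{i}.tsv"
            a.save(pa)
            b.save(pb)
            assert pa.read_bytes() == pb.read_bytes()


@pytest.fixture(scope="module")
def base_run():
    cfg = SimulationConfig(
        L=40, stop_size=3000, seed=3, growth_mode="surface",
        max_steps=2000, snapshot_every=10, p_driver=6e-4,
    )
    return run(cfg)


class TestSnapshotsAndReplay:
    def test_snapshot_roundtrip_lossless(self, base_run, tmp_path):
        _, snaps = base_run
        snap = snaps[len(snaps) // 2]
        p1 = tmp_path / "snap.tsv"
        snap.save(p1)
        back = Snapshot.load(p1)
        p2 = tmp_path / "snap2.tsv"
        back.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        restored = back.restore()
        restored.validate()
        assert restored.n_voxels == snap.n_voxels

    def test_resume_matches_uninterrupted_run(self, base_run):
        state, snaps = base_run
        mid = snaps[len(snaps) // 2]
        resumed, _ = run_state(mid.restore(), stop_size=3000)
        assert resumed.n_voxels == state.n_voxels
        assert resumed.step_count == state.step_count
        assert np.array_equal(resumed.occ, state.occ)
        assert np.array_equal(resumed.clone, state.clone)

    def test_replay_from_final_snapshot_returns_unchanged(self, base_run):
        state, snaps = base_run
        finals = replay(snaps[-1], [99], stop_size=state.n_voxels)
        assert finals[0].n_voxels == state.n_voxels
        assert np.array_equal(finals[0].occ, state.occ)

    def test_replay_replicates_diverge(self, base_run):
        _, snaps = base_run
        mid = snaps[len(snaps) // 2]
        finals = replay(mid, [101, 102, 103], stop_size=3000)
        occs = [f.occ for f in finals]
        assert not np.array_equal(occs[0], occs[1])
        assert not np.array_equal(occs[0], occs[2])

    def test_duplicate_seeds_rejected(self, base_run):
        _, snaps = base_run
        with pytest.raises(ValueError):
            replay(snaps[-1], [1, 1])


def test_stopping_size_geometry():
    """1e6 voxels of 1 mm^3 make a sphere of ~12.4 cm diameter."""
    d_mm = equivalent_spherical_diameter_mm(1_000_000)
    assert d_mm / 10 == pytest.approx(12.4, abs=0.05)
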