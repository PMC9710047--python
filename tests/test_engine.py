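"""Engine dynamics: binding, strides, collisions, release, determinism."""

import numpy as np
import pytest
from scipy import stats

from loopsim.barriers import ExtrusionBarrier, barrier_arrays
from loopsim.contacts import BandedContactMatrix
from loopsim.engine import (
    STALL_BARRIER,
    STALL_LEF,
    STALL_NONE,
    _Instance,
    detect_and_resolve_collisions,
    index_units,
    run_simulation,
    task_seed,
)
from loopsim.genome import SimulationConfig

from oracles import micro_step_resolve, random_system

NO_BARRIERS = barrier_arrays([])


def make_instance(L=1_000_000, n=20, barriers=(), config=None, seed=0):
    cfg = config or SimulationConfig(
        bin_size=5_000, diagonal_width=500_000, seed=seed
    )
    rng = np.random.default_rng(seed)
    return _Instance(L, n, barrier_arrays(list(barriers)), cfg, rng)


class TestBinding:
    def test_positions_uniform(self):
        inst = make_instance(n=100_000)
        inst.bind()
        pvalue = stats.kstest(inst.rev / inst.L, "uniform").pvalue
        assert pvalue > 0.01

    def test_new_lefs_have_zero_loop(self):
        inst = make_instance(n=50)
        inst.bind()
        assert np.all(inst.active)
        assert np.all(inst.rev == inst.fwd)

    def test_no_inactive_is_noop(self):
        inst = make_instance(n=5)
        inst.bind()
        rev = inst.rev.copy()
        inst.bind()
        assert np.array_equal(inst.rev, rev)

    def test_progressive_cap(self):
        inst = make_instance(n=100)
        inst.bind(max_bind=7)
        assert inst.active.sum() == 7


class TestIndexUnits:
    def test_sorted_input_unchanged(self):
        order, _ = index_units(np.array([1, 2, 3]), np.array([1, 2, 3]))
        assert np.array_equal(order, [0, 1, 2])

    def test_reversed_input_sorted(self):
        order, _ = index_units(np.array([3, 2, 1]), np.array([3, 2, 1]))
        assert np.array_equal(order, [2, 1, 0])

    def test_random_matches_argsort(self, rng):
        pos = rng.integers(0, 1000, 200)
        order, _ = index_units(pos, pos)
        assert np.array_equal(pos[order], np.sort(pos))


class TestMoves:
    def test_zero_sd_gives_exact_stride(self):
        cfg = SimulationConfig(stride_sd_fraction=0.0, seed=0)
        inst = make_instance(config=cfg)
        strides = inst.generate_moves(1_000)
        assert np.all(strides == cfg.mean_stride)

    def test_stride_mean_within_3_se(self):
        inst = make_instance()
        n = 100_000
        strides = inst.generate_moves(n)
        cfg = inst.cfg
        se = cfg.stride_sd_fraction * cfg.mean_stride / np.sqrt(n)
        assert abs(strides.mean() - cfg.mean_stride) < 3 * se

    def test_boundary_clip(self):
        new_rev, new_fwd, rstall, fstall = detect_and_resolve_collisions(
            np.array([100]), np.array([100]), np.array([500]), np.array([10**6]),
            1_000, np.array([], dtype=int), np.array([], dtype=bool),
            np.array([], dtype=bool),
        )
        assert new_rev[0] == 0 and new_fwd[0] == 999


class TestCollisions:
    def test_bound_blocking_barrier_stalls_one_bp_short(self):
        # forward unit at 10 kbp, bound '-' barrier at 12 kbp, stride 5 kbp
        rev, fwd, rs, fs = detect_and_resolve_collisions(
            np.array([10_000]), np.array([10_000]),
            np.array([0]), np.array([5_000]),
            100_000, np.array([12_000]), np.array([False]), np.array([True]),
        )
        assert fwd[0] == 11_999 and fs[0] == STALL_BARRIER

    def test_unbound_barrier_is_transparent(self):
        rev, fwd, rs, fs = detect_and_resolve_collisions(
            np.array([10_000]), np.array([10_000]),
            np.array([0]), np.array([5_000]),
            100_000, np.array([12_000]), np.array([False]), np.array([False]),
        )
        assert fwd[0] == 15_000 and fs[0] == STALL_NONE

    def test_wrong_direction_barrier_is_transparent(self):
        # a '+' barrier blocks reverse units only
        rev, fwd, rs, fs = detect_and_resolve_collisions(
            np.array([10_000]), np.array([10_000]),
            np.array([0]), np.array([5_000]),
            100_000, np.array([12_000]), np.array([True]), np.array([True]),
        )
        assert fwd[0] == 15_000 and fs[0] == STALL_NONE

    def test_approaching_units_split_gap(self):
        # fwd unit of LEF 0 at 1000, rev unit of LEF 1 at 2001: gap 1000,
        # both with ample stride -> stop adjacent, extra bp to the left unit
        rev, fwd, rs, fs = detect_and_resolve_collisions(
            np.array([0, 2_001]), np.array([1_000, 3_000]),
            np.array([0, 5_000]), np.array([5_000, 0]),
            100_000, np.array([], dtype=int), np.array([], dtype=bool),
            np.array([], dtype=bool),
        )
        assert fwd[0] == 1_500 and rev[1] == 1_501
        assert fs[0] == STALL_LEF and rs[1] == STALL_LEF

    def test_units_of_one_lef_never_cross(self, rng):
        for _ in range(50):
            args = random_system(rng, chrom_length=50_000, max_lefs=8)
            new_rev, new_fwd, _, _ = detect_and_resolve_collisions(*args)
            assert np.all(new_rev <= new_fwd)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equivalence_with_micro_stepping_oracle(self, seed):
        """Closed-form resolver == 1-bp micro-stepping on random systems."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            args = random_system(rng)
            got = detect_and_resolve_collisions(*args)
            expected = micro_step_resolve(*args)
            for g, e in zip(got, expected):
                assert np.array_equal(g, e)


class TestRelease:
    def test_lifetime_is_geometric_with_expected_mean(self):
        """Mean LEF lifetime = processivity / (2 * stride) epochs, and the
        lifetime distribution passes a chi-square goodness-of-fit test."""
        cfg = SimulationConfig(
            bin_size=5_000, processivity=200_000, seed=3
        )  # release p = 0.05, mean lifetime 20 epochs
        inst = make_instance(L=100_000_000, n=20_000, config=cfg, seed=3)
        inst.bind()
        # one un-replenished cohort, followed until (almost surely) everyone
        # has been released, so lifetimes are uncensored
        ages = np.zeros(inst.n, dtype=int)
        lifetimes = []
        for _ in range(600):
            ages[inst.active] += 1
            before = inst.active.copy()
            inst.release()
            released = before & ~inst.active
            lifetimes.extend(ages[released])
            if not inst.active.any():
                break
        lifetimes = np.asarray(lifetimes)
        assert lifetimes.size == inst.n
        assert lifetimes.mean() == pytest.approx(20.0, abs=0.5)

        # chi-square against Geometric(0.05), pooled tail
        edges = np.arange(1, 61, 5)
        observed, _ = np.histogram(lifetimes, bins=list(edges) + [np.inf])
        p = 0.05
        cdf = lambda k: 1 - (1 - p) ** k
        probs = np.diff([cdf(e - 1) for e in edges] + [1.0])
        expected = probs * lifetimes.size
        chi2 = ((observed - expected) ** 2 / expected).sum()
        crit = stats.chi2.ppf(0.99, df=len(observed) - 1)
        assert chi2 < crit

    def test_neutral_multiplier_ignores_stall(self):
        cfg = SimulationConfig(hard_stall_lifetime_multiplier=1.0, seed=1)
        inst = make_instance(n=2_000, config=cfg, seed=1)
        inst.bind()
        inst.rev_stall[:1_000] = STALL_BARRIER
        inst.fwd_stall[:1_000] = STALL_BARRIER
        released = []
        for _ in range(50):
            before = inst.active.copy()
            inst.release()
            released.append((before & ~inst.active))
            inst.active[:] = True
        released = np.stack(released)
        r_stalled = released[:, :1_000].mean()
        r_free = released[:, 1_000:].mean()
        assert r_stalled == pytest.approx(r_free, rel=0.15)

    def test_hard_stall_extends_lifetime(self):
        cfg = SimulationConfig(hard_stall_lifetime_multiplier=5.0, seed=1)
        inst = make_instance(n=20_000, config=cfg, seed=1)
        inst.bind()
        inst.rev_stall[:10_000] = STALL_BARRIER
        inst.fwd_stall[:10_000] = STALL_BARRIER
        before = inst.active.copy()
        inst.release()
        released = before & ~inst.active
        assert released[:10_000].mean() < released[10_000:].mean() / 2

    def test_infinite_processivity_never_releases(self):
        cfg = SimulationConfig(processivity=1e18, seed=0)
        inst = make_instance(n=100, config=cfg)
        inst.bind()
        for _ in range(200):
            inst.release()
        assert np.all(inst.active)


class TestContactSampling:
    def _pinned(self, cfg, rev, fwd):
        inst = make_instance(L=1_000_000, n=1, config=cfg)
        inst.active[0] = True
        inst.rev[0], inst.fwd[0] = rev, fwd
        return inst

    def test_loop_only_pinned_lef_hits_single_pixel(self):
        cfg = SimulationConfig(
            bin_size=5_000, diagonal_width=500_000, contact_sampling_fraction=1.0,
            seed=0,
        )
        inst = self._pinned(cfg, 100_000, 400_000)
        m = BandedContactMatrix(1_000_000, 5_000, 500_000)
        for _ in range(1_000):
            inst.sample_contacts(m, mode="loop-only")
        assert m.total == 1_000
        assert m.get(100_000 // 5_000, 400_000 // 5_000) == 1_000

    def test_zero_loop_contact_on_diagonal(self):
        cfg = SimulationConfig(contact_sampling_fraction=1.0, seed=0)
        inst = self._pinned(cfg, 250_000, 250_000)
        m = BandedContactMatrix(1_000_000, 5_000, 500_000)
        inst.sample_contacts(m, mode="loop-only")
        assert m.get(50, 50) == 1

    def test_tad_only_contacts_uniform_within_loop(self):
        cfg = SimulationConfig(
            bin_size=5_000, diagonal_width=1_000_000,
            contact_sampling_fraction=1.0, tad_to_loop_contact_ratio=1.0, seed=0,
        )
        inst = self._pinned(cfg, 100_000, 400_000)

        class RecordingMatrix(BandedContactMatrix):
            recorded = []

            def add_pairs(self, p1, p2, weight=1):
                self.recorded.extend(np.concatenate([p1, p2]).tolist())
                return super().add_pairs(p1, p2, weight)

        m = RecordingMatrix(1_000_000, 5_000, 1_000_000)
        for _ in range(50_000):
            inst.sample_contacts(m, mode="tad-only")
        samples = np.asarray(m.recorded)
        assert samples.min() >= 100_000 and samples.max() <= 400_000
        u = (samples - 100_000) / (400_000 - 100_000)
        pvalue = stats.kstest(u, "uniform").pvalue
        assert pvalue > 0.01


class TestBurnIn:
    def test_no_contacts_during_burn_in(self):
        inst = make_instance(n=20)
        epochs = inst.burn_in()
        assert epochs > 0  # burn-in actually ran, with no matrix to fill

    def test_hard_cap_respected(self):
        cfg = SimulationConfig(
            burn_in_max_epochs=40, burn_in_tolerance=-1.0, seed=0
        )
        inst = make_instance(n=20, config=cfg)
        assert inst.burn_in() == 40

    def test_loop_sizes_grow_during_burn_in(self):
        # low density so crowding does not cap the loops
        inst = make_instance(L=10_000_000, n=5)
        inst.burn_in()
        assert inst.mean_loop_size() > 5 * inst.cfg.mean_stride


class TestSafetyInvariants:
    def test_epoch_audit(self):
        """rev <= fwd, positions in range, after many busy epochs."""
        barriers = [
            ExtrusionBarrier("chrT", p, "+" if k % 2 == 0 else "-", 0.9, 0.7)
            for k, p in enumerate(range(50_000, 1_000_000, 90_000))
        ]
        inst = make_instance(L=1_000_000, n=50, barriers=barriers, seed=11)
        m = BandedContactMatrix(1_000_000, 5_000, 500_000)
        for _ in range(200):
            inst.epoch(matrix=m)
            act = inst.active
            assert np.all(inst.rev[act] <= inst.fwd[act])
            assert np.all(inst.rev[act] >= 0)
            assert np.all(inst.fwd[act] < inst.L)


class TestRunSimulation:
    def test_same_seed_identical_output(self, toy_spec, fast_config):
        r1 = run_simulation(toy_spec.chromosomes, toy_spec.barriers(), fast_config)
        r2 = run_simulation(toy_spec.chromosomes, toy_spec.barriers(), fast_config)
        for name in r1.matrices:
            assert np.array_equal(r1.matrices[name].counts, r2.matrices[name].counts)

    def test_worker_count_does_not_change_results(self, toy_spec, fast_config):
        r1 = run_simulation(
            toy_spec.chromosomes, toy_spec.barriers(), fast_config, workers=1
        )
        r2 = run_simulation(
            toy_spec.chromosomes, toy_spec.barriers(), fast_config, workers=2
        )
        for name in r1.matrices:
            assert np.array_equal(r1.matrices[name].counts, r2.matrices[name].counts)

    def test_density_stopping_rule(self, toy_spec, fast_config):
        result = run_simulation(toy_spec.chromosomes, [], fast_config)
        for m in result.matrices.values():
            assert m.mean_contact_density() >= fast_config.target_contact_density

    def test_epoch_stopping_rule(self, toy_spec, fast_config):
        cfg = fast_config.replace(target_epochs=30, target_contact_density=None)
        result = run_simulation(toy_spec.chromosomes, [], cfg)
        assert result.report["total_epochs"] == 30 * cfg.ncells

    def test_unknown_barrier_chromosome_rejected(self, toy_spec, fast_config):
        bad = [ExtrusionBarrier("chrNOPE", 100, "+", 0.5)]
        with pytest.raises(ValueError, match="chrNOPE"):
            run_simulation(toy_spec.chromosomes, bad, fast_config)

    def test_no_chromosomes_rejected(self, fast_config):
        with pytest.raises(ValueError, match="no chromosomes"):
            run_simulation([], [], fast_config)

    def test_convergent_pair_forms_dot(self, toy_spec, fast_config):
        """Contacts at the (left, right) barrier pixel are enriched vs. a
        barrier-free paired run with the same seeds."""
        cfg = fast_config.replace(target_contact_density=2.0)
        with_b = run_simulation(toy_spec.chromosomes, toy_spec.barriers(), cfg)
        without = run_simulation(toy_spec.chromosomes, [], cfg)
        (chrom,) = toy_spec.chromosomes
        (left, right) = [b.position for b in toy_spec.barriers()]
        bs = cfg.bin_size
        # anchors stall 1 bp inside the pair
        i, j = (left + 1) // bs, (right - 1) // bs

        def dot_mass(result):
            m = result.matrices[chrom.name]
            return sum(
                m.get(i + di, j + dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            ) / max(m.total, 1)

        assert dot_mass(with_b) > 2 * dot_mass(without)

    def test_deleted_region_removes_dot(self, toy_spec, fast_config):
        from loopsim.genome import GenomicInterval

        cfg = fast_config.replace(target_contact_density=2.0)
        (left, right) = [b.position for b in toy_spec.barriers()]
        wt = run_simulation(toy_spec.chromosomes, toy_spec.barriers(), cfg)
        mut = run_simulation(
            toy_spec.chromosomes, toy_spec.barriers(), cfg,
            deleted_regions=[GenomicInterval("chrS1", left - 10, left + 10)],
        )
        bs = cfg.bin_size
        i, j = (left + 1) // bs, (right - 1) // bs

        def dot(m):
            return sum(
                m.get(i + di, j + dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            )

        assert dot(mut.matrices["chrS1"]) < dot(wt.matrices["chrS1"])

    def test_task_seed_is_pure_function(self):
        s1 = task_seed(5, "chr1", 3).generate_state(4)
        s2 = task_seed(5, "chr1", 3).generate_state(4)
        s3 = task_seed(5, "chr1", 4).generate_state(4)
        assert np.array_equal(s1, s2)
        assert not np.array_equal(s1, s3)


class TestTracks:
    def test_track_sum_equals_unit_visits(self, toy_spec, fast_config):
        result = run_simulation(
            toy_spec.chromosomes, toy_spec.barriers(), fast_config,
            record_tracks=True,
        )
        track = result.lef_tracks["chrS1"]
        assert track.sum() > 0
        # every sampled epoch contributes 2 visits per active LEF at most
        assert track.sum() <= 2 * result.report["total_epochs"] * 20

    def test_barrier_bins_accumulate_units(self, toy_spec, fast_config):
        """Strong convergent barriers pile up extrusion units locally."""
        toy_spec.occupancy = 0.95
        result = run_simulation(
            toy_spec.chromosomes, toy_spec.barriers(), fast_config,
            record_tracks=True,
        )
        track = result.lef_tracks["chrS1"].astype(float)
        positions = [b.position // 1_000 for b in toy_spec.barriers()]
        at_barriers = np.mean([track[p - 1 : p + 2].max() for p in positions])
        background = np.median(track[track > 0])
        assert at_barriers > 2 * background
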