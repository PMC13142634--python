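import math

import numpy as np
import pytest
from scipy import stats

from ecdnasim.hazards import HazardModel, SegregationModel
from ecdnasim.ssa import (
    Population,
    SimulationConfig,
    enforce_capacity,
    predict_phase_occupancy,
    run_ssa,
)

NEUTRAL_SEG = SegregationModel(mode="fixed", r_mean=0.5, orientation="random")


def constant_hazards(b, d):
    return HazardModel(
        alpha_div=math.log(b),
        beta_div=0.0,
        alpha_death=math.log(max(d, 1e-12)),
        beta_death=0.0,
        rate_min=1e-12,
        rate_max=10.0,
    )


class TestSSADynamics:
    def test_critical_birth_death_population_martingale(self):
        # b = d: E[N(t)] = N(0)
        haz = constant_hazards(0.02, 0.02)
        sizes = []
        for seed in range(200):
            cfg = SimulationConfig(n_max=5000, n_target=2500, snapshot_generations=(50,), t_max=100.0, seed=seed)
            snaps = run_ssa(Population(np.full(500, 300)), haz, NEUTRAL_SEG, cfg)
            sizes.append(len(snaps.final) if snaps.final is not None else 0)
        mean = float(np.mean(sizes))
        se = float(np.std(sizes)) / math.sqrt(len(sizes))
        assert abs(mean - 500) < max(4 * se, 10)

    def test_yule_process_mean_growth(self):
        # pure birth: E[N(t)] = N(0) exp(bt)
        haz = constant_hazards(0.02, 1e-12)
        b, t = 0.02, 60.0
        sizes = []
        for seed in range(60):
            cfg = SimulationConfig(n_max=10_000, n_target=5000, snapshot_generations=(50,), t_max=t, seed=seed)
            snaps = run_ssa(Population(np.full(200, 300)), haz, NEUTRAL_SEG, cfg)
            sizes.append(len(snaps.final))
        expected = 200 * math.exp(b * t)
        assert np.mean(sizes) == pytest.approx(expected, rel=0.05)

    def test_neutral_copy_number_mean_is_martingale(self):
        haz = constant_hazards(0.02, 0.005)
        means = []
        for seed in range(100):
            cfg = SimulationConfig(n_max=5000, n_target=2500, snapshot_generations=(3,), t_max=1e6, seed=seed)
            snaps = run_ssa(Population(np.full(300, 300)), haz, NEUTRAL_SEG, cfg)
            means.append(float(snaps[-1].copies.mean()))
        grand = float(np.mean(means))
        se = float(np.std(means)) / 10.0
        assert abs(grand - 300.0) < max(4 * se, 3.0)

    def test_division_bias_increases_mean_copy_number(self):
        # selection acts on standing variance, so start from a dispersed population
        haz = HazardModel(alpha_div=-6.0, beta_div=0.35, alpha_death=math.log(0.004), beta_death=0.0)
        init = np.round(np.random.default_rng(0).lognormal(math.log(300), 0.7, 300)).astype(int)
        means = []
        for seed in range(40):
            cfg = SimulationConfig(n_max=4000, n_target=2000, snapshot_generations=(3,), t_max=1e6, seed=seed)
            snaps = run_ssa(Population(init), haz, NEUTRAL_SEG, cfg)
            means.append(float(snaps[-1].copies.mean()))
        t = stats.ttest_1samp(means, float(init.mean()))
        assert np.mean(means) > init.mean() and t.pvalue < 1e-6

    def test_first_event_time_is_exponential(self):
        # single cell, division-only: the generation-1 snapshot time is the
        # first event time, distributed Exponential(b)
        haz = constant_hazards(0.05, 1e-12)
        times = []
        for seed in range(10_000):
            cfg = SimulationConfig(n_max=10, n_target=5, snapshot_generations=(1,), t_max=1e6, seed=seed)
            snaps = run_ssa(Population(np.array([100])), haz, NEUTRAL_SEG, cfg)
            times.append(snaps[0].time)
        ks = stats.kstest(times, "expon", args=(0, 1 / 0.05))
        assert ks.pvalue > 0.01

    def test_snapshots_ordered_and_deterministic(self):
        haz = constant_hazards(0.02, 0.005)
        cfg = SimulationConfig(n_max=2000, n_target=1000, snapshot_generations=(0, 1, 2, 3), t_max=1e6, seed=42)
        a = run_ssa(Population(np.full(400, 250)), haz, NEUTRAL_SEG, cfg)
        b = run_ssa(Population(np.full(400, 250)), haz, NEUTRAL_SEG, cfg)
        gens = [s.generation for s in a]
        times = [s.time for s in a]
        assert gens == sorted(gens)
        assert all(t2 > t1 for t1, t2 in zip(times[1:-1], times[2:]))  # first snapshot at t=0
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa.time == sb.time
            assert np.array_equal(sa.copies, sb.copies)

    def test_extinction_is_flagged_not_raised(self):
        haz = constant_hazards(1e-6, 0.5)
        cfg = SimulationConfig(n_max=100, n_target=50, snapshot_generations=(5,), t_max=1e6, seed=7)
        snaps = run_ssa(Population(np.full(5, 100)), haz, NEUTRAL_SEG, cfg)
        assert snaps.status == "extinct"
        assert len(snaps) == 0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            run_ssa(Population(np.array([], dtype=int)), HazardModel(), NEUTRAL_SEG, SimulationConfig())


class TestCapacity:
    def test_below_capacity_unchanged(self, rng):
        pop = Population(np.arange(900))
        cfg = SimulationConfig(n_max=1000, n_target=500)
        assert enforce_capacity(pop, cfg, rng) is pop

    def test_bottleneck_size_and_unbiasedness(self):
        source = np.random.default_rng(3).integers(0, 1000, size=2000)
        cfg = SimulationConfig(n_max=1500, n_target=1000)
        means = []
        for seed in range(500):
            out = enforce_capacity(Population(source), cfg, np.random.default_rng(seed))
            assert len(out) == 1000
            means.append(float(out.copies.mean()))
        assert np.mean(means) == pytest.approx(source.mean(), rel=0.005)

    def test_same_seed_same_subsample(self):
        pop = Population(np.arange(3000))
        cfg = SimulationConfig(n_max=1000, n_target=400)
        a = enforce_capacity(pop, cfg, np.random.default_rng(9))
        b = enforce_capacity(pop, cfg, np.random.default_rng(9))
        assert np.array_equal(a.copies, b.copies)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_target=0)


class TestPhaseOccupancy:
    def test_direct_formula(self):
        haz = constant_hazards(0.02, 0.001)
        assert predict_phase_occupancy(300, haz, t_fixed=10.0) == pytest.approx(10.0 / 60.0, rel=1e-9)

    def test_vanishes_for_slow_cycles(self):
        haz = HazardModel(alpha_div=-30.0, beta_div=0.0, rate_min=1e-9)
        assert predict_phase_occupancy(10, haz, t_fixed=10.0) < 1e-4

    def test_monotone_in_dosage_under_division_bias(self):
        haz = HazardModel(alpha_div=-6.0, beta_div=0.4, rate_min=1e-9, rate_max=5.0)
        ks = np.arange(0, 1001)
        occ = predict_phase_occupancy(ks, haz, t_fixed=10.0)
        assert np.all(np.diff(occ) > 0)
        assert np.all(occ < 1.0)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            predict_phase_occupancy(10, HazardModel(), t_fixed=0.0)
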