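import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecdnasim.inference import (
    DEFAULT_BOUNDS,
    PARAM_NAMES,
    FitnessEvaluator,
    FitnessTargets,
    GAConfig,
    ModelVariant,
    ga_fit,
    histogram_kl,
    params_to_models,
)
from ecdnasim.initsort import CopyNumberSample


def kl_brute_force(p, q, n_bins, pseudocount):
    """Independent direct summation on explicitly computed shared bins."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if hi <= lo:
        hi = lo + 1.0
    width = (hi - lo) / n_bins
    total = 0.0
    for b in range(n_bins):
        left = lo + b * width
        right = hi if b == n_bins - 1 else left + width
        cp = np.sum((p >= left) & (p < right)) + (np.sum(p == hi) if b == n_bins - 1 else 0)
        cq = np.sum((q >= left) & (q < right)) + (np.sum(q == hi) if b == n_bins - 1 else 0)
        pb = (cp + pseudocount) / (p.size + n_bins * pseudocount)
        qb = (cq + pseudocount) / (q.size + n_bins * pseudocount)
        if pb > 0:
            total += pb * math.log(pb / qb)
    return total


class TestHistogramKL:
    def test_identical_samples_zero(self, rng):
        x = rng.integers(0, 500, 200)
        assert histogram_kl(x, x.copy()) == pytest.approx(0.0, abs=1e-14)

    def test_two_bin_hand_computation(self):
        # P = (1/2, 1/2) vs Q = (1/4, 3/4): 0.5 ln2 + 0.5 ln(2/3)
        p = np.array([0, 0, 10, 10])
        q = np.array([0, 10, 10, 10])
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert histogram_kl(p, q, n_bins=2, pseudocount=0.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1438, abs=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_non_negative_and_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        p = r.integers(0, 400, r.integers(5, 60))
        q = r.integers(0, 400, r.integers(5, 60))
        val = histogram_kl(p, q, n_bins=10, pseudocount=0.5)
        assert val >= -1e-12
        assert val == pytest.approx(kl_brute_force(p, q, 10, 0.5), abs=1e-12)

    def test_target_anchored_bins_resolve_masked_shape_mismatch(self, rng):
        # a far outlier tail stretches pooled bins until an in-range shift
        # becomes invisible; target-anchored bins keep resolving it
        target = rng.integers(100, 300, 150)
        shifted = np.concatenate([rng.integers(300, 500, 140), rng.integers(40_000, 50_000, 10)])
        pooled = histogram_kl(target, shifted, bin_source="pooled")
        anchored = histogram_kl(target, shifted, bin_source="p")
        assert pooled < 0.5  # the mismatch is masked
        assert anchored > 2 * pooled

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            histogram_kl(np.array([1]), np.array([2]), n_bins=1)


class TestModelVariants:
    def test_named_variant_restrictions(self):
        neutral = ModelVariant.from_name("neutral")
        assert neutral.fixed == {"beta_div": 0.0, "beta_death": 0.0, "r_mean": 0.5, "r_sd": 0.0}
        div_only = ModelVariant.from_name("division_bias_only")
        assert div_only.fixed == {"r_mean": 0.5, "r_sd": 0.0}
        inh_only = ModelVariant.from_name("inheritance_bias_only")
        assert inh_only.fixed == {"beta_div": 0.0, "beta_death": 0.0}
        assert ModelVariant.from_name("both").free_parameters == PARAM_NAMES

    def test_apply_overrides_fixed_genes(self):
        v = ModelVariant.from_name("neutral")
        out = v.apply({name: 0.42 for name in PARAM_NAMES})
        assert out["beta_div"] == 0.0 and out["r_mean"] == 0.5
        assert out["log_div_rate"] == 0.42

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant.from_name("frequentist")

    def test_params_to_models_anchoring(self):
        params = dict(
            log_div_rate=math.log(0.02), beta_div=0.4, log_death_rate=math.log(0.005),
            beta_death=1.0, r_mean=0.6, r_sd=0.1,
        )
        haz, seg = params_to_models(params)
        from ecdnasim.hazards import hazard

        assert hazard(300, haz, "division") == pytest.approx(0.02, rel=1e-9)
        assert hazard(300, haz, "death") == pytest.approx(0.005, rel=1e-9)
        assert seg.r_mean == 0.6


class TestGA:
    def toy_variant(self):
        fixed = {n: 0.0 for n in PARAM_NAMES if n != "beta_div"}
        fixed["r_mean"] = 0.5
        return ModelVariant("toy", fixed)

    def test_recovers_toy_optimum_against_grid_oracle(self):
        objective = lambda p: -((p["beta_div"] - 0.37) ** 2)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        oracle = grid[np.argmax(-((grid - 0.37) ** 2))]
        bounds = dict(DEFAULT_BOUNDS, beta_div=(0.0, 1.0))
        cfg = GAConfig(pop_size=40, max_generations=60, stall_limit=60, seed=3, bounds=bounds)
        res = ga_fit(self.toy_variant(), None, cfg, evaluator=objective)
        assert abs(res.best_params["beta_div"] - oracle) <= 0.01

    def test_fitness_trace_non_decreasing_with_elitism(self):
        objective = lambda p: -((p["beta_div"] - 0.8) ** 2)
        cfg = GAConfig(pop_size=16, max_generations=25, stall_limit=25, elitism=2, seed=11)
        res = ga_fit(self.toy_variant(), None, cfg, evaluator=objective)
        assert np.all(np.diff(res.fitness_trace) >= 0)

    def test_fixed_genes_never_mutate(self):
        seen = []

        def spy(params):
            seen.append(dict(params))
            return -((params["beta_div"] - 0.5) ** 2)

        variant = ModelVariant("spy", {"r_mean": 0.5, "r_sd": 0.0, "beta_death": 0.125})
        cfg = GAConfig(pop_size=12, max_generations=10, stall_limit=10, seed=2)
        ga_fit(variant, None, cfg, evaluator=spy)
        assert len(seen) > 100
        for p in seen:
            assert p["r_mean"] == 0.5 and p["r_sd"] == 0.0 and p["beta_death"] == 0.125

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(bounds={"beta_div": (1.0, 0.0)})

    def test_missing_bounds_for_free_gene_rejected(self):
        cfg = GAConfig(bounds={"beta_div": (0.0, 1.0)})
        with pytest.raises(ValueError, match="bounds"):
            ga_fit(ModelVariant.from_name("both"), None, cfg, evaluator=lambda p: 0.0)


class TestFitnessTargets:
    def make_targets(self, rng):
        mk = lambda lo, hi: CopyNumberSample(rng.integers(lo, hi, 150))
        recovery = {
            ("high", 0): mk(300, 900),
            ("high", 1): mk(250, 800),
            ("low", 0): mk(20, 200),
            ("low", 1): mk(40, 260),
        }
        return FitnessTargets(
            steady_state=mk(50, 700),
            recovery=recovery,
            control_reference=mk(50, 700),
            steady_generation=2,
        )

    def test_both_weights_zero_rejected(self, rng):
        t = self.make_targets(rng)
        with pytest.raises(ValueError):
            FitnessTargets(
                steady_state=t.steady_state,
                recovery=t.recovery,
                control_reference=t.control_reference,
                weight_steady=0.0,
                weight_recovery=0.0,
            )

    def test_unknown_recovery_group_rejected(self, rng):
        t = self.make_targets(rng)
        with pytest.raises(ValueError):
            FitnessTargets(
                steady_state=t.steady_state,
                recovery={("mid", 1): t.steady_state},
                control_reference=t.control_reference,
            )

    def test_extinction_penalized_not_raised(self, rng):
        from ecdnasim.ssa import SimulationConfig

        t = self.make_targets(rng)
        ev = FitnessEvaluator(t, SimulationConfig(n_max=400, n_target=200, t_max=1e6, seed=4), n_replicates=1)
        lethal = dict(
            log_div_rate=math.log(0.004), beta_div=0.0, log_death_rate=math.log(0.08),
            beta_death=0.0, r_mean=0.5, r_sd=0.0,
        )
        score, _ = ev.evaluate(lethal)
        assert math.isfinite(score)
        assert score <= -1000

    def test_truth_outscores_neutral_on_biased_targets(self):
        from ecdnasim.experiments import recovery_study, FIT_SIM, SCORED_GENERATIONS, N_BINS
        from ecdnasim.synthetic import make_fitness_targets
        from dataclasses import replace

        study = recovery_study(777)
        targets = make_fitness_targets(study, recovery_generations=SCORED_GENERATIONS, n_bins=N_BINS)
        ev = FitnessEvaluator(targets, replace(FIT_SIM, seed=9), n_replicates=2)
        ht, st_ = study.truth["hazard"], study.truth["segregation"]
        lk = math.log1p(300.0)
        truth = dict(
            log_div_rate=ht.alpha_div + ht.beta_div * lk,
            beta_div=ht.beta_div,
            log_death_rate=ht.alpha_death + ht.beta_death * lk,
            beta_death=ht.beta_death,
            r_mean=st_.r_mean,
            r_sd=st_.r_sd,
        )
        neutral = dict(truth, beta_div=0.0, beta_death=0.0, r_mean=0.5, r_sd=0.0)
        s_truth, _ = ev.evaluate(truth)
        s_neutral, _ = ev.evaluate(neutral)
        assert s_truth > s_neutral


class TestGeneticFitter:
    def test_fit_sets_fitted_attributes(self):
        from ecdnasim.experiments import recovery_study
        from ecdnasim.inference import GeneticFitter
        from ecdnasim.ssa import SimulationConfig
        from ecdnasim.synthetic import make_fitness_targets

        study = recovery_study(550)
        targets = make_fitness_targets(study, recovery_generations=(1,), n_bins=12)
        fitter = GeneticFitter(
            variant="both",
            ga_config=GAConfig(pop_size=6, max_generations=2, stall_limit=2, seed=1),
            sim_config=SimulationConfig(n_max=400, n_target=200, t_max=1e6, seed=2),
        )
        assert fitter.fit(targets) is fitter
        assert set(fitter.best_params_) == set(PARAM_NAMES)
        assert np.all(np.diff(fitter.fitness_trace_) >= 0)
        assert "steady" in fitter.kl_terms_
        assert fitter.hazard_model_().beta_div == fitter.best_params_["beta_div"]
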