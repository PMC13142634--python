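# ecdnasim

Stochastic modeling of extrachromosomal DNA (ecDNA) copy-number evolution
in cancer cell populations.

ecDNA elements are circular, acentric DNA bodies carrying amplified
oncogenes. Lacking centromeres, they are *not* split evenly at mitosis:
after duplication, the 2k copies of a cell with k copies are partitioned
between daughters by a binomial draw whose success probability may be
biased away from ½. This non-Mendelian inheritance, combined with
dosage-dependent cell fitness, produces the broad, right-skewed, heritable
copy-number spectra seen by metaphase FISH — and lets a population rebuild
that full spectrum within a few generations after being sorted into
high- and low-dosage fractions.

`ecdnasim` is for computational cancer biologists who want to simulate,
perturb, and fit these dynamics:

- an exact Gillespie (direct-method) birth–death simulator where each
  cell's division and death hazards are log-linear in a dosage transform,
  `rate(k) = clamp(exp(α + β·ln(1+k)), r_min, r_max)`, and mitotic
  partitioning is `k₁ ~ Binomial(2k, p)` with the daughter fraction `p`
  fixed at 0.5 (unbiased) or drawn from a truncated Gaussian centered
  near 0.6 (biased), with a fair coin deciding which daughter is favored;
- initialization of realistic populations from small FISH count tables
  (truncated Gaussian KDE + Metropolis–Hastings upsampling);
- a virtual FACS sort that gates cells on a noisy multiplicative proxy of
  dosage, emulating sorting on an ecDNA-encoded surface protein;
- genetic-algorithm inference of hazard and segregation parameters from
  steady-state and post-sort recovery distributions, scored by histogram
  Kullback–Leibler divergence;
- model comparison (neutral / division-bias / inheritance-bias / both) by
  1-D Wasserstein distance, a bootstrap criterion for the generation at
  which a sorted population is indistinguishable from control, and a
  sister-cell partitioning-asymmetry statistic;
- a synthetic-study generator that emulates the empirical design
  (~150 cells per condition at 0/48/96/432 h post-sort, i.e. generations
  0/1/2/9) with known ground-truth parameters, for closed-loop validation.

## Worked example

Sort a simulated population on a noisy dosage proxy and watch the sorted
fractions re-converge to the control distribution:

```python
import numpy as np
from ecdnasim import (
    BaselineSpec, generate_baseline_counts, fit_kde, mh_upsample, MHConfig,
    virtual_facs, DEFAULT_STUDY_SORT, Population, SimulationConfig, run_ssa,
    wasserstein_1d,
)
from ecdnasim.synthetic import calibrated_truth

baseline = generate_baseline_counts(BaselineSpec(seed=7))        # 150 FISH-like counts
pop = mh_upsample(fit_kde(baseline), 2000, MHConfig(seed=7))     # KDE + MH upsample
gates = virtual_facs(pop, DEFAULT_STUDY_SORT, np.random.default_rng(7))
haz, seg = calibrated_truth(gates["high"].median, gates["low"].median,
                            baseline.median)                     # 60% division advantage, r = 0.6
for j, grp in enumerate(("high", "low", "control")):
    cfg = SimulationConfig(n_max=4000, n_target=2000,
                           snapshot_generations=(0, 1, 2, 3), t_max=1e6, seed=70 + j)
    snaps = run_ssa(Population(gates[grp].counts), haz, seg, cfg)
```

With seed 7 this prints, per generation, the Wasserstein distance of each
sorted arm to the same-generation control:

```
g0: W1(high,ctrl)=106.7  W1(low,ctrl)=112.4  means h/l/c = 417/197/310
g1: W1(high,ctrl)= 35.9  W1(low,ctrl)= 74.8  means h/l/c = 282/178/250
g2: W1(high,ctrl)= 29.9  W1(low,ctrl)= 57.2  means h/l/c = 248/162/219
g3: W1(high,ctrl)= 29.8  W1(low,ctrl)= 48.0  means h/l/c = 229/151/199
```

The initially separated high (417 copies on average) and low (197) arms
collapse toward the control arm within two to three generations — the
dosage continuum is rebuilt by biased segregation spreading each lineage
while dosage-dependent division and death pull both tails back toward the
bulk.

A command-line interface exposes the same pipeline
(`ecdnasim synth | sort | simulate | fit | evaluate`); see
`ecdnasim --help`.

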