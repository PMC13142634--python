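# Methods

## Model

The population is a continuous-time Markov branching process with a soft
carrying capacity. Each cell carries an integer ecDNA copy number `k ≥ 0`
and fires two kinds of events:

- **division** at hazard `b(k) = clamp(exp(α_b + β_b·T(k)), r_min, r_max)`,
- **death** at hazard `d(k) = clamp(exp(α_d + β_d·T(k)), r_min, r_max)`,

with the dosage transform `T(k) = ln(1 + k)` by default (a power-law-like
dependence that stays finite over the observed 0–2,000+ copy range; a
linear transform `k / k_scale` is available by configuration). Zero slopes
recover the neutral model with dosage-independent rates. Rates are in
events per hour; the default neutral division rate 0.02/h makes one
population doubling ≈ 50 h, matching the roughly one-generation-per-48 h
experimental time course. Hard clamps (defaults 10⁻⁴ and 1.0 events/h)
guard against numerical runaway for extreme parameter candidates.

At division all copies are first duplicated; the `2k` copies are then
partitioned between the daughters as `k₁ ~ Binomial(2k, p)`,
`k₂ = 2k − k₁`. The daughter fraction `p` is either fixed (0.5 = unbiased)
or drawn per division from a Gaussian centered at `r_mean` (≈0.6 in the
biased regime) truncated to [0.5, 1). Which daughter receives the larger
expected share is decided by a fair coin at every division. This choice —
rather than a lineage-persistent favored daughter — makes segregation
alone a martingale for the population mean (`E[k₁] = k` for any `p`) while
inflating the variance, which is what symmetric restoration from both
sorted extremes requires.

Cells with `k = 0` remain in the population with hazards evaluated at 0;
no special extinction rule is applied to ecDNA-free cells.

**Generation clock.** Each cell tracks the number of mitoses in its
ancestry since simulation start; generation `g` is reached when the
population mean of that counter first crosses `g`. This clock is robust to
death events and matches the experimental convention (one generation
≈ 48 h). Snapshots of the copy-number vector are emitted at requested
generation indices; fixed-horizon runs also return the final state.

**Capacity.** When the population exceeds `n_max` it is uniformly
subsampled without replacement to `n_target` — a distribution-preserving
bottleneck (the expected copy-number distribution is unchanged), chosen
over rate rescaling so capacity control cannot masquerade as selection.

**Exactness and performance.** The simulator is the exact direct-method
SSA — waiting times are exponential in the total rate, the event cell is
chosen proportionally to its rate — with the inner loop compiled by
numba. Populations of a few thousand cells over ten generations simulate
in milliseconds, so no tau-leaping approximation is used. Running rate
sums are refreshed every 4,096 events to cancel floating-point drift.

## Initialization and virtual sorting

FISH count tables are small (~150 cells). Populations are initialized by
fitting a Gaussian KDE to the counts — truncated at zero and renormalized
(truncation, not reflection: observed distributions carry negligible mass
near zero) — and upsampling it with a random-walk Metropolis–Hastings
chain (burn-in 3,000 steps, thinning 5, proposals rejected below zero,
outputs rounded to non-negative integers). The proposal scale defaults to
half the sample standard deviation: a broad, heavy-tailed count
distribution smoothed with a modest bandwidth has isolated tail kernels
that a small fixed step cannot reach, which silently narrows the chain's
output. The chain is validated against an independent direct sampler from
the same truncated KDE (two-sample KS < 0.03 at n = 10⁴, chi-square
convergence on quantile bins).

The virtual FACS sort models gating on an ecDNA-encoded surface protein:
each cell's sort proxy is `k · exp(ε)` with lognormal multiplicative noise
of coefficient of variation `proxy_cv`. The top and bottom proxy quantiles
become the high and low gates (13.7% tails in the experimental protocol
preset); the full input is the sorted control. Higher proxy noise
monotonically shrinks the true-copy separation between gates.

## Synthetic study conditions

The study generator emulates the empirical design: a right-skewed baseline
(rounded lognormal, median 300 copies, 5% of cells above 1,000 — the
lognormal shape parameter is solved from that tail condition, σ ≈ 0.73),
~150 cells per (group, generation) stratum, strata at generations
{0, 1, 2, 9} for high/low/control arms. Its default generating dynamics
("truth") encode the modeled biology and were chosen once, as a coherent
set:

- **Sort proxy noise `proxy_cv = 3.5`.** Surface-protein abundance is a
  loose readout of DNA copy number (rank correlation ≈ 0.45 at this
  noise level against a σ_log ≈ 0.73 dosage signal). The resulting gates
  are modestly separated (medians typically ~2× apart) with nearly
  control-wide spread — the regime in which few-generation restoration is
  dynamically possible at all. A near-noiseless sort would produce ~8×
  separated, narrow gates which *no* log-linear hazard model with a ~60%
  division advantage can re-converge in three generations.
- **Division advantage anchored at the realized gates.** The division
  slope β_b solves `b(k_high)/b(k_low) = 1.6` where `k_high`, `k_low` are
  the medians of the high/low gates actually produced by the sort; the
  intercept pins the baseline-median division rate at 0.02/h. The
  recovered advantage is evaluated at the same medians, so the generating
  advantage is 60% by construction.
- **Dosage-dependent death, slope 5× the division slope,** with its level
  set so net fitness `b(k) − d(k)` peaks at the baseline median. Death
  prunes the high tail, division advantage lifts the low tail, and the
  distribution stabilizes around the bulk over long times. Without a
  death slope steeper than the division slope there is no interior
  fitness peak and the control arm drifts upward without bound.
- **Daughter share `r_mean = 0.6`, `r_sd = 0.15`** (truncated to
  [0.5, 1), random orientation). The spread matters: per-division variance
  injection of log-dosage σ²_inj ≈ 0.1–0.15 per generation is what lets a
  sorted, spectrum-truncated population rebuild a broad continuum on the
  few-generation timescale (see Limitations for the quantitative
  trade-off).

Studies are simulated at 3,000 cells (capacity 6,000) so early-phase
demographic drift in the small sorted gates does not dominate stratum
noise; an arm that goes extinct before its last snapshot is regenerated
with the next seed, with a warning.

## Inference

**Objective.** Candidates are scored by simulating the model and
comparing simulated to target distributions with a histogram KL
divergence, two-part as in the experimental design: (i) a steady-state
term — the control arm replayed from its generation-0 distribution to the
late timepoint must match the observed late control — and (ii) recovery
terms — arms initialized from the generation-0 high/low strata must match
the observed strata at each scored generation (defaults 1, 2 and 9). The
score is the negative weighted sum (equal weights by default), so 0 is
the maximum. Conventions, each switchable:

- KL orientation is KL(target ‖ simulated): the fit is penalized for
  failing to cover observed mass, the standard orientation when fitting a
  model to data histograms.
- Fitness histograms use 12 bins, spaced evenly in `ln(1 + k)` over the
  *target's* range, with pseudocount 0.5. Log spacing resolves the bulk
  of a right-skewed distribution instead of its tail. Anchoring the bins
  to the target (with out-of-range simulated mass still counted in the
  simulation's normalization) closes a degeneracy of pooled-range
  binning, where a candidate producing enormous dosages stretches the
  shared bins until both histograms collapse together and the divergence
  goes to zero. The bin count keeps the sampling-noise floor of
  ~150-cell targets ((B−1)/2N ≈ 0.04 nats per term) below the
  identifiable signal. The generic `histogram_kl` operation defaults to
  pooled-range linear bins.
- Each evaluation averages three simulation replicates run under common
  random numbers fixed per GA run, so the objective is deterministic for
  the optimizer while simulation noise stays below the data noise.
- Initial populations for the fitness simulations are MH-upsampled from
  the corresponding strata with a narrow fixed KDE bandwidth (15 copies):
  the inits should track the observed strata, not a smoothed envelope.
- Simulated extinction contributes a large finite penalty (10³ per
  missing term), never an exception.

**Genetic algorithm.** Tournament selection (size 3), per-gene uniform
crossover (probability 0.5), per-gene Gaussian mutation (probability 0.2,
sd = 0.1 × bound width), clipping to bounds, elitism 2 — so the best
fitness trace is non-decreasing — stopping at a generation cap or after a
stall. Genes are `(log b(k₀), β_b, log d(k₀), β_d, r_mean, r_sd)` with
the rate levels parameterized at the anchor dosage `k₀ = 300` rather than
at k = 0: level and slope are then nearly orthogonal, which conditions
the search far better than raw intercepts. Variants fix subsets: neutral
fixes both slopes to 0 and `r = 0.5`; division-bias-only frees the
hazards but fixes `r = 0.5`; inheritance-bias-only frees segregation with
flat hazards; *both* frees everything. In the packaged recovery
experiments the both-bias variant fixes `r_sd = 0.15`, treating the
daughter-share distribution's spread as externally measured (live imaging
of mitotic partitioning constrains the shape of the split distribution;
only its center is inferred) — leaving both spread parameters free lets
`r_mean` and `r_sd` trade off against each other with no identifying
signal at 150-cell stratum depth.

The packaged recovery experiment runs the GA at population 32 for up to
20 generations (stall limit 7) with 800-cell fitness simulations — enough
that doubling either budget does not change where fits land — and
aggregates ten independent studies, two common-random-number fits each
(per-study average, cross-study median).

**Model comparison.** Each fitted variant re-simulates post-sort recovery
and is ranked by the summed 1-D Wasserstein distance to the high/low
targets at generations 1 and 2. On studies generated with both biases the
both-bias variant ranks first.

## Metrics

- `wasserstein_1d`: exact 1-D W1 via integrated CDF difference (scipy),
  validated against a brute-force optimal-transport linear program on
  small samples; unequal sizes handled by CDF integration, no resampling.
- `recovery_generation`: a sorted arm has "recovered" at the first
  generation whose snapshot is within a bootstrap noise floor of the
  control — the floor is the 95th percentile of W1 distances between 200
  pairs of size-matched control resamples. The control may be a single
  sample or a per-generation trajectory (the experimental design measures
  control alongside the sorted arms; comparing same-generation samples is
  the faithful reading and also tolerates slow control drift).
- `sister_asymmetry`: per division pair, `|k₁ − k₂| / ((k₁ + k₂)/2) × 100`,
  with a Monte-Carlo reference under unbiased binomial splits of the same
  totals (for totals near 600 the unbiased reference mean is ≈ 6.5%;
  biased splits at p = 0.6 stochastically dominate it).

## Numerical choices and degenerate inputs

Hazard parameters must be finite; `rate_min > 0` keeps the total rate
positive so the SSA cannot stall with live cells (a zero total rate
raises). Constant samples cannot take an automatic KDE bandwidth (error
with guidance to use a fixed one). Sort fractions must leave non-empty,
disjoint gates. Copy counts are validated as non-negative integers at
every file boundary, with line-numbered errors. All sub-seeds derive from
one global seed via `SeedSequence` with a stable per-module tag; with the
seed fixed, snapshot lists and output files are byte-identical across
runs.

## What the synthetic generator does and does not emulate

It reproduces the *statistical* structure of metaphase-FISH count data —
sampling depth, right-skewed baseline, group/timepoint layout, sort-gate
regression to the mean — and provides exact ground truth for closed-loop
validation. It does not model FISH imaging noise, probe efficiency,
metaphase-selection bias, lineage correlation between sampled cells at
late timepoints, co-segregation or hub clustering of ecDNA, cell-cycle
structure (the G2/M occupancy prediction is a closed form on top of the
fitted division hazard, not a simulated phase), or chromosomal CNV
background. Passing the packaged experiments therefore demonstrates the
method's internal consistency under the stated generative assumptions,
not performance on real images or sequencing data.

## Limitations

- **Fluctuation–dissipation trade-off.** With binomial(+truncated
  Gaussian bias) segregation, per-generation log-dosage variance
  injection is σ²_inj ≲ 0.15. A stationary spectrum of width σ²_stat
  requires mean-reversion rate θ ≈ σ²_inj / 2σ²_stat per generation, so a
  broad continuum (σ_log ≈ 0.7) forces slow relaxation (≈ 10+
  generations), while 2–3-generation restoration is possible only for
  moderately separated, broad-spread sorted gates (which is what noisy
  protein-proxy sorting produces) and a somewhat narrower steady spectrum.
  Within this model family, maximal baseline breadth and maximal
  restoration speed cannot be satisfied simultaneously; the default study
  conditions balance the two. Consequently the bootstrap restoration
  criterion lands at generation ~1–3 for typical studies but not for
  every random realization.
- **Birth–death slope identifiability.** Generation-indexed distribution
  snapshots constrain net fitness `b(k) − d(k)` tightly but its split
  into division and death components only weakly (division events inject
  segregation variance, deaths do not — a second-order signature). At
  150 cells per stratum the recovered division advantage scatters
  substantially across study realizations (roughly a factor of two in
  either direction) even though its cross-study median centers near the
  generating 60%; the recovered daughter share is much better determined
  (typically within ±0.05 per study). Per-study advantage estimates
  should be treated as order-of-magnitude; only ensemble medians are
  reported as point estimates.
- The MH upsampler needs a proposal scale matched to the data spread
  (the adaptive default); tail mixing is slow, so applications needing
  near-independent draws should thin aggressively.
- The GA objective is a deterministic noisy-landscape surrogate, not a
  likelihood; no posterior uncertainty is produced.
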