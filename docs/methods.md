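# Methods

## The two indices

**Specificity.** A session is a `trials × neurons` matrix of pre-windowed
activity (time-averaged ΔF/F, or spike counts in a fixed analysis
window — the window itself is upstream preprocessing and is carried only
as an annotation). For condition *c* the template λ_c is the plain
arithmetic mean of that condition's trial rows. The Specificity Index of
trial *i* is ρ_i = cor(λ_correct, r_i) − cor(λ_wrong, r_i) with Pearson's
coefficient; because each correlation lies in [−1, 1], ρ ∈ [−2, 2] and no
further normalization is applied. The correct/wrong assignment is
explicit configuration (a map from trial or condition to template
labels): which template counts as "wrong" is task-specific
(present/absent, left/right) and is not inferred.

Zero-variance vectors make the Pearson coefficient undefined. Such trials
are excluded from the result with a logged reason rather than assigned a
value, because any imputation would bias ρ; if every trial is excluded
the computation errors out.

Templates include the scored trial by default, matching the plain
trial-averaging procedure. Self-inclusion inflates the correct-template
correlation by O(1/n_trials), which matters for small sessions, so a
leave-one-out flag recomputes the correct template without the scored
trial; it requires at least two trials in the trial's condition.

**Behavioural Relevance.** The ρ values of behaviourally correct and
incorrect trials (hit and correct rejection vs miss and false positive)
are compared through the Mann–Whitney/Vargha–Delaney route: pool, rank
low-to-high with mid-ranks for ties, take rank sums R_X, R_Y, then
U_X = R_X − n_X(n_X+1)/2 and A = U_X/(n_X n_Y). A equals the probability
that a random draw from X exceeds one from Y with half credit for ties;
an explicit pairwise-enumeration oracle (`brute_force_A`) is the
normative definition and the rank route is required (and tested) to agree
with it exactly. Ω = max(A, 1−A) is evaluated as
max(U_X, U_Y)/(n_X n_Y) so that the symmetry Ω(X, Y) = Ω(Y, X) holds
bit-exactly rather than to a float rounding. Groups with fewer than two
members yield a degenerate rank test; the result is then flagged
undefined, carrying the group sizes, instead of reporting a number.

No p-value machinery is attached to Ω; the index is an effect size, and
significance testing of it is outside the test's definition.

**Shape and variability statistics.** The Yule–Kendall index
γ = (Q¾ + Q¼ − 2Q½)/(Q¾ − Q¼) summarizes skewness of jackknife
distributions; quantiles use linear interpolation between order
statistics — one convention fixed package-wide (quantiles, percentile
bands, covariate splits) so values reproduce bit-for-bit. γ is clamped to
its mathematical range [−1, 1] to absorb last-ulp float excursions, and
is undefined (NaN) for zero interquartile range. The per-neuron Fano
factor uses the unbiased (n−1) variance over the condition's trials
divided by the mean, with zero-mean neurons flagged NaN.

## Surrogate null models

Both generators ask: how would single trials look if they were faithful
random samples of the average template?

- **Gaussian (continuous data).** Per condition and neuron, draws are
  i.i.d. normal with the neuron's across-trial mean and unbiased
  variance, independent across neurons; default 200 draws per condition.
  Values are not truncated at zero — ΔF/F is legitimately negative and
  clipping would distort the null.
- **Poisson reallocation (count data).** Per trial, the trial's total
  spike count is redistributed across neurons by a single multinomial
  draw with probabilities λ_m/Σλ from the template; default 100 draws per
  trial. Each surrogate conserves the trial total exactly, realizing the
  null of independent neurons sampling the template: per-spike allocation
  probability λ_m/Σλ is the only law satisfying fixed total, independent
  spikes, and template-proportional occupancy simultaneously.

Surrogate Specificity is computed against the same correct/wrong
templates as the real trials, pooled across surrogates and trials, and
summarized by the median and a percentile band (default 5th–95th).
Per-trial medians are retained alongside the pooled band since either
summary may be wanted. Calibration: on sessions whose trials genuinely
are multinomial samples of the templates, the real median ρ falls inside
the 5–95% band in ≥ 90% of seeded replicates (tested).

## Population dissections

**Jackknife.** For each neuron *j* and trial *i*, the contribution is
n·ρ_i − (n−1)·ρ_i^(¬j), where ρ_i^(¬j) removes the neuron from both the
trial vector and the templates (template removal is exact — a per-neuron
mean simply loses one component). Undefined cells (zero-variance after
deletion) are NaN, never imputed. γ is reported pooled over all cells
(the headline summary) and per neuron. Super-coder selection ranks
neurons by the median (robust against heavy-tailed trial distributions)
of their contributions and takes the ceiling of `fraction · n` from
either end, ties broken by neuron index so selection is stable.

**Subsampling.** For each population fraction, random neuron subsets
(without replacement) get fresh templates and metrics; the full
per-fraction distributions are returned. No extrapolation curve is
fitted — no functional form is privileged here, so any fit is the
caller's choice.

**Trial clustering.** Response vectors are standardized per neuron (so
high-rate neurons do not dominate the Euclidean metric), partitioned by
k-means with 10 restarts under one seed for each k in 2…5, and k is
chosen by the highest mean silhouette. Centroid-based clustering with
standardization is this package's explicit choice where the procedure was
genuinely open; the k range matches the silhouette comparison the test
was designed around.

**Grouped metrics.** One contract covers trial clusters, covariate
quantile splits (e.g. pupil median split) and easy/difficult condition
splits: recompute templates, ρ and Ω within each group meeting a minimum
size (default 4 trials), report smaller groups as skipped with a reason,
and always include the pooled baseline for comparison.

## Generative simulator

Per trial, stimuli S1, S2 ~ Bernoulli(p) i.i.d. (defaults p1 = p2 = 0.5,
making the two informative differences ΔS = S1 − S2 = ±1 each probability
1/4); ΔS = 0 trials have no correct response and never enter templates,
Specificity, decisions or Ω. Each of the default 200 neurons has baseline
r⁰ ~ N(5, 1), gain g ~ N(5, 1), and selectivity ξ = 2·Beta(β, β) − 1 ∈
[−1, 1]: β < 1 concentrates preferences near ±1 (a segregated code),
β > 1 near 0 (homogeneous). Rates are
r = ReLU(r⁰ + g·ξ·ΔS) + |N(0, σ²)| and spikes are Poisson(r).

**SNR convention.** The background-noise scale is σ = gain_mean / snr, so
the default snr = 5 with gain_mean = 5 reproduces the unit-variance
background term; the gain sets the stimulus-signal scale against which
noise is measured. This mapping is this package's convention.

**Decision.** ρ is computed against the *empirical* ΔS = ±1 templates of
the simulated session — what an analyst could actually compute — not the
ground-truth rate profiles. Then ψ′ = ρ + N(0, q²),
p = 1/(1 + e^(−ψ′)), and the trial is a hit iff p ≥ 0.5 (the tie at
exactly 0.5 counts as a hit). Ω compares ρ of hits vs misses.

**Seeding.** One master seed spawns fixed, named per-stage streams
(stimuli, population, rate noise, spikes, decision), so adding a stage
never perturbs earlier draws and every output is bit-reproducible.

**Landscapes.** Sweeps run independent seeded replicates per grid cell
and record the across-replicate median of per-simulation median ρ
(β × SNR) and of Ω (β × q at the base config's fixed SNR; NaN-aware,
since Ω is undefined when one outcome group has fewer than two trials).
An optional compatibility mask marks cells with
|measured − modelled| < 0.05 (default threshold). The acceptance suite
uses a 3 × 3 β × SNR grid ({0.25, 1, 4} × {1, 2, 5}) and a q grid
{0.2, 0.5, 1, 2} at β = 0.5 with snr = 0.2 and 50 replicates of
200-trial, 200-neuron simulations per cell — the q sweep sits at a low
("intermediate") SNR deliberately, so that both hits and misses occur
even at the smallest decision noise and Ω is defined everywhere.

## Fixture generators

Two seeded generators emulate the experimental data styles end to end and
are first-class, tested code.

- **Continuous fixture** (two-photon style): per-neuron baseline
  b ~ N(0, 1) and preference u ~ N(0, 1); ground-truth templates
  b ± (effect_size/2)·u; trials are template + N(0, noise_sd); outcomes
  hit/miss (condition 1) and correct_rejection/false_positive
  (condition 2) through a sigmoid link of configurable slope on the
  trial's ground-truth Specificity — slope 0 decouples behaviour from the
  neural match, infinite slope is a noiseless threshold. An
  `outcome_counts` mapping instead assigns outcome labels in exactly the
  configured numbers.
- **Count fixture** (electrophysiology style): baselines
  b ~ N(rate_base, 1), selectivities ξ ~ U[−1, 1], condition profiles
  ReLU(b ± rate_effect·ξ), Poisson counts, hit/miss outcomes via the same
  link. Optional latent two-mode structure gives each hidden mode an
  additive rate offset (making states clusterable) and its own
  selectivity pattern (`mode_mix`; pooling across modes then blurs the
  templates, so within-mode Specificity exceeds pooled — the structure
  trial clustering and grouped metrics are designed to reveal). The mode
  index is stored as a covariate, plus an optional noisy covariate
  tracking it.

**Calibration choices.** Zero-effect fixtures are checked to give mean ρ
within 0.02 of 0 and mean Ω within 0.02 of 0.5. Because templates include
the scored trial, the null ρ has a positive O(1/n_trials) bias, and
because Ω ≥ 0.5 by construction its null mean exceeds 0.5 by
≈ 0.8·sd(A) ≈ 0.8/√(6·n_group); the null checks therefore use long
sessions (80–250 trials per condition for ρ; 2500 for Ω) so that both
estimator biases sit well inside the 0.02 band. The strong-separation
check uses rate_effect = 0.8 with an infinite link slope: strong relative
to Poisson noise yet leaving ~10% misses, so Ω is defined in essentially
every session while averaging ≥ 0.9. These sizes are the package's chosen
study conditions, fixed before use and not revisited.

## Numerical conventions and edge cases

- Pearson correlations are clipped to [−1, 1] (guarding last-ulp
  excursions); zero variance → NaN, handled explicitly everywhere.
- All percentiles/quantiles: linear interpolation between order
  statistics.
- Degenerate inputs error loudly and specifically: empty rank-test
  samples, conditions without trials, counts matrices with non-integer
  cells, clustering of identical trials, reallocation templates with zero
  mass against nonzero spikes.
- Every stochastic operation takes an explicit integer seed; there is no
  wall-clock seeding anywhere, and results are bit-reproducible given
  (inputs, arguments, seed).

## What passing tests do and do not show

The fixtures and the simulator share the package's own generative
assumptions: independent neurons given the condition (no noise
correlations beyond the latent-mode construction), Poisson or Gaussian
trial noise, stationarity across a session, and a behaviour link driven
only by template match quality. Passing the calibration and recovery
suites shows the statistics are implemented correctly and behave
correctly under these conditions; it does not certify behaviour on real
recordings with correlated variability, slow drifts, or behaviour driven
by unmodelled variables. The real-data conclusions of the original
studies are likewise out of scope: nothing here reads raw imaging or
electrophysiology formats, and no decoder-based area selection or
PCA-distance variant is included.
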