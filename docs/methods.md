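# Methods

This note documents the models behind `dormtrace`, the parameters that
matter, the design choices made where the procedure was genuinely open,
and what the synthetic benchmarks do and do not demonstrate.

## The experimental design being modelled

A founder population of uniquely barcoded ER+ breast cancer cells (one
barcode per founder cell) is expanded for ~13 days into the "POT", split
by randomization into replicate "carbon copies", and placed under
continuous endocrine therapy without passaging. The population passes
through a latency phase of mass cell death, a lineage bottleneck around
day 30, a long dormancy, and — asynchronously, weeks to months later —
awakening driven by one (occasionally two) lineages. Read-count tables of
barcode abundance at POT, dormancy and awakening timepoints are the
primary data; confluency scan grids, expression matrices, single-cell
barcode tags and longitudinal variant tables are the companions.

## Synthetic cohort generator

### Founder expansion (`simulate_pot`)

Lineage *i* draws a doubling time from a lognormal with arithmetic mean
32 h and coefficient of variation 0.15 and contributes
2^(24·t/dt_i) cells after *t* = 13 days; frequencies are normalized in
log2 space. The lognormal is a modelling choice: multiplicative growth
noise is the standard generative story for right-skewed clone-size
distributions, and the resulting POT has a long right tail (top lineage
around 10% at 100 barcodes) without degenerate dominance. With CV = 0
the POT is exactly uniform, which several tests exploit.

### Carbon copies (`split_carbon_copies`)

Multinomial draws of `cells_per_copy` cells at POT frequencies —
replicates are statistically identical at seeding, which is the premise
the replicate-concordance statistics check.

### Treatment dynamics (`simulate_treatment`)

A discrete-time Markov chain at daily resolution, binomially thinned per
barcode (no per-cell loops). Each day a cycling cell dies with
probability `death_prob`, enters dormancy with probability
`dormancy_prob` (only during the latency window, default 30 days), and
survivors proliferate by the growth factor `awakened_growth`. Dormant
cells neither grow nor die; once latency has closed they awaken with
daily hazard `awaken_hazard`, and awakened cells grow drug-insensitively
at the same factor, capped by a flask `capacity` (10⁷ cells) that halts
growth rather than modelling contact inhibition in detail. Growth of an
integer pool uses stochastic rounding (floor plus a Bernoulli on the
fractional part), which preserves expectations, lets one-cell clones
grow, and is exact whenever `n × factor` is integral — the closed-form
growth tests rely on that exactness.

Defaults: `death_prob` 0.5/day, `dormancy_prob` 0.012/day,
`latency_days` 30, `awaken_hazard` 1.5e-4/day, `awakened_growth`
1.4/day. The first two were fixed, once, so that the canonical desk-scale
design (100 lineages, ~16 founding cells per lineage) loses roughly
two-thirds of its lineages by day 30 — the reported scale of the
dormancy bottleneck — and the hazard so that awakening detection lands
well inside a 150-day horizon at desk-scale dormant-pool sizes (a few
thousand cells). Restricting dormancy entry to the latency window makes
the bottleneck sharp and the dormant pool stable, matching the observed
arc; gating the awakening hazard to after latency encodes that awakening
is an exit from established dormancy, not a failure to arrest.

Awakening is detected as the first sampled day on which total viable
count exceeds twice its post-latency running minimum for three
consecutive sampled days — a quantitative surrogate for "sudden and
exponential change in cell number". `winner_truth` is the set of
barcodes whose awakened descendants hold ≥ 10% of the final population;
it is computed from the simulator's internal awakened pool, a different
route than the frequency-table winner call it validates.

The per-cell persister probability has the closed form
p_s = Σ_t q(1−d−q)^(t−1) over the latency window (`persister_probability`),
and lineage survival is 1−(1−p_s)^c when growth is 1; the simulator is
tested against this oracle at 500 replicates / 3 binomial SE.

### Sequencing noise, confluency panels, expression, cell tags

Sequencing is multinomial at given depth (Dirichlet-multinomial when an
overdispersion is requested; concentration f_i/dispersion). Confluency
panels place one planted event per window: awakening windows follow a
logistic rise to ~95%, failed awakenings a linear rise to a 25% peak
followed by regression below baseline, dormant windows sit at the 5%
baseline and cleared windows at 0. Measurement noise is Gaussian with a
standard deviation scaled by window occupancy (an empty, cleared window
images as ~0 with only trace jitter; a populated one gets the full
`noise_sd`), then clipped to [0, 100]. Expression data are per-gene
Gaussians (mean U(3,12), sd 0.5 log2 units) with planted dormancy genes
shifted ±`effect_size` in dormancy samples; the DE table carries the
observed shift, a Welch t p-value and BH-adjusted q. Cell-tag tables
give every cell one true barcode (reads 1+Poisson(19)), a second
comparable-read integration with probability `multi_tag_rate`, and a 1–2
read ambient tag with probability `ambient_rate`.

What the generator does **not** emulate: PCR jackpotting and
GC-dependent amplification bias, barcode sequence errors that merge
lineages, spatially resolved growth (awakening colonies expanding across
scanning windows), mixed cell states, batch effects, copy-number-driven
VAF shifts. Passing round-trips therefore demonstrate the correctness
and calibration of the analysis rules on data that satisfies the
models' assumptions — not robustness to every artefact of real
libraries.

## Analysis rules and their open choices

**Quantification.** Retention uses reads ≥ min_reads (10 high-complexity,
3 dormancy designs); high-frequency selection is strict > 0.1 with an
`inclusive` flag, since the source convention is stated both ways.
Filtered-out barcodes are kept as explicit zeros so extinctions remain
countable. Read matching is substring search with Hamming tolerance and
an unambiguity rule (ties at minimal distance are discarded) — a
deliberate reimplementation of aligner-based matching for short fixed
tags, not claimed equivalent to MAPQ filtering. Spearman p-values use
the t approximation at n ≥ 10 and exact (vectorized full-permutation)
enumeration below.

**Survival quartiles.** Bins are assigned by frequency rank with ties
broken by barcode id (`np.array_split` on the sorted order), so the four
bins always partition the POT as evenly as possible.

**Doubling time.** t = T/(log₂x + 1) under the printed convention
x = 2^(n−1) (a founder that never divides has x = 1, t = T); the
x = 2^n alternative is exposed behind a flag because the printed formula
is ambiguous at x = 1.

**Lottery test.** The simulation follows the published recipe: survival
ratios from a Normal(μ, σ) truncated to [0,1] (truncated sampling, not
clipping, to avoid point masses at the bounds), initial frequencies
resampled with replacement from the empirical POT distribution
(renormalized across the drawn barcodes by default; a flag disables
renormalization since the original is silent), c₀ ~ Binomial(N, f) and
month-1 counts ~ Binomial(round(N·s), f) with round-half-to-even, so
N·s < 1 forces extinction. The goodness-of-fit test is this package's
formalization of a comparison the original study made visually: observed
per-well barcode survival ratios are first inverted to per-cell survival
probabilities through the monotone map r(s) = mean_i[1−(1−f_i)^(N·s)]
(bisection) — the barcode-level ratio is not itself a per-cell
probability, and using it directly would miscalibrate the null — then a
truncated normal is fitted to the inverted values, lineages are binned
by initial cell count (log-spaced, small bins merged), and the statistic
sums squared standardized deviations of per-bin presence totals and
per-bin presence variances from their Monte-Carlo expectations under the
fitted null (199 parametric-bootstrap replicates). The variance
component is what gives power against lineage-heterogeneous entry
probabilities, which leave bin means nearly unchanged after refitting
but overdisperse within-bin presence. Measured at the 18-well,
100-barcode design: ~95–98% of lottery-generated datasets are judged
consistent at α = 0.05, and power against a 10%-of-lineages /
5×-entry-probability alternative is ~94%.

**Topography.** Baseline per window is the median of the first three
scans; episodes open when confluency exceeds baseline + 10 points for
two consecutive scans, close as failed awakenings on regression below
peak × 0.5, and count as awakenings when still elevated at the end of
the series. Clearance is max confluency < 1%. Well classes: GA when ≥ 3
awakening windows with onsets within 14 days span non-rook-adjacent
positions (GA outranks LA on ambiguity); otherwise rook-connected
components of awakening windows count origins — one component is 1LA,
several are >1LA; no awakening windows is D. All thresholds are
`TopographyParams` fields: the original rules were applied by human
inspection of image sequences, so every number here is a documented
surrogate, and the well-awakening day (mean confluency ≥ 50%, confirmed
twice) is computed independently of the window labels.

**Signatures.** z-scores use the sample standard deviation (ddof = 1)
over the POT + dormancy subset, optionally extended to held-out samples
with the subset's moments; zero-variance genes are flagged and zeroed
rather than dropped. The recurrence rule counts dormancy samples with
positive z at or above the 0.1-quantile of the gene's positive z-scores
(down: negative z at or below the 0.9-quantile of its negatives).
Quantiles use order-statistic interpolation ("lower"/"higher") so the
boundary member of a small signed set passes its own floor — with
exactly six dormancy samples, linear interpolation would silently
exclude the minimum and make the ≥ 6 recurrence unattainable. Whether
the original quantile reference was per-gene or pooled is unstated; both
are implemented (`per-gene-signed` default, `global` alternative).
Ordering is ascending coefficient of variation of dormancy z (consistency
first), then descending |cumulative z|; both keys are reported since no
precedence is stated in the source.

**Single-cell calls.** Multi-tag cells take the entries strictly above
the within-cell 90th percentile of read counts, computed with the
"higher" method so that with two entries the percentile equals the
maximum; the documented consequence is that small tag sets cannot clear
the percentile, and a unique maximum ≥ 5× the runner-up
(`dominance_ratio`) is accepted instead. All-equal counts above 3 reads
are "complex"; everything unresolved is "others". The high-count QC
outlier cut is the 99th percentile of feature counts (no number is
given in the source).

**VAF dynamics.** Two-sample change testing is the exact Fisher test;
for k > 2 samples both a minimum-Bonferroni pairwise Fisher (default,
conservative) and a Monte-Carlo exact conditional test on the 2×k table
(margins fixed, sequential hypergeometric fills, chi-square ordering)
are provided, since the original's handling of k > 2 is unstated.
Thresholds are exactly as stated and boundary-tested: POT absence is
strict mean VAF < 5%, presence strict > 10%, VAF 0 is absent, zero depth
indeterminate; the patient chain applies depth ≥ 20, F1R2+F2R1 ≥ 4,
VAF ≥ 0.1, MODERATE/HIGH in a fixed order (the surviving set is
order-independent; attrition counts are not).

## Benchmark problem sizes

The verification suite (`dormtrace.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses desk-scale
versions of the study design, chosen once: 100 barcodes at POT size
100,000 and 18 wells for the lottery (the low-complexity dormancy
design), K = 1000 instances, a 5×5×5 (f, N, s) oracle grid, 200
single-well panels at noise sd 2 for topography, 500 genes with
6 POT / 6 dormancy / 4 other samples and 50+50 planted genes at a
4-log2-unit shift (σ = 0.5) for signatures, 1000 cells at ambient rate
0.3 for single-cell calls, 1000 null variants at depth 500 for Fisher
calibration, 200 seeded 150-day treatment arcs at 20,000 cells per copy
for winner recovery, and 20 copies of 1,600 cells (~16 cells per
lineage) for the bottleneck survival fraction. Under those conditions
the measured quantities sit comfortably inside their bands (oracle
agreement ≥ 99% of grid cells, calibration ≈ 98%, power ≈ 94%, label
accuracies ≥ 99%, signature precision/recall 100%, day-30 lineage
survival ≈ 32–34%).

## Known limitations

- The lottery fit requires the full well × barcode presence matrix; a
  wells-present count alone cannot support the per-well ratio inversion.
- The topography classifier labels windows independently and does not
  model awakening colonies crossing window boundaries; its 1LA rule for
  adjacent windows relies on rook connectivity, not image evidence.
- The signature recurrence rule with exactly six dormancy samples
  demands positivity in all six; small effects (≲ 2 log2 units at
  σ = 0.5) are intentionally not recoverable at that stringency.
- No estimator is provided for the pre-existent dormant fraction
  (~1/10,000 in the source's modelling); it is out of scope here.
- Fisher change tests are conservative on discrete low-depth data; the
  null calibration bound is one-sided by design.
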