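# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `rifdecay`.

## Decay model and half-life estimation

Transcript decay after a rifampicin block is modelled as first-order:
`I(t) = I(0)·exp(−k·max(0, t − τ))`, with half-life `t_1/2 = ln2/k`. The
no-delay estimator is ordinary least squares of ln(intensity) on time over
all arrays of a condition pooled across replicates (the uneven replicate
layouts contribute 12 arrays per condition: three T0 arrays and nine
distinct chase times). T0 arrays are included in the regression by default;
this is configurable per series by trimming the input columns.

The coefficient of variation of the slope, `cv = 100·se(k)/k` (percent),
gates reliability: estimates are reliable iff `k > 0` and `cv ∈ [0, 40]`.
The window is expressed in percent because a threshold of 40 is only
plausible on that scale — a fractional cv of 40 would pass essentially
nothing. `cv = 0` occurs only for an exact noiseless fit and is treated as
reliable. Rising series (`k < 0`) keep their negative half-life and cv in
the output but are always unreliable; nothing is dropped, only flagged.

### Onset delay

Polymerases already elongating when initiation is blocked keep producing
mRNA briefly, so decay can start after a delay τ. The delay model
`ln I = c + b·max(0, t − τ)` is linear in `(c, b)` for fixed τ, so τ is
chosen on a grid (default 0–3 min in 0.25-min steps, a superset of the
sub-minute delays expected from elongation run-through) by residual sum of
squares, ties broken toward smaller τ. Continuity at τ is enforced; a free
breakpoint intercept is not offered. Candidates leaving fewer than three
points after τ are skipped. Because τ = 0 is always a candidate, the delay
fit never has larger RSS than the plain fit. The post-onset slope's OLS
standard error supplies `se(k)` and cv as before.

With the uneven 12-array layouts, a free delay of up to 3 min can overfit
noisy long-half-life series (steepening the post-onset slope); at the
probe-summarized noise level of the study design this is rare, and
half-lives fitted with and without the delay agree with Pearson R² above
0.98, which is why downstream comparisons use the no-delay estimates.

### RT-qPCR series

For threshold-cycle data, CT rises one cycle per template halving, so
`CT(t) = CT(0) + t/t_1/2` and the half-life is the reciprocal of the
CT-vs-time slope (`halflife_from_ct_slope`).

## Probe-level preprocessing

Summarization is two-way median polish per gene on log2 intensities (the
robust core of RMA): the array summary is the overall plus the array
effect, which absorbs probe-affinity rows and outlying probes. Iteration
stops when no effect moves by more than 1e-6 (20 sweeps maximum); blocks
sharing the modal probe count are polished as one vectorized stack.
Quantile normalization forces columns to a common distribution (mean of
order statistics; ties receive the reference interpolated at their average
rank, so it is idempotent on tie-free data). Common-median rescaling
multiplies each array by a single factor so medians over a shared
("invariant") probe set — by default the common probe set — equal the
grand median of per-array medians.

In the synthetic pipeline, quantile normalization is applied only within
each condition's T0 replicate triplet, and cross-array median rescaling is
off by default. The generator produces background-free arrays on a common
intensity scale, so these steps have nothing to correct there — and
applying distribution-equalizing normalization across *chase time points*
would erase the genuine global decay signal (every transcript really is
lower at t = 8 min than at t = 0). For real data, where array-level scale
effects exist and invariant control probes are available, both switches
(`quantile_normalize_t0`, `median_scale_arrays`) can be enabled. No
background-correction model is implemented; real data should be
background-corrected upstream.

T0 concentrations are the mean of the T0 replicate intensities (intensity
scale, then log2 for testing) multiplied by the condition's total-RNA
extraction yield in µgRNA per mg cell dry weight, giving arbitrary
units/mgDW.

## Statistical comparisons

**Stability.** Per gene and condition pair, the pooled model
`ln I ~ condition + time + condition:time` with separate intercepts (T0
abundances differ between conditions) and slopes. The two-sided t test on
the slope difference uses the pooled residual variance with
`n_A + n_B − 4` df; because the intercepts are separate, the per-condition
slopes equal independent per-condition OLS fits exactly. The half-life
fold change is `log2(t_B/t_A) = log2(k_A/k_B)`. Calls: BH-adjusted
p < 0.1, sign of the fold change. One model per gene per pair is fitted
(not one genome-wide model), since per-gene p-values are the output.

**Differential expression.** A moderated two-sample t: per-gene pooled
variances `s_g²` (d_g df) are shrunk toward a scaled inverse-chi-square
prior `(d_0, s_0²)` fitted by method of moments on `ln s_g²` across genes
(digamma/trigamma moment equations, trigamma inverted by Newton
iteration); the statistic uses the posterior variance with `d_0 + d_g` df.
With `d_0 = 0` it reduces exactly to the ordinary pooled t; the test suite
also cross-checks the implementation against R/limma on a shared fixture.
Calls: BH-adjusted p < 0.01 and |log2 FC| > 1. Bonferroni is available as
a config option (`padjust_method`), BH is the default.

**Distribution-level tests.** Kruskal–Wallis (tie-corrected, chi-square
p) for comparing half-life distributions across phases, with Dunn's
pairwise z tests on joint ranks (tie-corrected variance, two-sided normal
p, BH-adjusted) as the post hoc.

## Regulation decomposition

From steady state `[RNA] = V_t/k`: `ρ_D = −dlnk/dln[RNA]`,
`ρ_T = 1 − ρ_D`, computed from two-point log differences of the pooled
per-condition point estimates (no regression across more than two
conditions, no error propagation into ρ — an uncertainty treatment would
require bootstrapping the time points). `V_t = k·[RNA]` is reported as a
transcription-rate proxy. Eligibility: only genes that are differentially
expressed for the pair AND reliable in every condition are decomposed.
The exclusion rule removes the `round(0.05·n)` genes with the smallest
|dln[RNA]| plus the same for |dlnk| (union; boundary ties all excluded;
`dln[RNA] = 0` always excluded) — magnitudes, not signed values, because
near-zero changes are what destabilize the ratio; a signed variant can be
obtained by pre-filtering.

Category boundaries: the five intervals are closed/half-open so that they
partition the line — 1: ρ_D < 0; 2: [0, 0.4); 3: [0.4, 0.6]; 4: (0.6, 1];
5: > 1. The boundary values 0 and 1 are assigned to the "pure"
transcriptional (2) and degradational (4) categories respectively.

## The synthetic generator

The generator emulates the four-phase carbon-transition study design:
conditions P1–P4 with half-life medians 3.1/6.3/8.3/9.5 min, three
biological replicates, 12 arrays per condition laid out unevenly across
replicates (each replicate contributes its T0 array plus 2–4 chase times
between 0.5 and 11 min), 32 probes per transcript, and total-RNA yields
45.2/33.6/24.3/27 µgRNA/mgDW linking intensities to concentrations.

Per gene: one standard-normal quantile is drawn and shared across
conditions, scaled to each condition's median with log-sd 0.5, so gene
half-lives are rank-correlated across phases and identical medians with no
stabilization give identical half-lives. A per-pair fraction of genes
(default 10% for the first pair, 0 afterwards — stabilization concentrated
at glucose exhaustion and persisting, with no destabilization) receives an
extra two-fold increase from the downstream condition onward; each
condition is then rescaled by a closed-form factor so the population
median of the fold mixture stays at the configured value. Onset delays are
uniform on [0, 0.5] min. T0 concentrations are log-normal around 1000
arbitrary units/mgDW (ln-sd 1); differential expression plants ±2 log2
units in concentration space for 5%/10% of genes per pair. In
`constant_vt` mode concentrations instead track `V_t/k` with gene-constant
transcription, making every concentration change purely degradational —
the positive control for the decomposition.

Noise is Gaussian on the ln-intensity scale (multiplicative on
intensities, the scale on which the regression runs), sd 0.2 per probe by
default, scaled by `(1 + floor/expected intensity)` with floor 5 arbitrary
units (capped at 20×): a scanner-floor surrogate that makes weak signals —
low-abundance transcripts and late chase points — noisier, which is what
drives unreliable cv values to concentrate in the lowest concentration
quartile, as observed in real chase data. Probe affinities are
gene-specific, time-invariant log-normal multipliers (log-sd 0.5),
absorbed by median polish. With noise sd 0 every probe series equals the
model curve to machine precision regardless of the floor.

What the generator does *not* emulate: array background and spatial
artifacts, scanner saturation, cross-hybridization, growth-phase
bioreactor dynamics, and any correlation between half-life and abundance
beyond the noise floor. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated noise model, not
performance on raw scanner output.

All randomness derives from a single seed (`numpy` `SeedSequence`
splitting: one stream for the truth, one for measurement noise), so truth
and measurements are independently reproducible; `PipelineConfig.seed`
overrides the simulation seed so a whole run is governed by one integer.

## Numerical choices and degenerate inputs

- Fits require ≥ 3 points at ≥ 3 distinct times; zero time-variance is an
  error. A zero slope yields infinite half-life and cv and is unreliable.
- Summarization works on log2 (array convention); decay regression
  converts to natural log (decay-constant convention); the conversion is a
  constant factor and exact.
- Quantile normalization of a single array warns and returns it unchanged.
- Median polish of a one-probe block returns the probe's values unchanged.
- `dln[RNA] = 0` genes are excluded from the decomposition rather than
  producing infinities; the scalar API raises instead.
- BH/Bonferroni adjustment validates p ∈ [0, 1] and delegates to
  statsmodels.
- Problem sizes in the test suite (60–1000 genes, 8–32 probes) are chosen
  to make distributional checks stable at a few seconds per test; the
  acceptance script uses 400 genes, where the eligible-gene set after DE
  and exclusion filtering is comfortably non-empty at any seed.

## Known limitations

- Single-phase exponential decay only; no multi-exponential or
  mechanistic degradosome models.
- The interaction test assumes homoscedastic residuals across the two
  conditions; strongly abundance-dependent noise violates this mildly.
- No error propagation into ρ_D/ρ_T; point estimates only.
- The series-matrix reader targets the generic tab-delimited dialect
  (`!`-prefixed metadata, ID column + sample columns) and does not fetch
  from the network; real deposited supplements may need column renaming
  before ingestion.
- GO/KEGG/regulon enrichment of the resulting gene sets is out of scope.
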