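# rifdecay

Genome-wide mRNA decay analysis from rifampicin-chase experiments, with a
fully specified synthetic-data generator so every stage can be validated
against known ground truth.

When rifampicin blocks transcription initiation in bacteria, each mRNA's
subsequent decline reflects degradation alone. Measuring transcript levels
at a series of chase time points therefore yields genome-wide half-lives,
and combining them with pre-arrest (T0) abundances lets one ask *why* a
gene's expression changed between growth conditions: because transcription
changed, or because mRNA stability changed. The motivating setting is the
*E. coli* glucose–acetate–starvation transition, where transcripts are
globally stabilized (median half-life rising from ~3 min during exponential
growth on glucose to ~9.5 min under carbon starvation) while most mRNA
concentrations fall.

The package is aimed at microbial physiologists and computational
biologists analysing transcription-arrest time courses — microarray- or
qPCR-based — and at anyone who wants a tested reference implementation of
the decay-rate/regulation-decomposition analysis chain.

## The model

First-order decay after transcription arrest:

```
ln I_g(t) = ln I_g(0) − k_g · max(0, t − τ_g),      t_1/2 = ln 2 / k
```

- `k` is the decay constant, estimated as the negated OLS slope of
  ln(intensity) vs time, pooling all replicate arrays of a condition.
- `τ` is an optional onset delay (residual elongation after the initiation
  block); it is selected on a grid by least squares, with the fit
  constrained to be continuous at `τ`.
- Reliability: `cv = 100 · se(k)/k` (percent); estimates are reliable only
  for `k > 0` and `cv` in `[0, 40]`. Rising series give negative `cv` and
  negative half-life and are always unreliable.

Stability changes between two conditions are tested via the
time × condition interaction of `ln I ~ condition + time + condition:time`
(separate intercepts and slopes per condition), BH-adjusted, with calls at
adjusted p < 0.1. Differential expression of T0 concentrations
(summarized intensity × total-RNA extraction yield, in arbitrary
units/mgDW) uses an empirical-Bayes moderated t test (per-gene variances
shrunk toward a prior fitted across genes), with calls at adjusted
p < 0.01 and |log2 FC| > 1.

Regulation decomposition: at steady state `[RNA] = V_t / k`, so

```
1 = dlnV_t/dln[RNA] − dlnk/dln[RNA],
ρ_D = −dlnk/dln[RNA],   ρ_T = 1 − ρ_D
```

`ρ_D` is the share of a concentration change attributable to altered
stability, `ρ_T` the share attributable to altered transcription. Genes in
the 5% smallest |dln[RNA]| or |dlnk| tails are excluded (the ratio is
unstable for vanishing changes), and `ρ_D` is binned into five regulatory
categories from "transcriptional with opposing degradational control"
(ρ_D < 0) to "degradational with opposing transcriptional control"
(ρ_D > 1).

Probe-level processing follows standard one-color array practice: quantile
normalization within replicate groups, optional common-median rescaling
over a shared probe set, and per-gene two-way median-polish summarization
on the log2 scale.

## Worked example

`examples/01_simulate_and_fit_halflives.py` simulates a 200-gene chase
during exponential growth (configured median half-life 3.1 min, 32 probes
per transcript, 12 arrays with the uneven replicate layouts of the study
design) and refits the half-lives:

```
simulated 76,800 probe intensities (200 genes x 32 probes x 12 arrays)
reliable fits (cv in [0, 40], k > 0): 200/200
median estimated half-life: 3.16 min (the simulator's configured median is 3.1 min)
median |relative error| vs truth: 4.3%
```

The fitted median (3.16 min) recovers the configured 3.1 min, and typical
per-gene half-life errors are ~4% at the default multiplicative noise.
`examples/06_full_pipeline.py` runs all four phases end to end and prints
the run report (reliable counts per phase, the reliable-in-every-phase
intersection, stabilization/DE calls per consecutive phase pair, and
regulation category counts); the remaining examples demonstrate the delay
model, the stability test, the moderated t, and the ρ_D/ρ_T decomposition
individually.

A thin CLI wraps the same functions:

```
rifdecay simulate --n-genes 300 --seed 1 --out sim/
rifdecay run-all --seed 1 --out run/
rifdecay report run/
```

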