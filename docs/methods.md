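# Methods

## Problem and model

`dermrisk` assesses the non-carcinogenic health risk that heavy-metal
contamination of cosmetic hair dyes poses to consumers through skin contact.
The exposure metric is the average daily dermally absorbed dose

    D_dermal = C · SA · SL · ABS · EF · ED / (BW · AT) · 10⁻⁶,   AT = ED · 365

with C the metal concentration in the product (mg·kg⁻¹), SA the exposed
scalp area (cm²), SL the skin adherence of the product (mg·cm⁻²), ABS the
absorbed fraction (unitless), EF the exposure frequency (days·year⁻¹), ED
the exposure duration (years), BW body weight (kg) and AT the averaging
time (days). The 10⁻⁶ factor converts the mg-scale product chain onto the
mg·kg⁻¹·day⁻¹ dose scale. Because AT = ED·365, ED cancels algebraically:
the dose is invariant to exposure duration, a deliberate and tested
consequence of the averaging-time convention (the sensitivity module still
reports ED, with a note, rather than suppressing it).

Risk is characterized per metal by the hazard quotient HQ = D_dermal / RfD
against a dermally adjusted reference dose, and per stratum (pooled, brand,
or color) by the chronic hazard index HI = Σ HQ. An index strictly above 1
is classified "significant", otherwise "not-probable". The dermal RfD
column is the default basis because the modeled pathway is dermal; the
ingestion column is retained and selectable. Metals removed by the
censoring policy are listed as excluded rather than entered as HQ = 0, so a
stratum's HI is reported as a lower bound whenever exclusions exist.

## Censored concentrations

Measurements below the instrument detection limit are left-censored. The
policy is all-or-nothing per metal: if the censored fraction is ≥ 20% (the
threshold is configurable) the metal is excluded from assessment and the
decision is recorded with the observed fraction; below the threshold,
censored values are substituted (LOD/2 by default; zero and full-LOD rules
are available) and flagged as imputed. Substitution never changes the
number of uncensored measurements. Censored-likelihood fitting is out of
scope; censoring is resolved before any fit.

## Distribution families and fitting

Concentration uncertainty is modeled by one of five positive families —
lognormal(μ, σ), log-gamma (ln X ~ Gamma(α, rate β), support x ≥ 1),
Weibull(shape, scale), Pareto type I (x_min, α) and log-Laplace
(ln X ~ Laplace(μ, b)) — plus normal, gamma, exponential and a degenerate
point mass for fixed inputs. All families are backed by `scipy.stats`
except log-gamma, which is implemented as an exponential transform of a
gamma variate because scipy's log-gamma is the reverse transform.

Fitting is by maximum likelihood: closed forms for the log-scale families
(normal/Laplace MLEs on the log observations) and for the Pareto (x_min at
the sample minimum, α = n / Σ ln(x_i/x_min)); scipy's numeric MLE with the
location pinned at zero for Weibull and gamma. Candidates are ranked by the
Kolmogorov–Smirnov statistic, with Anderson–Darling as tie-break and a
chi-square statistic on ⌈1 + log₂ n⌉ equal-probability bins reported; a
single deterministic order is required, and fit failures (support
violations, degenerate samples) are recorded per family, never dropped
silently. Fitted parameters are validated by parameter-recovery simulation,
not against published values, because the study reports only family names.
The Pareto minimum is a boundary parameter: its MLE is biased upward by
exactly x_min/(nα − 1), so the recovery test centers on that expectation
rather than on zero.

## Monte Carlo engine

Each distributional input (concentration and any distributional exposure
factor) draws from its own named substream of the run seed, so streams stay
independent across inputs — a requirement for the rank-correlation
sensitivity analysis — and runs are bit-reproducible. The default is
20,000 iterations for reported figures; a 2,000-iteration screening preset
exists for fast exploration. Realizations outside an input's domain
(possible only for unbounded user-supplied families such as a normal body
weight) are rejected and redrawn from the same stream with a hard cap of
10× the iteration count, and the rejection count is reported; silent
truncation would bias summaries invisibly. Inputs are sampled
independently; no correlation structure is modeled. The central dose is
the distribution median by default (robust under the strong right skew of
the concentration families — a log-Laplace fit with b ≥ 1/2 has an
infinite mean, and sample means under such fits are dominated by single
draws), with the mean available.

## Default exposure factors

The measurement tables cannot supply exposure factors, so defaults are
explicit in the run configuration and echoed in every manifest:

| factor | default | units | rationale |
| ------ | ------- | ----- | --------- |
| SA | 580 | cm² | adult scalp area |
| SL | 1.45 | mg·cm⁻² | product adherence during application |
| ABS | 0.001 | — | conservative dermal absorption fraction for metals |
| EF | lognormal fit to survey use frequency (fallback 12) | day·yr⁻¹ | one exposure day per application |
| ED | 20 | yr | cancels out of the dose |
| BW | lognormal fit to survey body weights (fallback 60) | kg | adult female population |

EF and BW default to survey-derived distributions rather than fixed values
because they are questionnaire quantities with real population spread, and
the sensitivity analysis is only informative when they vary; with no survey
available they fall back to the fixed values above. All defaults are
config-overridable per run.

## Synthetic study generator

The generator emulates the study design: 8 brands × 4 colors = 32 samples,
10 metals, detection-limit censoring. Each (brand, metal) cell draws from a
lognormal moment-matched to the published cell mean ± SD (σ² = ln(1 +
sd²/mean²), μ = ln mean − σ²/2), the natural choice for positive,
right-skewed concentrations; a per-color parameterization ships as an
alternate design. The two brand cells marked ">20% below LOD" draw from a
lognormal with 75% of its mass below the LOD. The four metals the study
excluded outright (Ag, Co, Cr, Mn) draw with 25% sub-LOD mass, so the
exclusion branch of the censoring policy is exercised end to end —
deterministically in expectation but stochastically per run, which is why
threshold-crossing tests fix their generation seed. The survey generator
reproduces the questionnaire marginals (92.19% dye use, 49.5% chemical-dye
use, the published color-preference shares) with moment-matched lognormals
for body weight (68 ± 12 kg) and use frequency (12 ± 4 per year).

What the generator does not emulate: the joint structure between the
per-brand and per-color summaries (they are marginals of the same 32 real
samples and cannot both be matched by independent cell-wise generation —
the brand parameterization is primary), any within-sample correlation
between metals, and measurement error of the assay. Passing tests
therefore demonstrate the pipeline's correctness and the stability of its
conclusions under the study's statistical shape, not properties of the
original raw measurements, which were never published.

## Numerical choices and degenerate inputs

- Canonical concentration unit is mg·kg⁻¹ (ppm); µg·kg⁻¹ (ppb) inputs are
  divided by 1000 at ingest and units are carried in all I/O.
- Percentiles use linear interpolation between order statistics (the common
  "type 7" rule), stated here because summary tables rarely name theirs.
- Summary SDs use the n−1 (sample) convention.
- Goodness-of-fit ties break AD, then chi-square, then family name.
- HQ = 1 exactly classifies as "not-probable" (strictly greater than 1 is
  significant); the boundary is unit-tested.
- A single-iteration run works but warns that summaries are degenerate;
  sensitivity needs at least 3 draws and reports "not estimable" below that.
- A metal that survives censoring but has no reference-dose entry (possible
  for the four sub-LOD metals on lucky seeds) is summarized but dropped
  from fitting and risk, with the decision recorded in the manifest,
  because a missing RfD must never be silently treated as zero risk.

## Problem sizes

Default analyses use the study-scale fixture (32 samples per metal), 370
survey respondents and 20,000 Monte Carlo iterations. Test-suite
simulations use the 2,000-iteration screening preset and replicated designs
of 50–100 seeds, sizes at which the checked statistics (KS pass rates,
recovery biases, ordering frequencies) are stable.

## Known limitations

- Absolute dose and hazard levels depend on exposure-factor defaults the
  original study did not print; conclusions validated here are therefore
  bounds (every HQ and HI « 1) and orderings (Pb highest, Fe lowest risk;
  concentration then frequency in sensitivity), not absolute figures.
- With only 4 samples per (brand, metal), stratum-level point estimates are
  noisy: the brand with the heaviest cells tops the hazard index in a
  plurality of runs, not a guaranteed majority.
- Only the dermal pathway is modeled: no ingestion/inhalation, no
  carcinogenic slope factors, no age-segmented averaging, no input
  correlations, no variance-based (Sobol) sensitivity indices.
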