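# Methods

## Model

Larval head-capsule widths from a mixed-age brood are modelled as a
K-component univariate normal mixture,

    f(x) = Σ_{k=1..K} w_k · N(x | μ_k, σ_k²),   Σ w_k = 1,

with K equal to the number of larval instars. The biological premise
is that the head capsule is fixed within an instar, so within-instar
width variation is measurement noise plus individual variation
(approximately normal), while between-instar variation follows Dyar's
rule: μ_{k+1}/μ_k ≈ constant, typically 1.1–1.9.

The analysis runs in the order the field uses it: density peaks first,
mixture/BIC second, Dyar validation third. The Dyar fit never feeds
back into the choice of K; it is a post-hoc test of the selected
hypothesis.

### Peak counting

Gaussian KDE on a 512-point grid spanning [min − 3h, max + 3h].
Bandwidth h defaults to Silverman's rule, 0.9·min(sd, IQR/1.34)·n^(−1/5);
the original analysis judged peaks on a frequency plot with unstated
binning, so "distinct peak" needs an explicit rule here: a local
maximum whose topographic prominence exceeds `min_prominence` (default
0.05) times the maximum density. Both knobs are exposed.

### EM fit

Standard EM for univariate normal mixtures, hand-authored because the
decomposition is the core of this package. Initial means are the KDE
peak locations, padded or truncated to K by quantile spacing; initial
σ is sd(x)/K, weights uniform. Iteration stops when the relative
log-likelihood change drops below 1e-8 (max 500 iterations); the
log-likelihood is checked to be non-decreasing at every step. A σ
floor of 0.001 mm — the measurement quantization step — prevents
variance collapse onto repeated quantized values; hitting the floor or
a weight below 1e-6 marks the fit "not converged" instead of raising.
With K = 1 the algorithm reproduces the closed-form normal MLE
(divisor n) exactly, which the tests assert.

### Model selection and anchoring

BIC = −2·log L + p·ln n with p = 3K − 1, minimized over K = 1..k_max
(default 6). Developmental anchors act as disqualifiers, not priors: a
candidate is removed when its smallest component mean falls outside
the observed embryo head-width interval widened by 2σ̂ of that
component, or its largest outside the prepupa interval likewise. If
every candidate is disqualified the run stops with a diagnostic rather
than returning a K that contradicts the anchors.

### Assignment and summaries

Specimens take the component of maximal posterior probability; exact
ties break toward the lower instar, and observations beyond 4σ from
every mean are flagged as outliers but still labeled. Per-instar
summaries use the n−1 SD divisor and round only at presentation.
Measurement-based classification scores each instar by the product of
normal densities over shared characters (conditional independence
given the instar — the source reports no within-instar correlations).
Qualitative diagnosis intersects the observations with a built-in
instar × character key; it is monotone (more observations, never a
larger compatible set). First-instar mandibles are recorded both as
"weakly sclerotized" and "completely unsclerotised" in different parts
of the source description, so the key accepts either level for
instar 1. Hair types C/D/E occur in both later instars and do not
discriminate between them; body-hair count intervals (300–400,
400–500, 500–600) do.

### Dyar statistics

`growth_rates` returns r_i = μ_{i+1}/μ_i. `mean_rate` is their
arithmetic mean — the convention that reproduces the published mean
rate from the published per-moult rates under round-half-up.
`dyar_regression` fits ln μ_i on i by OLS and reports R² and
exp(slope) ("implied rate", a weighted geometric mean of the r_i). The
published fit quality (R² = 0.95) is treated as a lower bound: the
regression form behind it is unstated, and recomputation from the
published rounded means gives 0.9966, so the verdict threshold
defaults to R² ≥ 0.9 (overridable). Note the two rate summaries are
not interchangeable: arithmetic and weighted-geometric means can
differ by up to ~0.055 across the Dyar band, and the tests bound their
gap by the observed rate spread rather than a fixed tolerance.

## Synthetic-population generator

The generator emulates the measurement *structure* of the study, not
its biology: per-(stage, instar, character) truncated normals with the
published mean, SD and min–max, sampled independently given the
instar, then quantized to 0.001 mm (the precision of the published
values). Truncation is mean ± 3sd intersected with the published
range. Defaults (all mm):

- 344 larval head widths, component means (0.123, 0.151, 0.184),
  common SD 0.006, instar mix 32:38:89. The unrounded means reconcile
  two published printings: each rounds to the published 0.12/0.15/0.18
  and the successive ratios round to the published 1.23/1.22 (the
  rounded means alone would give 1.25). The head-width SD is not
  published; 0.006 makes the three components distinct (≈4.7σ apart)
  while adjacent ranges nearly touch. The study never reconciles the
  344 measured widths with the per-instar head-capsule counts
  32/38/89 (sum 159); the weights adopt the ratio, the total stays
  344.
- 159 eggs (length 0.29 ± 0.01 in [0.26, 0.34], width 0.18 ± 0.02 in
  [0.15, 0.20]), 50 pupae (1.42 ± 0.07 in [1.26, 1.54]).
- 20 mature embryos and 20 prepupae, drawing head widths from the
  first and last larval component respectively — the published shaded
  anchor intervals are figure-only and are not read off the figure.
- Per-instar body length/width, mandible length, spiracle diameter and
  body length through spiracles from the published per-instar
  paragraphs.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real broods: within-instar growth,
allometric correlation between characters, caste structure
(reproductive larvae are absent, as they were excluded during the
original collections), non-normal measurement error, and observer
effects beyond the 0.001 mm quantization.

A known emulation limit: truncating a normal to an asymmetric
published range shifts its mean. The shift is ≤ 3.2 % of the published
mean for every character except spiracle diameters (9–17 %), whose
published ranges (e.g. 0.005–0.013 around a mean of 0.006) cannot be
matched by any truncated normal centered on the published mean. Tests
therefore compare sample moments against the analytic truncated-normal
truth (scipy's `truncnorm` as an independent oracle) and separately
bound the analytic-vs-published gap.

## Numerical choices

- σ floor 0.001 mm (= quantization); weight floor 1e-6; EM tolerance
  1e-8 relative; BIC ties cannot occur in float practice, argmin takes
  the smaller K.
- Posterior and classification ties break toward the lower instar.
- Rounding for presentation is decimal round-half-up, matching the
  published tables; JSON reports carry full precision.
- Peak counting requires ≥ 10 observations; the Dyar regression
  requires ≥ 3 means (R² on two points is vacuous).

## Problem sizes

The test suite and acceptance script run the study-sized problem
(n = 344 plus eggs/pupae/anchors) throughout; stability is checked
over 100 generator seeds, parameter-recovery sweeps use 25 replicates
per true K, and moment-convergence checks use one n = 10⁴ population.
The full suite completes in about two minutes on one CPU.

## Known limitations

- The mixture is univariate; a multivariate mixture over several
  characters (or a dip test for multimodality) could sharpen K
  selection but is out of scope.
- BIC with well-separated components is consistent, but with heavily
  overlapping instars (ratios near 1.1 and large σ) both peak counting
  and BIC will under-count; anchors mitigate only the extremes.
- The character key encodes one species' published states; it is data,
  not biology shared across Monomorium.
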