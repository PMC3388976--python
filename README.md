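# instars

Determination of the number of larval instars of an insect — here the
bicoloured trailer ant *Monomorium floricola*, a widespread urban pest
— from the frequency distribution of maximum head-capsule widths, with
validation against Dyar's rule and per-instar morphometric summaries.

## The problem and the method

Ant larvae cannot be staged by watching moults in the nest, but the
sclerotized head capsule does not grow *within* an instar. A mixed-age
brood therefore shows a multimodal head-width distribution with one
mode per instar. The classic analysis is:

1. **Peak counting.** Estimate the head-width density (Gaussian KDE,
   Silverman bandwidth) and count its distinct peaks; each peak is one
   instar.
2. **Mixture decomposition.** Model the widths as a K-component normal
   mixture, `f(x) = Σ_k w_k · N(x | μ_k, σ_k²)`, fitted by
   expectation–maximization; select K by BIC
   (`−2·log L + (3K−1)·ln n`). Candidate K whose extreme components
   conflict with the developmentally identifiable anchors — mature
   embryos carry first-instar head capsules, prepupae last-instar ones
   — are disqualified.
3. **Dyar's rule.** Head capsules grow in geometric progression across
   moults: the ratios `r_i = μ_{i+1}/μ_i` should be roughly constant,
   typically in [1.1, 1.9]. The fitted means are tested by regressing
   `ln μ_i` on the instar index `i` and requiring near-unit R² plus
   all ratios inside the band.
4. **Morphometrics.** Per-instar descriptive statistics
   (mean ± SD, min–max, n) for body, mandible and spiracle dimensions,
   Gaussian classification of new specimens, and a qualitative
   character key (hair types A–E, body-hair counts, mandible
   sclerotization).

No raw measurement data accompany the original study, so the package
ships a synthetic-population generator (`instars.synthgen`)
parameterized from the published descriptive statistics (n = 344
larval head widths in a 3-component mixture with means near
0.123/0.151/0.184 mm, 159 eggs, 50 pupae, per-instar body characters).
Every downstream stage is exercised against that generator's hidden
ground truth.

## Worked example

```python
from instars import InstarDeterminationModel

results = InstarDeterminationModel.from_simulation(seed=1).fit(seed=1)
print(results.summary())
```

```
Instar determination from head-capsule widths
======================================================
Observations (larval head widths): 344
KDE bandwidth: 0.00723 mm; distinct peaks: 3
Selected number of instars (BIC): K = 3

Component   mean (mm)   SE       sd (mm)   weight
  1         0.1235      0.0007   0.0059    0.225
  2         0.1509      0.0006   0.0057    0.244
  3         0.1846      0.0004   0.0055    0.532

Embryo anchor interval:  [0.115, 0.130] mm
Prepupa anchor interval: [0.169, 0.194] mm

Dyar growth ratios: 1.22, 1.22  (mean 1.22, implied 1.22)
Log-linear fit: R² = 1.0000
Dyar verdict: PASS
```

Three distinct density peaks and the BIC-selected K = 3 agree: three
larval instars. The component means round to 0.12, 0.15 and 0.18 mm,
the per-moult growth ratios sit inside the Dyar band, and the
log-linear fit is effectively perfect — the geometric-progression
signature of a correctly identified instar sequence.
`results.summary_frame()` returns the per-instar tables
(e.g. instar-1 body length 0.385 ± 0.049 mm), `results.labels_frame()`
the per-specimen posterior assignments, and `results.plot()` the
density with peaks and fitted mixture.

The same pipeline is scriptable from the shell; `run` exits 0 iff the
Dyar verdict passes:

```sh
instars simulate --out pop.csv --seed 1
instars run --in pop.csv --out results/ --seed 1
instars dyar --means 0.12,0.15,0.18
instars diagnose -o mandible_sclerotization=none
```

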