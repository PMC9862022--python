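# brcaprog

Breast-cancer prognosis transcriptomics: a tested, reusable
implementation of a cohort analysis that links tumor gene expression to
five-year survival.

## What it does, and for whom

Given a genes × samples normalized expression matrix (FPKM-UQ-like) and
a clinical table, the library:

1. **builds the cohort** — tumors from patients who died within five
   years form the Poor Prognosis (PP) group, patients alive with more
   than five years of follow-up the Good Prognosis (GP) group, plus
   unpaired normal tissue;
2. **types the tumors** — ER/PR/HER2 positivity thresholds come from a
   two-component Gaussian mixture fitted to log10 expression of *ESR1*,
   *PGR*, *ERBB2*, taking the intersection of the weighted component
   densities as the cutoff, and combine into the surrogate intrinsic
   subtypes (Luminal A/B, HER2 enriched, Triple Negative);
3. **finds prognosis-specific genes** — per-gene Welch t tests of each
   tumor group against normal tissue on log2 expression,
   Benjamini–Hochberg FDR, volcano classification (fold change ≥ 2 or
   ≤ 0.5, q < 0.05), then set differences select genes dysregulated in
   PP but not GP (and vice versa), visualized by 2-component PCA;
4. **screens genes for survival impact** — patients are split into
   lowest/middle/highest expression tertiles per gene; the top vs
   bottom tertile are compared by a log-rank test and their five-year
   survival fractions read off Kaplan–Meier curves;
5. **computes the clinical table** — two-sided Fisher exact tests per
   stage/subtype/race category, Welch t for age, binomial logistic
   regression for independent prognosis factors, and ANOVA + Tukey HSD
   for immune-cell fraction tables.

A synthetic-cohort generator (`simulate_cohort`) reproduces the
statistical structure this analysis assumes — bimodal receptor genes,
planted group-specific expression effects, proportional-hazards
survival tied to chosen genes — with full ground truth, so every stage
is testable without downloading anything. It is intended for
computational biologists analyzing their own expression/survival
cohorts or validating this class of screen.

## The statistics at the core

For a receptor gene with fitted mixture
`w₁·N(μ₁,σ₁²) + w₂·N(μ₂,σ₂²)` (μ₁ < μ₂ on log10 scale), the positivity
threshold solves `w₁·φ(x;μ₁,σ₁) = w₂·φ(x;μ₂,σ₂)` on (μ₁, μ₂) — a
quadratic in x, linear when σ₁ = σ₂. The survival screen uses the
product-limit estimator `S(t) = ∏_{tᵢ≤t} (1 − dᵢ/nᵢ)` and the standard
two-group log-rank statistic `(O₁−E₁)²/V` with hypergeometric variance
at each distinct event time, χ² with 1 df. DE selection applies the BH
step-up procedure and classifies genes by linear fold change and
adjusted significance.

## Worked example

```python
import brcaprog as bp

expr, clinical, truth = bp.simulate_cohort(bp.CohortConfig(n_genes=300), seed=3)
genes = ["PPG_OVER00", "PPG_UNDER00"] + [g for g in expr.genes if g.startswith("BG")][:48]
screen = bp.gene_survival_screen(expr, clinical, genes)
print(screen.head(2).round(4))
```

```
             n_low  n_high      chi2    p  s5_low  s5_high    q
gene
PPG_OVER00     101     100  168.1076  0.0  0.9245   0.1452  0.0
PPG_UNDER00    101     100  128.8379  0.0  0.1987   0.8760  0.0
```

`PPG_OVER00` is the planted risk gene (+1.1 log-hazard per SD of log10
expression): the third of patients with the highest expression has a
five-year survival of 0.15 against 0.92 for the lowest third, log-rank
p ≈ 2e-38 — exactly the pattern the screen exists to surface. The
protective planted gene shows the mirror image. The `examples/`
directory walks through each capability (simulation, subtyping,
differential expression, survival screen, clinical statistics) as a
short narrative script.

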