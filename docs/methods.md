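# Methods

## Scope and model

`brcaprog` re-implements, as a tested library, a transcriptome-based
breast-cancer prognosis analysis over three sample groups: unpaired
normal tissue (Normal), tumors from patients alive with more than five
years of follow-up (Good Prognosis, GP), and tumors from patients who
died within five years (Poor Prognosis, PP). The pipeline has five
analytical stages — cohort construction, receptor subtyping,
differential expression with group-specific gene selection, tertile
survival screening, and clinical statistics — plus a synthetic cohort
generator that provides ground truth for all of them.

## Cohort rule

A tumor sample is PP when `vital_status == dead` and `time < 5` years
(strict), GP when alive with `time > 5` years. Alive samples with five
or fewer years of follow-up are indeterminate and excluded. Patients who
died *after* the horizon did survive past it and default to GP; the
convention only matters for late deaths and is configurable
(`deaths_after_horizon="Excluded"`). Classification is monotone in
follow-up time for alive patients. Duplicate gene symbols in input
matrices keep the highest-mean row (duplicates are common in public
matrices; the choice is logged).

## Receptor thresholds and subtypes

ER/PR/HER2 status is read from *ESR1* / *PGR* / *ERBB2* expression.
Tumor-sample values are transformed as `log10(x + 1e-3)` (the
pseudocount admits zeros; configurable) and fitted with a two-component
Gaussian mixture by EM. Choices that matter:

- **Estimator**: EM on the raw log10 values rather than histogram curve
  fitting; it is the maximum-likelihood estimator for this model and its
  recovery is directly testable by simulation. Initial responsibilities
  come from a median split; one random-restart (seeded) guards against
  poor local optima. The log-likelihood is asserted non-decreasing every
  iteration; component variances are floored at 1e-6 and flagged if the
  floor binds. Convergence: Δloglik < 1e-8 within 500 iterations.
- **Threshold**: the root of `w1·φ(x;μ1,σ1) = w2·φ(x;μ2,σ2)` between the
  two component means — a quadratic in x for unequal variances, the
  closed linear form when variances are (numerically) equal. If neither
  quadratic root falls between the means the nearest root is returned
  and flagged. The second quadratic root (outside the means) is a
  mathematical artifact with no biological meaning and is discarded.
- **Calls**: positive iff log10 expression strictly exceeds the
  threshold; a value exactly at the threshold is negative.
- Mixtures are fitted on tumor samples only by default (normal tissue
  would distort the negative component); a flag includes normals.

Subtypes follow the surrogate clinical rules: Luminal A = (ER+ and/or
PR+) and HER2−; Luminal B = (ER+ and/or PR+) and HER2+; HER2 enriched =
ER−/PR−/HER2+; Triple Negative = all negative. The four subtypes
partition all eight status combinations.

At component separations of ~2.5 SD and receptor-scale component SDs
(0.3–0.5 log10 units), the median absolute threshold-recovery error at
n = 2000 is ≈ 0.06 log10 units; at unit SDs the same relative geometry
gives proportionally larger absolute error (≈ 0.13) for any
maximum-likelihood fit — we verified our EM tracks scikit-learn's to
~0.003 on identical draws.

## Differential expression and selection

Per-gene Welch (unequal-variance) t tests between groups, computed on
`log2(x+1)` values by default (variance stabilization; `scale="linear"`
is available since the source scale is not dictated by the data format).
Fold change is always the ratio of *linear*-scale group means with a
1e-3 pseudocount. P-values are BH-FDR adjusted across all tested genes.
Volcano classes: *over* iff FC ≥ 2 and q < 0.05; *under* iff FC ≤ 0.5
and q < 0.05; otherwise *ns*. Genes constant across the tested samples
get t = 0, p = 1.

Group-specific selection is set algebra on the two tumor-vs-normal
contrasts: `pp_only_over = over(PP vs N) \ over(GP vs N)`, etc., with
`shared_*` the intersections; the outputs partition each contrast's
significant sets (asserted).

Two-component PCA runs on column-centered, per-gene standardized
log2 values via SVD, with a deterministic sign convention (the
largest-magnitude loading of each component is positive). Standardizing
keeps high-abundance genes from dominating; it can be disabled.

## Survival screening

Kaplan–Meier product-limit estimation and the two-group log-rank test
are implemented in-package (both are small, and the screen calls them
tens of thousands of times on a full transcriptome); they are
cross-validated against `lifelines` to 1e-10 on random censored data in
the test suite. Ties between deaths and censorings at the same time
follow the standard convention (deaths first; censored subjects leave
the risk set after the time point). `survival_at` is right-continuous
(the value at an event time is the post-jump value) and carries the
last value forward beyond the final observation, with a warning.

Tertile stratification is rank-based with stable, input-order tie
breaking; when n is not divisible by 3 the spare slots go to the lower
tertiles first (n = 10 → 4/3/3). The screen compares the top third
against the bottom third only (the middle tertile is held out), reports
the raw log-rank p as the screening statistic — matching how such
screens are usually reported — and appends an optional BH column. The
five-year survival fractions are read at exactly t = 5.0 years.

## Clinical statistics

- **Fisher exact** (two-sided, probability-mass rule) via scipy; tested
  against brute-force enumeration of every table with the observed
  margins. Stage categories pool their sub-stages (I = I+IA+IB, …)
  before testing each category against the rest.
- **Prognosis regression** is binomial logistic (PP vs GP) by maximum
  likelihood, with age dichotomized at the tumor-cohort median, stage
  dichotomized early (I–II) / late (III–IV), and sex/race as indicator
  contrasts against the most frequent level. On perfect separation a
  lightly penalized fit is substituted and flagged; Wald quantities are
  then unavailable rather than misleading.
- **Cell fractions**: one-way ANOVA + Tukey HSD per cell type across
  Normal/GP/PP on a CIBERSORTx-style samples × 22 fraction table (the
  deconvolution itself is out of scope; the table is an input).
- **Pearson correlation** with the t-approximation p-value.

## Synthetic cohorts

The generator's defaults are the study conditions: arms of 105 normal /
200 GP / 101 PP samples; per-gene log10-normal expression (baseline
means ~N(1.5, 0.8), SDs U(0.2, 0.6) in log10 units of an FPKM-UQ-like
scale); receptor genes drawn from two-component mixtures whose positive
weights equal typical positivity rates (ER 73.4%, PR 57.8%, HER2 11.0%),
with normal tissue drawn from the negative component; planted DE sets
(default ten over- and ten under-expressed genes per set at |log2FC| = 2)
applied to the intended arm(s); survival from an exponential
proportional-hazards model whose log-hazard is linear in the
standardized log10 expression of chosen genes (defaults: one planted
PP over-expressed gene at +1.1 per SD, one under-expressed at −1.1;
baseline 0.08/yr), with independent exponential censoring (0.03/yr)
truncated at a 10-year follow-up horizon; age/stage/race drawn per arm
from cohort-table-like distributions.

GP/PP labels are then *re-derived* from the simulated outcomes with the
same five-year rule the real pipeline uses, so label noise relative to
the intended arms is part of the data-generating process (≈75–85%
concordance under the defaults). The intended arms are returned in the
ground truth and are what controlled power/calibration tests condition
on. The true positivity threshold per receptor is computed by Brent
root-finding on the weighted density difference — deliberately
independent of the analytic intersection used by the fitting code.

The optional cell-fraction generator draws Dirichlet rows (LM22 naming)
with the pro-inflammatory cell types depleted in PP and a shared
log-normal latent factor coupling the M1-macrophage and CD8 T-cell
fractions (scale 0.75, giving a Pearson correlation ≈ 0.53 at cohort
size, the magnitude reported for co-recruited cell types).

What the generator does **not** emulate: read-count noise (values are
log-normal, not negative binomial), batch effects, gene–gene
correlation beyond the planted structure, correlation between ER and PR
positivity (drawn independently, so joint receptor cross-tabulations are
not realistic), stage–survival coupling beyond the arm-level covariate
distributions, and the deconvolution generative model. Passing tests
demonstrate correctness and calibration of the statistical machinery
under this idealized structure, not performance on real cohorts.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the tested effects are decisively powered:
500-gene cohorts for DE calibration (10 seeds), n = 2000 for threshold
recovery (20 seeds), 100-gene screens at ~300 tumor samples, 20
replicates for logistic recovery at n = 300. Determinism: every source
of randomness flows from one `numpy.random.Generator` seeded explicitly;
derived seeds use `SeedSequence` and stay below 2^31. Degenerate inputs
(constant genes, zero margins, no events, rank-deficient PCA inputs)
return the documented flagged values or raise named errors rather than
propagating NaNs.

## Known limitations

Real-cohort headline quantities (positivity percentages, selected-gene
counts, specific genes' survival fractions) depend on the actual tumor
cohort and are only emulated in distribution here. The log-rank
implementation is the standard unweighted (Mantel–Haenszel) form; no
Cox modeling, competing risks, or time-dependent covariates. The EM
fitter supports k ≤ 2 components by design.
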