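# Methods

## The feature-extraction model

Let `X` be the probe-by-sample matrix after per-sample z-normalization
(each sample column to mean 0 and unit sample standard deviation, n−1
denominator). The analysis embeds probes, not samples: the PC scores `u_k`
solve `X Xᵀ u_k = λ_k u_k` with `λ_1 ≥ λ_2 ≥ …`, and the sample-side
loadings are `v_k = Xᵀ u_k`, which are eigenvectors of `Xᵀ X` with the
same eigenvalues (`Xᵀ X v_k = λ_k v_k`). With ~10⁴–5×10⁴ probes and ~20
samples, `X Xᵀ` is enormous but has rank at most the number of samples, so
the implementation never forms it: a thin SVD `X = U S Vᵀ` yields
`u_k = U_k`, `λ_k = s_k²`, `v_k = s_k V_k`. This is numerically stabler
and orders of magnitude cheaper, and the test suite verifies the duality
identity against a dense eigensolver on `Xᵀ X`.

Eigenvector signs are arbitrary; they are fixed so each `u_k`'s
largest-magnitude component is positive. The probe statistic is squared,
so no downstream quantity depends on this convention (also tested).

**Discriminative PC.** Loadings attribute one scalar per sample to each
PC, so group separation can be tested directly: a two-group t-test on
`v_k` for k = 1..(number of samples), with the selected PC the argmin of
the p-values (ties to the smallest k) and a manual override available.
The Welch (unequal-variance) form is the default because it is the common
software default and is safer under unequal group variances; the
pooled-variance Student form is available as an option and the choice is
recorded in pipeline output.

**Probe attribution.** On the chosen PC with scores `u`, the statistic for
probe i is `(u_i / σ)²` with `σ` the sample standard deviation of the
components of `u` (mean-subtracted, n−1 denominator; an uncentered
root-mean-square option exists for sensitivity analysis). Under the null
that a probe carries no group structure, its standardized score is treated
as standard normal, so the statistic is referred to the upper tail of
χ²(1); the degree of freedom is configurable but 1 is the natural choice
for a single squared standardized quantity. P-values are adjusted by the
Benjamini–Hochberg step-up rule and probes with adjusted p strictly below
the threshold (default 0.01) are selected. The BH implementation delegates
to statsmodels; the tests pin it to a brute-force enumeration of the
step-up definition.

This χ² reference is an approximation: the components of a unit-norm
eigenvector are exchangeable but not independent, and their tails are
slightly lighter than Gaussian. In calibration simulations under the
global null (pure-noise 10 000 × 19 matrices) the realized false-discovery
proportion at BH 0.01 averages close to, and within 1.5× of, the nominal
level over a fixed 1000-seed family.

No probe (row) centering is applied beyond the column normalization:
the eigenproblem is taken on the column-normalized matrix directly, and
adding row centering would change the selected set.

## Discrimination

The loading is recomputed by decomposing the row-subset matrix restricted
to the selected probes (columns are not re-normalized; normalization is a
per-sample operation already applied), giving one scalar per sample. The
classifier is classic two-class LDA on that scalar: class means, pooled
within-class variance with the n−2 denominator, priors from training-fold
class frequencies (uniform priors available). Evaluation is leave-one-out
cross-validation with the selection held fixed; `strict_loocv` additionally
repeats normalization, selection and decomposition inside every fold,
projecting the held-out sample onto the fold's score vector, because the
default (conventional) protocol lets the held-out sample influence the
selection.

Numerical conventions worth stating:

* On a 1-D feature the decision boundary has the closed form
  `(μ_a + μ_b)/2 + s² ln(π_a/π_b)/(μ_b − μ_a)`; the tests locate the
  implementation's boundary by bisection of the discriminant-score
  difference and require agreement to 1e-8.
* Score ties resolve to the class with the larger prior, then
  lexicographically, so predictions are deterministic.
* `s² = 0` with distinct class means is treated as the vanishing-variance
  limit (nearest class mean); `s² = 0` with coincident means is a
  degeneracy error.
* LOOCV with frequency priors is pessimistically biased on data with no
  signal: removing the held-out sample makes its class the training
  minority, so the prior term votes against it (mean accuracy ≈ 0.32 for
  10+10 noise samples — sklearn's LDA behaves identically). This is a
  property of the decision rule, not an implementation artifact; the
  null-calibration check therefore uses the uniform-prior option, whose
  chance level is exactly 1/2.

## Survival screen

For each gene the cohort (time in days > 0, event 1 = death / 0 =
censored, one expression value per patient) is split at the median
expression, ties at the median falling to the low half (a deterministic
rule; with distinct values and even n the halves are equal). The halves
are compared by the standard two-group log-rank test (observed minus
expected events over event times, squared, over the hypergeometric
variance, referred to χ²(1)); Kaplan–Meier product-limit curves summarize
each half, and the half with the larger restricted-mean survival (area
under the KM curve up to the shorter arm's last observed time) is recorded
as the better-surviving direction. A per-gene Cox proportional-hazards
regression on continuous expression is available where a rank-based
screen is preferred. P-values are BH-adjusted across the genes screened
in one call (one cancer cohort = one FDR family; pooling is done by
concatenating cohort maps), and genes with FDR < 0.05 are flagged.
KM, log-rank and Cox estimation delegate to lifelines; the tests pin them
to hand-worked product-limit values and a manual O−E/variance tabulation.
Per-gene failures (e.g. constant expression) yield NA rows, not aborts.

## Enrichment

Over-representation of a query gene list in each set of a GMT collection:
with universe size M, set size K, query size N and overlap k, the Fisher
p-value is the hypergeometric upper tail P(X ≥ k); EASE mode recomputes
the tail at k−1 (floored at 0, so a single-gene overlap gives p = 1 —
deliberately conservative). Symbols are matched case-insensitively and
queries are de-duplicated. The default background is the union of all
genes in the collection, overridable by an explicit list (e.g. all genes
on the array) because the background choice materially shifts p-values.
BH runs across the sets of the collection.

## Synthetic data

`gen_expression` emulates the motivating study design: Gaussian(0,
noise_sd) background for `n_probes × (n_controls + n_cases)` (defaults
10 000 × (10 + 9)), with the first `n_signal_probes` (default 100)
receiving an additive shift of `effect · noise_sd` (default 2) in the case
columns. Signal probes are named `sig_0001…` so truth recovery is a set
intersection. Gaussian noise is used deliberately: the pipeline operates
post-normalization, where the χ² attribution itself assumes approximate
normality, so heavier-tailed array-realistic intensity models would test
the generator, not the method. The generator therefore does not emulate
probe-level intensity distributions, batch effects, covariates (age/sex),
or correlated probes — passing tests show the method's behavior under its
own model assumptions, not robustness to those real-data features.

`gen_survival` draws expression standard normal, assigns the upper
expression half a hazard of `baseline_hazard · hazard_ratio` (defaults
1/1000 per day and 2), samples exponential survival times, and censors an
exact `round(censor_fraction · n)` subset (default 20% of 360 patients) at
an independent Uniform(0,1) fraction of the event time — the simplest
mechanism that hits the target censoring fraction exactly and
deterministically. Exponential times make the log-rank test's
proportional-hazards alternative exact, which is what the power
calibration (≈5% rejections at hazard ratio 1, ≥90% at ratio 3 with
n = 360) is meant to verify.

Both generators are pure functions of their config including the seed.

## Problem sizes used by the automated checks

The test and acceptance runs use the study-scale design (10 000 × 19) for
single runs, 1000 replicates for the null-FDR calibration, 500 replicates
of 20-sample features for the LOOCV null calibration, and 100–200
replicates of 360-patient cohorts for the survival calibrations; these
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands while keeping a full run in the minutes range on one core.

## Known limitations

* The χ²(1) attribution is approximate (see above); selection calibration
  is demonstrated under the Gaussian generator, not proven for arbitrary
  data.
* The automatic PC scan tests every PC and picks the argmin p without
  multiplicity correction across PCs; with ~20 PCs this is mild, but on
  null data the reported minimum p is optimistically biased (the selection
  stage is unaffected — probe p-values do not depend on group labels).
* The default LOOCV protocol keeps the full-data probe selection fixed
  across folds and thus overstates accuracy; use `--strict` for an
  unbiased estimate.
* Median dichotomization discards within-half expression variation; the
  Cox option uses the continuous value but assumes proportional hazards.
* Binary vendor formats (CEL/CHP) are not parsed; users export the signal
  matrix to TSV. No imputation: missing cells are load errors.
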