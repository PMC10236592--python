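# Methods

`nutrieff` re-implements, as a tested pipeline, the genetic analysis of
protein efficiency (PE) and related traits in growing-finishing pigs:
phenotype derivation from carcass scans and feeder records, pedigree-based
REML animal models, AIC screening of fixed effects, and a sensory
mixed-model comparison.  Because the raw study data are embargoed, every
stage is exercised end-to-end on a synthetic-data generator whose defaults
reproduce the published design and trait architecture of the source
population (a Swiss Large White resource herd).

## Phenotype derivation

Protein efficiency is the proportion of dietary crude-protein intake
retained in the carcass between entry to the grower phase (~20 kg live
weight) and slaughter (~106 kg):

    PE = (CP_carcass(slaughter) − CP_carcass(start)) / CP_intake

Retained protein and phosphorus are predicted from a DXA scan of the left
cold carcass half via the published linear prediction equations

    CP (g) = −482.745 + 0.23 · (Lean_DXA · P)
    Ph (g) = −6.388 + 0.109 · (BMC_DXA · P) + 0.004 · (Lean_DXA · P)

where `P` is the left-half weight as a proportion of the total cold
carcass weight.  The start content is the entry live weight times a
per-kg carcass composition constant per sex, estimated externally from a
chemically analysed piglet sample.  Those constants are not published;
the package ships documented placeholders (150 g protein and 5.5 g
phosphorus per kg live weight, identical across sexes, in the range of
piglet whole-body composition) and treats them as configuration.  All
derived quantities that matter downstream are either insensitive to the
placeholder (it cancels in round trips) or explicitly supplied.

Performance traits use ADG = Δweight/Δage, ADFI = feed/Δage and
FCR = ADFI/ADG (an exact identity in derived output).  Drip loss and
cooking loss are percentage weight losses of a loin chop across storage
and cooking.  Slaughter age is residualised on slaughter weight (rAgeLW)
to break their collinearity before use as a covariate.  Implausible
values (PE outside (0,1), negative losses, non-positive predicted
composition) are flagged in a QC table and never silently dropped or
clipped; dropping is an explicit CLI option.

## Animal model and REML

The core model is `y = Xb + Z_a a + Z_c c + e` with additive genetic
effects `a ~ N(0, A σ²_A)` (A the pedigree numerator relationship matrix),
litter (common-environment) effects `c ~ N(0, I σ²_CE)` and residuals
`e ~ N(0, I σ²_R)`.  Heritability is `h² = σ²_A / σ²_P` and the litter
ratio `CE² = σ²_CE / σ²_P` with `σ²_P` the sum of the components.
Bivariate models use unstructured 2×2 component matrices; genetic
correlations rescale the additive covariance by the additive variances,
phenotypic correlations rescale the summed covariance by the phenotypic
variances.

A is computed by the tabular method on the topologically sorted pedigree;
unknown parents are unique unrelated non-inbred founders.  Dense storage
is used throughout — at the study scale (~1.5k animals) sparse inverses
buy nothing.  Since ancestors without records contribute no data, REML
works directly with the A submatrix of phenotyped animals.

Estimation is average-information (AI) REML on the observation-level
covariance `V(θ) = Σ_k C_k ⊗ K_k` (kernels: A, litter identity, record
identity), with records missing one trait of a bivariate pair retained
for the other (full-information likelihood over observed entries, no
complete-case deletion).  Numerical safeguards:

* variances floored at 10⁻⁶ × the trait's phenotypic variance;
  correlations clamped to ±0.999; a variance pinned at its floor is
  treated as degenerate — its covariances are set to zero rather than
  clamped to a vanishing correlation bound; boundary estimates are
  flagged;
* coordinates held at a bound by the gradient are dropped from the
  Newton update (the AI system is solved in the free coordinates only);
  steps are ridged until finite and bounded, then step-halved so the
  restricted log-likelihood never decreases; when the joint AI step
  fails, a diagonal-AI scaled gradient step is tried before giving up;
* convergence requires |Δ log-likelihood| < 10⁻⁸ and relative parameter
  change < 10⁻⁶ after a full AI step; repeated sub-tolerance gains from
  halved steps (a flattened boundary crawl) also terminate, flagged by
  the boundary report;
* starting values split the phenotypic variance 1/3 to the genetic term,
  1/10 to each further random term, remainder residual; bivariate
  covariances start at half the geometric mean of the variances with the
  sign of the sample covariance; at most 200 iterations.

Standard errors of components come from the inverse AI matrix at the
optimum; SEs of h², CE² and correlations use the first-order delta method
with central-difference gradients.  The published analysis obtained these
from a commercial engine whose SE conventions are not documented; the
delta method is the standard first-order choice and is validated here
against a parametric bootstrap (within 25% on the scales tested).
Significance of variance components, where needed, is a one-sided
likelihood-ratio test against the boundary null.

## Fixed-effect screening

Before the animal models, a plain OLS model with all candidate covariates
(year of entry, slaughter weight, rAgeLW, treatment, sex, temperature and
four interactions) is screened by all-subsets AIC, enumerating only
subsets that respect marginality.  AIC uses the ML residual variance and
counts it as a parameter (the convention of R's `AIC` for `lm`).  Ties
are broken by fewer parameters, then lexicographic term order.  The terms
of the single best model feed the animal model; the whole ΔAIC < 2 set is
reported.  Screening is per trait, since the retained interactions differ
between meat-quality traits.

## Sensory analysis

Panel scores (0–10 line scale) are modelled per attribute as
`score = μ + Session + Judge + Sex + PE-group + FatThickness + ε` with
judge and session random (identity structures, fitted by the same REML
engine).  Group comparison uses Fisher's LSD on adjusted (least-squares)
means: threshold `t(1−α/2, df) · sqrt(2·MS_error/n_eff)` with `n_eff` the
harmonic mean of the pair's group sizes (groups are unbalanced: 12/13/14)
and `df` the residual degrees of freedom of the fixed-effect projection.
The commercial tool used originally does not document its df and n_eff
conventions; at this scale the results are insensitive, but the
convention here is stated rather than guessed to be identical.  α = 0.05
by default.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions:

* **Pedigree** — 39 sires and 79 dams (48 dams with one litter, 23 with
  two, 8 with three → 118 litters) across 14 farrowing series; litter
  sizes Poisson with mean 9.08, giving ~1071 phenotyped offspring.
  Parents descend from grandparent pools (60 grandsires, 160 granddams),
  yielding a three-generation pedigree of ~1400–1500 animals — the scale
  of the real 1468-animal pedigree, though not its 12-generation depth.
* **Breeding values** — recursive Mendelian sampling: founders from
  `N(0, G_a)`, offspring = parent average + deviation with covariance
  `0.5·(1 − (F_s+F_d)/2)·G_a`, inbreeding handled exactly via the
  pedigree module.  Cost is linear in pedigree size.
* **Trait architecture** — means and total SDs from the published
  descriptive statistics (PE 0.39 ± 0.04, PhE 0.43 ± 0.05, ADG
  0.85 ± 0.11, FCR 2.67 ± 0.23, ADFI 2.26 ± 0.31) with variance
  components from the published estimates (e.g. PE: σ²_A = 5.2×10⁻⁴,
  σ²_CE = 5.8×10⁻⁶, σ²_P = 9.6×10⁻⁴).  The excess of the target total
  variance over the model's phenotypic variance is assigned to fixed
  effects, split equally between a sex effect, a slaughter-weight slope
  and a temperature slope, all mean-centred.
* **Correlations** — the genetic correlation matrix is taken from the
  published estimates.  Litter effects are uncorrelated across traits.
  The residual correlation is derived as (phenotypic − genetic)
  covariance; the resulting matrix is not positive semi-definite (the
  published ADG/FCR/ADFI phenotypic triangle is unattainable for a free
  Gaussian because FCR is structurally ADFI/ADG), so it is projected to
  the nearest PSD correlation by eigenvalue clipping.  Realised
  phenotypic correlations therefore deviate slightly from the printed
  ones; genetic parameters are unaffected.
* **Records** — observation-level records are back-generated by inverting
  the derivation formulas (e.g. DXA lean mass solved from the protein
  equation), so `derive(back_generate(x)) = x` to machine precision.
  Feed composition constants (130 g crude protein and 5 g phosphorus per
  kg feed), carcass yield 0.79 and a left-half proportion of ~0.5 are
  plausible fixed conventions, not published values.  FCR in derived
  output is the exact ratio ADFI/ADG rather than the separately simulated
  Gaussian trait.
* **Sensory scores** — simulated independently with judge variance 1.0,
  session variance 0.25, residual variance 1.0 on a 0–10 scale, and a
  default −1.5-point juiciness offset for the high-PE group, emulating
  the reported separation pattern.

What passing tests on this generator show — and what they do not: the
pipeline recovers parameters from data that satisfy the model assumptions
exactly (multivariate-normal effects, independent covariates, correct
pedigree).  Real data add genotype-by-diet structure, non-normal intake
distributions, selection and pedigree errors that the generator does not
emulate, so recovery here validates the estimator, not the biology.

## Problem sizes used in validation

The recovery studies refit the bivariate animal model on fully
independent study-shaped simulations (fresh pedigree and effects each
replicate, ~1071 phenotyped animals).  The per-replicate spread of the
genetic-correlation estimate at this design is substantial — SD ≈ 0.16
for PE–PhE and ≈ 0.2 for PE–FCR, matching the single-fit SEs the
original analysis reports — so the averaged estimate uses 20 replicates
for PE–PhE and 40 for PE–FCR (empirical SE of the mean ≈ 0.03).  Oracle equivalences run at deliberately
small scales where the oracle is exact or its Monte-Carlo error is known:
gene dropping on ≤ 30 animals with 10⁵ drops (±0.01), balanced half-sib
ANOVA at 50×20, a brute-force likelihood grid at 10⁻³ resolution on an
8-animal pedigree, and a 200-draw parametric bootstrap at n = 500.

## Known limitations

* Two traits per REML fit (the published analysis is also bivariate);
  no maternal genetic effects; no genomic relationships.
* The LSD df/n_eff convention is an explicit approximation (see above).
* The generator's pedigree has depth 3, not 12; deeper ancestry changes
  mean inbreeding (tiny in the source population) but not the expected
  sampling properties of the estimators at this scale.
* Baseline piglet composition is configurable, not estimated.
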