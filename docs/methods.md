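# Methods

## The model

Ear and tail damage scores (0–3, victim's perspective, biting and necrosis
not distinguished) are analysed with a linear animal model

    y = X b + Z_a a + Z_l l + Z_g g + Z_hys hys + e

where the fixed effects b are sex, line, sex×line, scorer and age at
scoring (linear covariate, in days), and the random effects are the
additive genetic animal effect a ~ N(0, A σ²_a) with A the pedigree
relationship matrix, and i.i.d. litter l, pen-group g,
herd-year-season-of-scoring hys and residual e effects. Linear models are
used throughout, also for the ordinal 0–3 scores — they are what breeding
programmes run in practice; no threshold (probit) model is fitted.

Seven trait definitions are analysed: the raw scales ED03/TD03, their
binary versions ED01/TD01 (any damage on that body part), the combined
any-damage indicator AD01, the number of body parts affected NBP (0–2) and
the summed score SD06 (0–6).

Heritability is σ²_a over the sum of all five components; a variant
excluding the herd-year-season variance from the denominator is also
reported because studies that fit that grouping as fixed would exclude it.

## Pedigree machinery

Inbreeding coefficients and the Mendelian-sampling variance coefficients
d_i come from the Meuwissen–Luo path-tracing algorithm; A is built by the
tabular method when it is needed densely (tests, small analyses), and the
mixed-model equations always use the sparse A⁻¹ from Henderson's rules
with inbreeding (α_i = 1/d_i), so a fully inbred-correct inverse at O(n)
cost. log|A| = Σ log d_i supplies the constant in the restricted
likelihood. A single unknown parent is treated as an unrelated,
non-inbred founder contribution; "0", empty and "NA" are accepted unknown
codes.

## REML and BLUP

The restricted log-likelihood is evaluated exactly through the MME
identity: with W = [X Z], M = W'W + blockdiag(0, A⁻¹/γ_a, I/γ_l, …) and
γ_k = σ²_k/σ²_e,

    −2 l_R = (n−p) log σ²_e + Σ_k q_k log γ_k + log|A| + log|M| + y'Py
             + (n−p) log 2π .

Every evaluation needs one sparse factorisation of M. Because the REML
search factorises the same pattern hundreds of times, the package carries
a small up-looking sparse LDL' kernel (`sparse_ldl`, numba-compiled) with
a one-time symbolic phase (fill-reducing ordering taken from SuperLU's
minimum-degree permutation, elimination tree, column counts) and a cheap
numeric phase; log-determinants and solves are exact. Unit tests pin the
factor against dense `numpy` results and the whole likelihood against a
dense GLS evaluation of −2 l_R.

Maximisation is by L-BFGS-B on log γ (univariate; σ²_e profiled out
analytically) or on (log v₁, log v₂, atanh r) per random term plus the
residual (bivariate), with numerical gradients. The correlation
parameterisation keeps every 2×2 block positive semi-definite by
construction, and freezing a term's atanh r implements fixed-correlation
fits (used for near-duplicate trait pairs, e.g. a litter correlation fixed
at 0.99). Bivariate fits start from the univariate estimates and optimise
the correlations first, then polish all parameters jointly. Components are
floored at 1e-8 of the phenotypic variance. Optimiser tolerances are
matched to the precision of finite-difference gradients (step 1e-4 on the
transformed scale); a Nelder-Mead cross-check and a 21³ grid test verify
that the reported optimum is the true one.

Standard errors come from the inverse average-information matrix at the
optimum. The AI matrix 0.5·y'P V_i P V_j P y needs only MME solves
(V_k P y = Z_k û_k/σ²_k, P f = R⁻¹(f − W M⁻¹W'f)), so it is exact and
cheap; heritabilities and genetic correlations get delta-method SEs from
the same matrix. EM/AI-REML *iterations* are deliberately not used: their
expected-information updates need traces of inverse-MME blocks (selected
inversion), which direct likelihood maximisation avoids entirely.

Prediction error variances are σ²_e times the requested diagonal entries
of M⁻¹ (unit-vector solves against the stored factor); model-derived
accuracy is r_i = √(1 − PEV_i/σ̂²_a) with PEV clamped into [0, σ̂²_a]
(clamping logged).

## Validation procedures

*Replicated k-fold CV.* Records are allocated to five folds — uniformly,
or with full-sib families intact, or with all animals connected through a
shared sire or dam intact (connected components; the stricter reading of
"half-sibs never split"). Components are **not** re-estimated per fold;
each fold is a BLUP solve on the prediction records at the full-data REML
estimates (re-estimating 500 times is computationally disproportionate and
changes nothing material; a purist can call `reml_fit` per fold).
Validation phenotypes are adjusted with the full-data estimates of all
effects except the animal effect; accuracy is corr(y_adj, EBV)/h with
h = √h² from the full univariate model, dispersion is the regression
slope of y_adj on the EBVs.

A calibration caveat that the simulations make visible: the BLUP
adjustments remove only the *shrunken* litter/pen/hys effects, so
var(y_adj) exceeds σ²_a + σ²_e, while the h used to rescale the
correlation corresponds to the full phenotypic variance. Under the default
variance structure (pen fraction 0.20) this inflates the CV accuracy by a
factor ≈ √(var(y_adj)/ (σ²_a+σ²_e)) ≈ 1.2–1.3 relative to the true
corr(EBV_v, TBV_v) — a property of the estimator as defined, reproduced
faithfully here; the dispersion slope and the ranking of fold-grouping
schemes are unaffected. Forward (LR) accuracy does not share this
inflation and tracks the truth closely in the same simulations.

*LR forward validation.* Training animals are those born up to a cutoff
date; validation animals are younger. EBV_p are solved with the validation
phenotypes removed but pedigree links retained, EBV_c with everything.
accuracy = √(cov(EBV_p,EBV_c)/((1−F̄)σ̂²_a)) with F̄ the mean inbreeding of
the validation animals, bias = mean(EBV_p)−mean(EBV_c) reported in
genetic-SD units, dispersion = cov/var(EBV_p) (the OLS slope of EBV_c on
EBV_p). A negative covariance flags the accuracy as undefined rather than
fabricating a number.

## Selection intensity and response

EBVs are first detrended by an ordinary least-squares fit on
herd-year-season of scoring (equivalently, level-mean deviations), then
the realized intensity of selecting the best (lowest-damage) 5% is
|mean(selected) − mean(all)|/sd(all), with ties broken by a stable sort on
animal id. The normal-theory benchmark is φ(z_{1−p})/p = 2.063 at
p = 0.05; discrete EBV distributions (binary traits) fall below it, which
is the reason realized rather than tabulated intensities are used.
Responses per generation, in genetic-SD units, are R_direct = i·r with r
the forward-validation accuracy of the selection trait, and
R_correlated = R_direct·r_g. The bundled worked example feeds the
published intensity/accuracy/correlation tables of the six-line commercial
study through this assembly and reproduces its 7×7 response table to
within one unit in the third decimal (the published inputs are themselves
rounded to 3 d.p., which propagates up to ±0.0007 in the products).

## Synthetic data

The generator emulates the structure of commercial nucleus data: six
closed lines on 13 farms (three farms house two lines), discrete
generations with random mating within line, litters nested in dams
(clipped-Poisson size, mean 12.5, range 1–30), of which only
`tested_per_litter` = 4 piglets enter the testing station and are scored —
mirroring the real ratio of scored animals to litters — housed in pens of
6–16 animals formed from consecutive litters (most pens mix ≥2 litters),
with herd-year-season groups of birth and scoring, a scorer per pen, and
age at scoring 130–180 days. Defaults: 14 sires and 105 dams per line and
generation, three generations, ≈5,000 scored animals — enough family
structure to recover a 0.05 heritability.

Breeding values follow the pedigree exactly: founders ~ N(0, Σ_a),
descendants are the parent average plus a Mendelian deviation with
covariance d_i·Σ_a using the same d_i as A⁻¹, so simulated BVs and the
relationship matrix are mutually consistent (mid-parent regression and
gene-dropping tests). Litter, pen and HYS effects are i.i.d. draws from
their 2×2 covariances. True components default to
σ²_a = 0.05, σ²_l = 0.10, σ²_g = 0.20, σ²_hys = 0.10, σ²_e = 0.55 (unit
total variance, h² = 0.05) with a genetic correlation of 0.45 between the
ear and tail liabilities and 0.30 for the other terms; the non-genetic
fractions are simulation choices (no published decomposition exists), the
genetic ones match the study's reported range. Fixed-effect magnitudes
echo published effect sizes (age slope ~0.0012 per day, sex effects
±0.05, line spread 0.15). In ordinal mode liabilities are cut at the
N(0,1) quantiles for prevalences (0.75, 0.15, 0.07, 0.03); in gaussian
mode the liabilities themselves are the phenotypes, which is what the
parameter-recovery tests use.

What the generator does **not** emulate: social (indirect) genetic effects
of pen mates, selection across generations, across-line pedigree links,
non-proportional line sizes, missing or repeated scores, and
scorer-by-farm nesting. Passing tests therefore show that the estimators
are correct and calibrated under the assumed model, not that the model is
right for real barns.

## Numerical and design choices

- One RNG stream per simulation, keyed by the config seed and consumed in
  a documented order: identical seeds give byte-identical output files.
- MME solutions are checked against their equations (relative residual
  < 1e-6) on every univariate fit.
- REML non-convergence is reported through a flag, never an exception;
  singular designs (confounded fixed effects) raise with the offending
  columns named.
- Fold blocks are dealt largest-first to the emptiest fold (balanced to
  within one block); a block larger than n/k is placed with a warning.
- Restricted likelihoods include all constants, so values are comparable
  across parameterisations and against dense oracles, and invariant to
  record order and fixed-effect reference level (tested to 1e-6).

## Problem sizes

Simulation-based checks run at ≈5,000 scored animals per replicate — the
scale at which a 0.05 heritability is estimable with SE ≈ 0.02 — with 20
replicates for parameter recovery and 12 for validation calibration; the
acceptance script uses 6 replicates per block. Monte-Carlo oracles use
10⁶ draws (truncation intensity) and 6×10⁴–2×10⁵ gene drops
(relationships), with simultaneous-band tolerances sized to those counts.

## Known limitations

- At h² = 0.05 the REML sampling distribution of σ̂²_a is wide
  (SE ≈ 0.02 at n = 5,000) and slightly right-skewed with a boundary at
  zero; across many replicates the mean estimate can sit a few percent
  below the generating value.
- The bivariate optimiser reports the genetic correlation with an AI
  delta-method SE; when one trait's genetic variance collapses towards the
  floor that SE becomes very large (correctly reflecting that r_g is then
  barely identified).
- The CV accuracy inflation discussed above is inherent to the adjusted
  phenotype / full-model-h definition and should be kept in mind when
  comparing CV accuracies with forward-validation accuracies on real data.
- No genomic relationships, social genetic effects, threshold models or
  multi-trait (>2) REML.
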