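# Methods

## The model

Hip and elbow conformation are recorded as ordered categories — hips on a
seven-point scale (1 excellent … 7 severe), elbows on a four-point scale
(1 normal … 4 grade-III degenerative joint disease).  `threshped` treats
each score as the discretization of an unobserved Gaussian *liability*

    l_m = mu_m + sex_im + beta_m * age + year_km + a_m + e_m ,

for trait `m` in {hip, elbow}: an intercept, a male-minus-female contrast
(female reference), a linear regression on age in months at evaluation, a
categorical year-of-evaluation effect (first observed year as reference),
the animal's additive genetic effect, and a residual.  The observed
category is determined by which interval between ordered cutpoints the
liability falls into; the probit convention fixes the residual variance at
1 per trait and the first cutpoint at 0, leaving the intercept free.

Additive effects for the two traits jointly follow

    var[a_h, a_e] = G0 ⊗ A ,

with `A` the pedigree numerator relationship matrix and `G0` the 2×2
genetic covariance matrix (variances g_h, g_e, covariance g_he).
Residuals are unit-variance with correlation r_he estimated from dogs
scored on both joints; dogs scored on one joint contribute only that
trait's liability.  Reported quantities follow the liability-scale
definitions: heritability h² = g/(g+1), genetic correlation
r_g = g_he/√(g_h·g_e), both computed sample-wise along the chain and then
averaged (the posterior mean of the transform, not the transform of the
posterior mean).

Estimated breeding values (EBVs) are posterior-mean animal effects, one
per pedigree animal per trait, including unphenotyped ancestors.  They
live on the probit liability scale and have no direct mapping to a score
category: they rank animals by predicted disease liability, and a
*negative* slope of mean EBV against year of birth indicates genetic
improvement under this coding.

## Inference

Fitting is single-chain Gibbs sampling with latent-liability
augmentation:

1. **Cutpoints** move by random-walk Metropolis–Hastings with the
   own-trait liabilities integrated out of the acceptance ratio
   (partially collapsed update); immediately afterwards the liabilities
   are redrawn from truncated normals between their category's cutpoints,
   conditioning on the other trait's liability through r_he.  Proposal
   steps adapt during burn-in toward a 20–50 % acceptance rate and are
   frozen afterwards.
2. **Fixed effects** are drawn jointly from their exact multivariate
   normal conditional (the coefficient count is small), under diffuse
   N(0, e^10) priors.  The joint draw matters: the intercept and the
   year-of-evaluation dummies are nearly collinear and mix slowly under
   scalar updates.
3. **Animal effects** are updated in per-animal blocks across traits by a
   sparse scan over the rows of A⁻¹ (Henderson's rules with inbreeding
   adjustment), compiled with numba.
4. **G0** is drawn from its conjugate inverse-Wishart conditional with
   scale V·nu + aᵀA⁻¹a and degrees of freedom nu + n_animals
   (default prior: V = I, nu = 0.002, mode V·nu/(nu+2) — effectively flat
   over the variances).
5. A **multiplicative group move** rescales (a_m, G0) along the
   scale ridge of each trait (Metropolis step with the exact Jacobian);
   this shortens the autocorrelation time of the variance components.
6. The **residual covariance** updates by Metropolis–Hastings on the
   log-variances and on the correlation (conjugate scaled-inverse-χ²
   draws where no doubly-scored dogs couple the traits), with proposals
   leaving R0 non-positive-definite rejected.

The default chain schedule is 100,000 rounds, 20,000 burn-in, thinning
interval 20 — 4,000 stored samples.  Recovery studies in this package use
shorter desk-scale chains (8,000–10,000 rounds, 2,000 burn-in, thin 5),
which hold the Monte-Carlo error of posterior means well inside the
recovery tolerances asserted by the tests.

### Identification of the liability scale

With the residual variance pinned at 1 and *all* interior cutpoints free
under flat priors, the likelihood constrains the liability scale only
weakly for traits with several categories, and the flat cutpoint priors
put growing volume at larger scales.  The posterior mean of the genetic
variance is then inflated — on 7-category data simulated at h² = 0.57
this package measured a stationary upward bias of about +0.06 on h².  We
therefore *sample* in the equivalent parameterization that anchors the
first two cutpoints and lets the residual variance float (binary traits
keep residual ≡ 1), and rescale every stored sample back to the
unit-residual convention before storage.  All reported quantities —
h² = g/(g+r), correlations, cutpoints, fixed effects and EBVs in residual
SD units — are invariant under this rescaling, and the stored chain
satisfies the standard probit identification (residual 1, first cutpoint
0, cutpoints strictly increasing).  After the change, recovery is
unbiased across the full range of simulated heritabilities (0.01–0.90).

### Convergence checks

A chain passes when every monitored series (variance components and fixed
effects) has stored-sample lag-1 autocorrelation below 0.1 and no trend
by a Geweke-style comparison of the first 10 % against the last 50 % of
the chain (|z| < 2, spectral-density standard errors); moment-based
normality screens (|skewness| > 1, |excess kurtosis| > 2) are reported
but informational.  The pipeline refuses to emit summaries from a failing
chain unless forced.  Two caveats worth knowing: with ~30 monitored
series, the |z| ≥ 2 trend rule flags roughly one or two series by chance
in a perfectly stationary chain; and the variance components of threshold
models mix slowly under data augmentation, so desk-scale datasets need
heavier thinning (the end-to-end example in the test suite stores every
200th of 120,000 rounds) than the large-registry default schedule.

## The synthetic-data generator

The generator produces data with exactly the structure the model assumes,
so that every stage is testable against a known truth:

* founders draw breeding values from N(0, G0); offspring receive the
  parental mean plus a Mendelian deviation with covariance
  0.5·G0·(1 − (F_s+F_d)/2), with inbreeding F tracked exactly
  (Meuwissen–Luo);
* generations are non-overlapping (a simplification — real registries
  overlap); each generation draws up to `n_sires` studs (with
  replacement across matings, mimicking repeated stud use) and `n_dams`
  dams, each dam producing `offspring_per_dam` pups;
* liabilities add the configured fixed effects (zero by default so
  genetic parameters can be recovered in isolation), the breeding value,
  and unit-variance residuals correlated r_he across traits; scores
  follow by counting cutpoints below the liability; ages draw uniformly
  from a configurable window (default 24–120 months); per-trait
  missingness is applied afterwards;
* optional truncation selection keeps the best fraction of candidates by
  observed score (or true breeding value), for sires, dams, or both,
  with ties broken by a uniform draw — emulating voluntary phenotypic
  selection and producing the declining genetic trend that the trend and
  four-path analyses measure.

Default study conditions for the recovery runs: 300 founders, 4
generations, 50 studs and 150 dams per generation, 3 pups per dam
(≈1,650 animals); hip cutpoints (0, 0.75, 1.5, 2.25, 3.0, 3.75) with
intercept 1.5 and elbow cutpoints (0, 0.8, 1.6) with intercept 0.8,
chosen so that every category stays well populated across the simulated
heritability range (0.01–0.90) — parameter recovery, not prevalence
realism, is the design goal here, and real registry prevalences are much
lower; residual correlation 0.2; genetic correlation 0.3 in the
average-heritability scenario (mid-range of the published breed table,
fixed once).

What the generator does **not** emulate: overlapping generations,
score-dependent ascertainment (owners withholding poor radiographs —
available as optional score-dependent missingness but off by default so
recovery tests are unbiased), body-weight covariates, litter/maternal
environment, or the component lesions behind a composite elbow grade.
Passing recovery tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not robustness to the biases of real
voluntary registries.

## Numerical choices

* A⁻¹ is assembled by Henderson's rules with the Quaas inbreeding
  adjustment; dense A (tabular method) is limited to 5,000 animals, with
  the sparse inverse always available.  Inbreeding uses the
  Meuwissen–Luo L·D·L' traversal.
* Truncated-normal draws use the inverse-probit-CDF method with interval
  probabilities clipped at 1e-14; the (measure-zero) degenerate draws are
  clamped into their interval.
* Positive-definiteness is enforced by Cholesky success (inverse-Wishart
  draws are PD by construction; R0 proposals outside |r| < 1 are
  rejected).
* Cutpoint initialization inverts empirical cumulative category
  frequencies through the probit, opening empty-category gaps to 1e-3 to
  keep boundaries strictly increasing.
* Loess smoothing of trends is a tricube-weighted local quadratic
  (span 0.75, no robustness iterations), fit pointwise by least squares.
* Four-path quadratic fits use ordinary least squares on birth year
  centered at its mean.

## Known limitations

* Single-chain inference only; no Gelman–Rubin diagnostics across chains.
* The sampler's variance components carry long autocorrelation times at
  desk scale (see above); posterior means are accurate but tail
  quantiles need long chains.
* Full registry-scale analyses (10⁵–10⁶ records per breed) have not been
  run here; per-iteration cost is O(records + nonzeros of A⁻¹), so the
  default schedule at that scale is hours, not minutes.
* The sire-vs-dam path comparison is provided as a permutation test on
  category means and is an interpretation, not a canonical procedure.
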