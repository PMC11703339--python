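# Methods

## The scientific question and the modeling strategy

The package studies whether accelerated epigenetic aging in midlife predicts
change in cognitive ability since childhood, and whether childhood
socioeconomic status (SES) moderates that effect. Because DNA-methylation
age (DNAmAge) and IQ are both heritable and both shaped by the rearing
family, a raw association between the two is confounded at the family
level. The co-twin control design addresses this: monozygotic (MZ) co-twins
share all segregating genetic variation and their rearing environment, so a
within-pair association between DNAmAge and IQ change cannot be produced by
genetic or shared-environmental confounds. The "quasi-causal" structural
model formalizes this by decomposing each phenotype into additive-genetic
(A), shared-environment (C) and nonshared (E) components and estimating the
phenotypic regressions conditional on explicit A- and C-paths.

## Structural model

Three phenotypes per twin `j` in a family with centered SES `s`:
childhood IQ `X`, a latent DNAmAge factor `M`, adult IQ `Y`:

    X_j = mu_x + b_sx*s + A_Xj + C_X + E_Xj
    M_j = mu_m + b_sm*s + b_p2*X_j + b_a2*A_Xj + b_c2*C_X + A_Mj + C_M + E_Mj
    Y_j = mu_y + b_sy*s + b_p1*X_j + (b_p3 + b_int*s)*M_j
          + b_a1*A_Xj + b_c1*C_X + b_a3*A_Mj + b_c3*C_M + A_Yj + C_Y + E_Yj

A-components are correlated 1.0 across MZ and 0.5 across DZ co-twins,
C-components are shared, E-components are independent. Latent paths to the
observed variables are fixed at 1 and the component variances
(V_A, V_C, V_E per phenotype) are estimated. Because childhood IQ appears
as a regressor in the adult-IQ equation, `b_p3` and the SES terms are
interpretable as effects on IQ *change* (ΔIQ). `b_p3` is the quasi-causal
effect of age acceleration; `b_a1..b_c3` absorb family-level confounding.

The SES × DNAmAge interaction is handled as a *definition variable*: the
family's observed centered SES enters the M→Y slope, `q = b_p3 + b_int*s`,
so both the implied mean vector and the implied covariance matrix of a
family's observations depend on its own SES. The coherent-likelihood
alternative (a latent product term) is out of scope; the definition-variable
treatment is standard in twin SEM and exact when SES is observed, as here.
SES is centered at the analysis-sample mean before the product is formed;
`M` enters the product as the observed variable, not a latent factor.

### Likelihood and estimation

Families contribute a multivariate-normal likelihood of whatever they
observed (full-information ML): complete pairs contribute all six
observations `(X1, M1, Y1, X2, M2, Y2)`, singleton families the subvector
present. The implied moments come from the factor representation
`obs = mean(s) + T(q) u` with `T(q) = T0 + q*T1` over the 15 latent
components, so `Sigma(q) = A0 + q*A1 + q^2*A2`. `T0`, `T1` and the latent
covariance are affine in the canonical parameters, which gives exact
analytic gradients; the engine evaluates all families of one
zygosity-by-missingness pattern in a single vectorized pass.

Optimization is quasi-Newton (L-BFGS-B, memory 40, analytic gradient) on an
internally standardized metric (each variable scaled by its sample SD) with
moment/OLS starting values and jittered restarts on failure; estimates and
Wald covariance are mapped back to the native scale by the exact diagonal
reparameterization. Standard errors come from the observed information
(central differences of the analytic gradient). The reported log-likelihood
is exact on the native scale; an independently coded per-family density
(tests) reproduces it to 1e-8.

The *phenotypic association model* — the regression system X~S, M~X+S,
Y~X+M+S+S·M with coefficients equated across twin slots and a within-pair
residual covariance per phenotype — is fit in the same engine with all
latent-A structure fixed at zero (the within-pair covariance carried by the
shared component). It is therefore an exact submodel of the quasi-causal
model, and loglik(quasi) ≥ loglik(phenotypic) holds by construction. The
residual covariance is pooled across zygosity by default; a
zygosity-specific mode is available.

Shared-environment variances may go negative during unconstrained
estimation. Following the conventional workflow, the default refits with
V_C ≡ 0 for any phenotype whose unconstrained estimate is negative and
reports the constraint; the corresponding b_c path (which loses
identification when its component variance is zero) is fixed at zero. An
explicit constraint set can be supplied instead, which is what the
replicate studies use when the generating truth itself has V_C = 0.

## Clock preprocessing

Raw clock estimates (years) are turned into age-acceleration scores:
OLS residualization on chronological age at the adult assessment; further
residualization on the first two principal components of the six blood-cell
proportions (sign-fixed, largest-magnitude loading positive; a
cumulative-variance mode is available but off by default); winsorization at
mean ± 2 pre-winsorization sample SDs (applied once, bounds not
re-estimated); z-standardization. All fits pool both zygosities, use the
full analysis sample, and use the n−1 SD denominator. Composites are plain
sums of member z-scores — Gen 1: Horvath, Horvath Skin & Blood, Hannum;
Gen 2: PhenoAge, GrimAge — and are deliberately not re-standardized, so a
composite of m strongly correlated members has SD between 1 and m.
Residualization uses adult age only (the clocks are midlife measures).
Standardization is computed over the rows entering composites (all five
clocks present), so composite means are exactly zero.

## Exploratory factor analysis

ML EFA on the correlation metric (Wishart likelihood): for fixed
uniquenesses the profile loadings come from the eigenstructure of the
uniqueness-scaled correlation matrix; the discrepancy is minimized over
log-uniquenesses (bounded below at 1e-4; solutions at the bound are flagged
as Heywood cases). Oblique geomin rotation (ε = 0.01) uses gradient
projection with 30 random starts, keeping the best criterion; rotated
columns are ordered by sum of squared loadings with the dominant loading
positive. Model fit: χ² = (n−1)·F against the saturated model,
df = ((p−m)² − (p+m))/2, RMSEA with confidence limits from inverting the
noncentral χ². Missing clock rows are handled listwise or (default) by
two-stage full-information ML: EM estimation of the saturated
mean/covariance, then Wishart ML on the implied correlation with n = rows
contributing data; for complete data the two routes coincide exactly. The
factor loading most on the chronological-age clocks is labeled Gen 1.
The implementation was cross-checked against R's `factanal` (identical
solutions to the optimizer floor on shared inputs); composites are defined
by the a-priori clock groupings, with a loading-threshold sensitivity mode.

## Univariate twin models

Pair correlations are ML estimates under a bivariate normal with means and
variances equated across twin slots, per zygosity, complete pairs only,
with observed-information SEs through the Fisher-z parameterization.
The ACE model is two-group FIML with means equated across slots and groups;
singletons contribute univariate marginals. Both a direct variance
parameterization (V_C free to go negative) and a Cholesky-style
standard-deviation parameterization are provided and reach the same
maximized likelihood. Wald CIs on standardized shares use the delta method;
profile-likelihood intervals (χ²(1) cutoff) are available, with boundary
flags when a parameter is pinned (e.g. V_C = 0 in an AE-constrained fit).

## Synthetic cohort generator

The generator emulates the midlife twin cohort the analysis assumes: 186
families (110 MZ, 76 DZ by default), family-level Duncan-index SES drawn
from a [0, 100]-truncated normal whose *post-truncation* moments match the
targets (47.3, 25.7) — the parent parameters are solved numerically — and
test ages of 14.4 (1.93) and 51.9 (7.03) years shared within a pair.
Phenotypes follow the structural model above. Default native-unit
coefficients were chosen once to reproduce the published marginal scales
and twin-correlation ranges: childhood IQ 102.7 (13.4) with MZ/DZ
correlations near 0.88/0.58, a unit-variance DNAm factor with composite
correlations near 0.66/0.35, adult IQ near 105.4 (13.8).

Clock readouts are generated at the years-of-DNAmAge level: unit age slope,
a granulocyte-fraction effect (cell proportions are Dirichlet with means
ordered granulocytes > CD4 > CD8 > monocytes > B > NK), a loading on one of
two correlated generation factors (r = 0.57; the Gen 2 factor is the
standardized structural M), and clock-specific residual variation. Because
published clock measurement-error magnitudes are unavailable, the split
between common-factor and clock-specific variance (loadings ≈ 0.8 of the
target SD) and the heritable share of the clock-specific part (0.6) are
non-canonical defaults chosen to land the clock-level MZ/DZ correlations in
the plausible 0.55–0.65 / 0.28–0.35 range; both are exposed in the config.

"Singleton" families lose slot-2 adult-phase fields (adult IQ, clocks,
cells) but keep childhood records, matching a design where all twins were
studied as children and only some returned in midlife. The
`singleton_fraction` is specified on the individual scale (share of midlife
participants without a participating co-twin, anchored at 85/287 ≈ 0.296)
and converted internally to the per-family deletion probability
`2f/(1+f)`. The generator also writes each twin's error-free latent M
(`dnam_latent`) so estimator-validation studies can fit the structural
model without measurement-error attenuation; real data would not contain
this column.

What the generator does *not* emulate: methylation arrays, probe-level QC,
reference-based cell deconvolution, non-normal phenotype distributions,
age-dependent measurement error, sex-specific variance components
(opposite-sex DZ pairs are generated but modeled with genetic correlation
0.5 like same-sex DZ), and selective attrition (singleton status is
missing-completely-at-random). Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to their violation.

## Validation-study conditions and problem sizes

- Parameter recovery: 100 replicates of 2,500 MZ + 2,500 DZ pairs
  simulated at the published-scale generating values (b_p1 = 0.48,
  b_p3 = −0.18, b_int = 0.07, SES→M = −0.67; variance panel 1.06/0.21/0.23,
  1.73/0/0.80, 0.43/0/0.23; SES standardized). Fits constrain V_C of M and
  Y to zero, mirroring the generating truth. Across independent replicate
  batches the estimator is unbiased (componentwise batch means straddle
  truth within ~3 MC SEs, with signs varying by batch) and Wald SEs match
  the empirical spread within 6%. Note that checking 11 components
  simultaneously at ±2 MC SE is itself a stochastic criterion: an exact
  estimator passes all 11 in a given 100-replicate batch only ~57% of the
  time. A notable by-product: the phenotypic model fit to the same data
  yields b_p3 ≈ −0.10 — the attenuation pattern expected when family-level
  confounds are uncontrolled.
- Confound correction: 100 replicates of 1,000 + 1,000 pairs with
  b_p3 = 0 and genetic confounding b_a3 = 0.6 through the DNAm factor's A
  component (V_A(M) = V_E(M) = 1). The phenotypic slope is biased to
  ≈ +0.24 while the quasi-causal estimate is centered on zero with
  empirical spread equal to the mean reported SE within 0.5% — i.e. the
  Wald intervals are calibrated at their nominal level; any single
  100-replicate coverage count still fluctuates binomially around 95.
- EFA study: 100 replicates of n = 5,000 panels from the two-factor
  structure (loadings 0.8/0.8/0.8 and 0.85/0.8, factor r = 0.57).

## Numerical choices and degenerate inputs

- Convergence: L-BFGS-B with ftol 1e-13, projected-gradient tolerance 1e-7,
  up to 3 jittered restarts (10 for the univariate ACE optimizer, which
  polishes a Nelder-Mead pass with BFGS).
- Nonshared variances are bounded below at 1e-8 (scaled metric); a fit
  pinned there raises rather than reporting a boundary solution.
- Non-positive-definite implied covariances during line search are rejected
  with a large objective value rather than an exception.
- Constant age vectors, zero-variance PCs, all-identical cell profiles, and
  sub-minimal sample sizes raise typed errors naming the problem.
- Winsorization of a zero-SD vector warns and returns the input unchanged.
- Ties in geomin random starts resolve to the first-found minimum under a
  fixed rotation seed, making runs reproducible.

## Known limitations

- When the DNAm factor's variance is dominated by its A component and
  confounding runs through b_a3, the (b_p3, b_a3) pair approaches
  collinearity; the MLE then shows excess spread over the information bound
  (≈25% at 4,000 pairs in internal pilots) and Wald intervals undercover
  until much larger samples. Profile intervals match Wald here, so this is
  a property of the likelihood surface, not of the SE computation. In such
  designs the within-MZ-pair difference regression is a robust companion
  check.
- The two-indicator Gen 2 factor makes entrywise EFA loading recovery
  ill-conditioned: the (PhenoAge, GrimAge) loading split drifts along a
  likelihood ridge with sampling SD ≈ 0.1 at n = 5,000 and frequently ends
  at a Heywood boundary — behaviour shared by reference implementations.
  Population-level recovery is exact to the geomin criterion's smearing
  (< 0.04); single-sample loading values for that factor should be read
  with corresponding caution.
- Wald p-values and CIs are asymptotic; no bootstrap inference, no
  multiple-testing correction across composites, no dominance (ADE) models,
  and no formal causal identification beyond the co-twin-control logic.
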