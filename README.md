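# twinclock

Twin-cohort analysis of second-generation epigenetic-clock age acceleration
and childhood-to-midlife IQ change, with childhood socioeconomic status
(SES) as a moderator.

DNA-methylation age (DNAmAge) estimates — Horvath, Horvath Skin & Blood,
Hannum, PhenoAge, GrimAge — index biological aging. Both DNAmAge and
cognitive ability are heritable and shaped by the rearing family, so an
observed association between age acceleration and cognitive decline may be
entirely family-level confounding. This package implements the
co-twin-control ("quasi-causal") analysis that addresses this: monozygotic
co-twins are matched for genes and rearing environment, so a within-pair
association survives both confounds. It is built for a midlife twin cohort
with prospective childhood IQ, family-level Duncan-index SES, five
PC-trained clock estimates per adult twin, blood-cell proportions, and a
large share of "singleton" twins whose co-twin contributed childhood data
only — and, since such data are not public, ships a synthetic-cohort
generator with the same statistical structure, so every stage is testable
end to end.

## The model

Clock estimates are turned into age-acceleration scores (residualized on
chronological age and the first two cell-composition PCs, winsorized at
±2 SD), z-scored, and summed into Gen 1 (Horvath, Horvath Skin & Blood,
Hannum) and Gen 2 (PhenoAge, GrimAge) composites; an ML exploratory factor
analysis with geomin rotation establishes the two-factor structure. Each
variable's variance is decomposed by the classical twin model into additive
genetic (A, cross-twin correlation 1.0 MZ / 0.5 DZ), shared-environment (C)
and nonshared (E) components. The quasi-causal structural model is, per
twin `j` with centered family SES `s` (X = childhood IQ, M = DNAmAge
factor, Y = adult IQ):

    X_j = mu_x + b_sx*s + A_Xj + C_X + E_Xj
    M_j = mu_m + b_sm*s + b_p2*X_j + b_a2*A_Xj + b_c2*C_X + A_Mj + C_M + E_Mj
    Y_j = mu_y + b_sy*s + b_p1*X_j + (b_p3 + b_int*s)*M_j
          + b_a1*A_Xj + b_c1*C_X + b_a3*A_Mj + b_c3*C_M + A_Yj + C_Y + E_Yj

Because childhood IQ is conditioned on, `b_p3` is the effect of age
acceleration on IQ *change* (ΔIQ), purged of family-level genetic and
shared-environmental confounding by the explicit b_a/b_c paths; `b_int`
lets the effect depend on childhood SES. Estimation is full-information
maximum likelihood over MZ/DZ groups with per-family implied moments (the
SES × M interaction is a definition variable entering each family's mean
and covariance), analytic gradients, and observed-information Wald errors.
The phenotypic-association model (no latent A/C control) is the nested
reference fit. See `docs/methods.md` for assumptions, numerical choices
and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_prepare_clocks.py
python analysis/03_factor_structure.py
python analysis/04_twin_heritability.py
python analysis/05_quasicausal_models.py
python analysis/06_recovery_study.py --replicates 10
```

`01` prints the cohort demographics (a 186-family draw):

```
simulated 186 families: 113 complete pairs, 73 singletons, 299 midlife participants
childhood IQ: mean 102.6 (SD 12.9, n 372)
adult IQ: mean 104.7 (SD 13.2, n 299)
childhood SES: mean 48.7 (SD 25.9)
```

`03` reports the clock factor structure — the eigenvalue drop after two
factors, the 1-vs-2-factor likelihood-ratio test (df = 4), and the
correlated Gen 1 / Gen 2 factors:

```
eigenvalues: 2.72, 1.19, 0.47, 0.34, 0.28
1-vs-2-factor LRT: chi2 140.86, df 4, p 1.8e-29
factor correlation r = 0.38
```

`04` decomposes each composite's variance; at this cohort size the Gen 2
composite is substantially heritable with the shared-environment variance
constrained to zero after its unconstrained estimate went negative:

```
gen2  [AE-constrained] a2 0.62 [0.48, 0.75]  c2 0.00  e2 0.38
```

`06` is the estimator-validation study: it simulates at the published-scale
generating values and refits, e.g. (10 replicates of 5,000 pairs):

```
b_p3   truth  -0.180  mean  -0.181  sd  0.011
b_int  truth   0.070  mean   0.072  sd  0.003
```

and shows that the *phenotypic* model on the same data gives b_p3 ≈ −0.10:
exactly the attenuation pattern expected when family-level confounds are
left uncontrolled. A `twinclock` CLI (`simulate`, `prep`, `efa`, `ace`,
`fit`, `all`, `report`) wraps the same stages; `twinclock all --seed 0
--out run/` writes the full report bundle with a hash manifest.

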