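"""Phenotypic and quasi-causal models of DNAm age and IQ change.

For each generation composite, fits (i) the phenotypic-association model
(midlife IQ on childhood IQ, SES, the composite, and SES x composite, with
within-pair residual covariance) and (ii) the quasi-causal model that adds
latent A/C control of both childhood IQ and the composite, so the b_p3
coefficient is purged of family-level confounding. Reports simple slopes of
the composite effect at low/high SES and writes the moderation scatter.
"""

from pathlib import Path

import pandas as pd

from twinclock import (fit_phenotypic, fit_quasicausal,
                       moderation_scatter_data, simple_slopes, wald_test)
from twinclock.pipeline import path_model_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    wide = pd.read_csv(RESULTS / "cohort_with_composites.csv", na_values=["NA"])
    for comp in ("gen1", "gen2"):
        pheno = fit_phenotypic(wide, comp)
        quasi = fit_quasicausal(wide, comp)
        print(f"\n=== {comp} composite ===")
        for label, fit in (("phenotypic", pheno), ("quasi-causal", quasi)):
            w = wald_test(fit, "b_p3")
            print(f"{label:13s} b_p3 {fit.coef('b_p3'):+.3f} "
                  f"(SE {fit.se['b_p3']:.3f}, p {w['p']:.3f})  "
                  f"b_int {fit.coef('b_int'):+.4f} "
                  f"(SE {fit.se['b_int']:.4f})  loglik {fit.loglik:.1f}")
        fixed = [ph for ph, c in quasi.constraints.items() if c]
        if fixed:
            print(f"shared-environment variances fixed at zero for: {fixed}")
        eff = simple_slopes(quasi, wide, split="median")
        print(f"simple slopes (median SES split): "
              f"low {eff.slopes['low_ses']:+.3f} "
              f"(SE {eff.slope_se['low_ses']:.3f}), "
              f"high {eff.slopes['high_ses']:+.3f} "
              f"(SE {eff.slope_se['high_ses']:.3f})")
        path_model_table({"phenotypic": pheno, "quasi-causal": quasi}) \
            .to_csv(RESULTS / f"path_model_{comp}.csv", index=False)
        moderation_scatter_data(wide, comp) \
            .to_csv(RESULTS / f"moderation_scatter_{comp}.csv", index=False)


if __name__ == "__main__":
    main()
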