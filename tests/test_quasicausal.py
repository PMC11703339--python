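"""Phenotypic and quasi-causal path models: likelihood correctness,
recovery, nesting, and post-fit utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from twinclock import (PathModelFit, StructuralParams, family_loglik,
                       fit_phenotypic, fit_quasicausal,
                       moderation_scatter_data, recovery_config,
                       reference_structural_params, simple_slopes,
                       simulate_cohort, wald_test)
from twinclock.errors import EstimationError
from twinclock.params import PARAM_NAMES


def brute_force_loglik(params: StructuralParams, wide: pd.DataFrame,
                       dnam: str, ses_center: float) -> float:
    """Independent oracle: per-family multivariate-normal density with the
    implied moments derived by direct substitution of the structural
    equations (latents eliminated one observed variable at a time)."""
    g = params.as_dict()
    ll = 0.0
    for _, row in wide.iterrows():
        s = row["ses"] - ses_center
        rg = 1.0 if row["zygosity"] == "MZ" else 0.5
        q = g["b_p3"] + g["b_int"] * s
        # latent covariance: A_P pair block, shared C_P, independent E_P
        Phi = np.zeros((15, 15))
        for base, ph in zip((0, 5, 10), "xmy"):
            va, vc, ve = g[f"va_{ph}"], g[f"vc_{ph}"], g[f"ve_{ph}"]
            Phi[base, base] = Phi[base + 1, base + 1] = va
            Phi[base, base + 1] = Phi[base + 1, base] = rg * va
            Phi[base + 2, base + 2] = vc
            Phi[base + 3, base + 3] = Phi[base + 4, base + 4] = ve
        T = np.zeros((6, 15))
        for j in (0, 1):
            ax, ex, am, em = 0 + j, 3 + j, 5 + j, 8 + j
            ay, ey, cx, cm, cy = 10 + j, 13 + j, 2, 7, 12
            # X = A_X + C_X + E_X (+ mean terms)
            T[3 * j, [ax, cx, ex]] = 1.0
            # M = b_p2 X + b_a2 A_X + b_c2 C_X + A_M + C_M + E_M
            m_row = np.zeros(15)
            m_row[ax] = g["b_p2"] + g["b_a2"]
            m_row[cx] = g["b_p2"] + g["b_c2"]
            m_row[ex] = g["b_p2"]
            m_row[[am, cm, em]] = 1.0
            T[3 * j + 1] = m_row
            # Y = b_p1 X + q M + b_a1 A_X + b_c1 C_X + b_a3 A_M + b_c3 C_M
            #     + A_Y + C_Y + E_Y
            y_row = q * m_row
            y_row[ax] += g["b_p1"] + g["b_a1"]
            y_row[cx] += g["b_p1"] + g["b_c1"]
            y_row[ex] += g["b_p1"]
            y_row[am] += g["b_a3"]
            y_row[cm] += g["b_c3"]
            y_row[[ay, cy, ey]] = 1.0
            T[3 * j + 2] = y_row
        sigma = T @ Phi @ T.T
        mx = g["mu_x"] + g["b_sx"] * s
        mm = g["mu_m"] + g["b_sm"] * s + g["b_p2"] * mx
        my = g["mu_y"] + g["b_sy"] * s + g["b_p1"] * mx + q * mm
        mean = np.array([mx, mm, my, mx, mm, my])
        obs = np.array([row["child_iq_1"], row[f"{dnam}_1"], row["adult_iq_1"],
                        row["child_iq_2"], row[f"{dnam}_2"], row["adult_iq_2"]])
        fin = np.isfinite(obs)
        ll += multivariate_normal.logpdf(obs[fin], mean[fin],
                                         sigma[np.ix_(fin, fin)])
    return float(ll)


class TestLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_engine_matches_brute_force_density(self, seed):
        cfg = recovery_config(10, 10, rng_seed=seed)
        cfg.singleton_fraction = 0.3
        wide = simulate_cohort(cfg).data
        params = reference_structural_params().replace(vc_m=0.05, vc_y=0.04,
                                                       b_c3=0.1)
        center = float(wide["ses"].mean())
        ll = family_loglik(params, wide, "dnam_latent", center)
        oracle = brute_force_loglik(params, wide, "dnam_latent", center)
        assert abs(ll - oracle) < 1e-8

    def test_analytic_gradient_matches_finite_differences(self):
        from twinclock.quasicausal import _NP, _build_groups, _nll_and_grad
        cfg = recovery_config(25, 25, rng_seed=9)
        wide = simulate_cohort(cfg).data
        scales = {"x": 1.0, "m": 1.0, "y": 1.0, "s": 1.0}
        groups = _build_groups(wide, "dnam_latent", wide["ses"].mean(), scales)
        gmaps = [np.arange(_NP) for _ in groups]
        fixed = np.zeros(_NP)
        theta = reference_structural_params().to_array() + 0.03
        _, grad = _nll_and_grad(theta, groups, fixed, gmaps)
        for i in range(_NP):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            num = (_nll_and_grad(tp, groups, fixed, gmaps, False)[0]
                   - _nll_and_grad(tm, groups, fixed, gmaps, False)[0]) / (2 * h)
            assert abs(grad[i] - num) <= 1e-5 * max(1.0, abs(num)), PARAM_NAMES[i]


class TestPhenotypicModel:
    def test_null_data_recovers_zero_coefficients(self):
        cfg = recovery_config(500, 500, rng_seed=10)
        cfg.structural = StructuralParams(
            va_x=0.5, vc_x=0.2, ve_x=0.3, va_m=0.5, vc_m=0.2, ve_m=0.3,
            va_y=0.5, vc_y=0.2, ve_y=0.3)
        fit = fit_phenotypic(simulate_cohort(cfg), "dnam_latent")
        for name in ("b_sx", "b_sm", "b_sy", "b_p1", "b_p2", "b_p3", "b_int"):
            assert abs(fit.coef(name)) < 3 * fit.se[name] + 1e-6, name

    def test_moderate_effects_recovered(self):
        cfg = recovery_config(1000, 1000, rng_seed=11,
                              b_p3=-0.10, b_int=0.06,
                              b_a1=0, b_c1=0, b_a2=0, b_c2=0, b_a3=0, b_c3=0)
        fit = fit_phenotypic(simulate_cohort(cfg), "dnam_latent")
        assert abs(fit.coef("b_p3") - (-0.10)) < 3 * fit.se["b_p3"]
        assert abs(fit.coef("b_int") - 0.06) < 3 * fit.se["b_int"]

    def test_unpaired_individuals_reduce_to_ols(self):
        """With one observed twin per family and no residual covariance the
        triangular system factorizes; ML equals equation-wise OLS."""
        rng = np.random.default_rng(12)
        n = 400
        s = rng.normal(0, 1, n)
        x = 1.0 + 0.5 * s + rng.normal(0, 1, n)
        m = -0.3 + 0.4 * x - 0.6 * s + rng.normal(0, 1, n)
        y = 2.0 + 0.5 * x - 0.2 * m + 0.1 * s + 0.05 * s * m \
            + rng.normal(0, 1, n)
        wide = pd.DataFrame({
            "family_id": np.arange(n), "zygosity": ["MZ", "DZ"] * (n // 2),
            "ses": s + 50.0,
            "child_iq_1": x, "dnam_1": m, "adult_iq_1": y,
            "child_iq_2": np.nan, "dnam_2": np.nan, "adult_iq_2": np.nan,
        })
        fit = fit_phenotypic(wide, "dnam", constrain_c="always")
        sc = s - s.mean()
        X = np.column_stack([np.ones(n), x, m, sc, sc * m])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(fit.coef("b_p1") - beta[1]) < 1e-6
        assert abs(fit.coef("b_p3") - beta[2]) < 1e-6
        assert abs(fit.coef("b_sy") - beta[3]) < 1e-6
        assert abs(fit.coef("b_int") - beta[4]) < 1e-6


class TestQuasiCausalModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = recovery_config(400, 400, rng_seed=13)
        wide = simulate_cohort(cfg).data
        quasi = fit_quasicausal(wide, "dnam_latent", constrain_c={"m", "y"})
        pheno = fit_phenotypic(wide, "dnam_latent")
        return wide, pheno, quasi

    def test_phenotypic_nested_in_quasicausal(self, fitted):
        wide, pheno, quasi = fitted
        assert quasi.loglik >= pheno.loglik - 1e-6
        # the phenotypic solution is a point of the quasi-causal family
        embedded = family_loglik(pheno.params, wide, "dnam_latent",
                                 pheno.ses_center)
        assert abs(embedded - pheno.loglik) < 1e-6

    def test_invariant_to_twin_slot_permutation(self, fitted):
        wide, _, quasi = fitted
        df = wide.copy()
        swap = df.index % 3 == 0
        for c in ("child_iq", "adult_iq", "dnam_latent", "sex", "horvath"):
            df.loc[swap, [f"{c}_1", f"{c}_2"]] = \
                df.loc[swap, [f"{c}_2", f"{c}_1"]].to_numpy()
        refit = fit_quasicausal(df, "dnam_latent", constrain_c={"m", "y"})
        assert abs(refit.loglik - quasi.loglik) < 1e-6
        assert abs(refit.coef("b_p3") - quasi.coef("b_p3")) < 1e-4

    def test_invariant_to_ses_shift(self, fitted):
        wide, _, quasi = fitted
        df = wide.copy()
        df["ses"] = df["ses"] + 250.0
        refit = fit_quasicausal(df, "dnam_latent", constrain_c={"m", "y"})
        assert abs(refit.coef("b_p3") - quasi.coef("b_p3")) < 1e-4
        assert abs(refit.coef("b_int") - quasi.coef("b_int")) < 1e-5
        assert abs(refit.ses_center - quasi.ses_center - 250.0) < 1e-9

    def test_agrees_with_mz_difference_regression(self):
        cfg = recovery_config(1500, 300, rng_seed=14,
                              b_a1=0, b_c1=0, b_a2=0, b_c2=0, b_a3=0, b_c3=0)
        wide = simulate_cohort(cfg).data
        quasi = fit_quasicausal(wide, "dnam_latent", constrain_c={"m", "y"})
        mz = wide[wide["zygosity"] == "MZ"]
        s = (mz["ses"] - wide["ses"].mean()).to_numpy()
        dx = (mz["child_iq_1"] - mz["child_iq_2"]).to_numpy()
        dm = (mz["dnam_latent_1"] - mz["dnam_latent_2"]).to_numpy()
        dy = (mz["adult_iq_1"] - mz["adult_iq_2"]).to_numpy()
        X = np.column_stack([dx, dm, s * dm])
        beta = np.linalg.lstsq(X, dy, rcond=None)[0]
        resid = dy - X @ beta
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * resid.var())
        assert abs(quasi.coef("b_p3") - beta[1]) < 3 * se[1]

    def test_requires_pairs_in_both_groups(self):
        cfg = recovery_config(30, 2, rng_seed=15)
        wide = simulate_cohort(cfg).data
        with pytest.raises(EstimationError):
            fit_quasicausal(wide, "dnam_latent")


class TestPostFit:
    @staticmethod
    def synthetic_fit(b_p3=-0.18, b_int=0.07, se_p3=0.07, se_int=0.03,
                      ses_center=0.0, ses_sd=1.0):
        cov = pd.DataFrame(np.diag([se_p3 ** 2, se_int ** 2]),
                           index=["b_p3", "b_int"], columns=["b_p3", "b_int"])
        return PathModelFit(
            model="quasi-causal", dnam_variable="gen2",
            params=StructuralParams(b_p3=b_p3, b_int=b_int),
            se={"b_p3": se_p3, "b_int": se_int},
            pvalues={}, loglik=0.0, converged=True, n_families=0,
            n_pairs={}, n_singletons=0, ses_center=ses_center, ses_sd=ses_sd,
            constraints={}, free_names=("b_p3", "b_int"), cov=cov)

    def test_simple_slope_arithmetic_at_plus_minus_one_sd(self):
        fit = self.synthetic_fit()
        dummy = pd.DataFrame({"ses": np.linspace(-2, 2, 50)})
        eff = simple_slopes(fit, dummy, split="plus_minus_1sd")
        assert np.isclose(eff.slopes["low_ses"], -0.25)
        assert np.isclose(eff.slopes["high_ses"], -0.11)

    def test_slope_at_centering_constant_equals_b_p3(self):
        fit = self.synthetic_fit(b_int=0.4)
        slope = fit.coef("b_p3") + fit.coef("b_int") * (fit.ses_center
                                                        - fit.ses_center)
        assert slope == fit.coef("b_p3")

    def test_zero_interaction_gives_identical_group_slopes(self):
        fit = self.synthetic_fit(b_int=0.0)
        dummy = pd.DataFrame({"ses": np.linspace(10, 90, 60)})
        eff = simple_slopes(fit, dummy, split="median")
        assert eff.slopes["low_ses"] == eff.slopes["high_ses"]

    def test_wald_arithmetic(self):
        fit = self.synthetic_fit()
        out = wald_test(fit, "b_p3")
        assert np.isclose(out["z"], -0.18 / 0.07, atol=1e-12)
        assert np.isclose(out["p"], 2 * stats.norm.sf(0.18 / 0.07), atol=1e-12)
        assert np.isclose(out["p"], 0.0101, atol=5e-4)
        null = self.synthetic_fit(b_p3=0.0)
        assert wald_test(null, "b_p3")["p"] == 1.0
        bad = self.synthetic_fit()
        bad.se["b_p3"] = 0.0
        with pytest.raises(EstimationError):
            wald_test(bad, "b_p3")

    def test_estimate_at_1p96_se_gives_p_close_to_05(self):
        fit = self.synthetic_fit(b_p3=1.96 * 0.07)
        assert abs(wald_test(fit, "b_p3")["p"] - 0.05) < 1e-3

    def test_moderation_scatter_residualizes_adult_iq(self):
        cfg = recovery_config(150, 150, rng_seed=16)
        wide = simulate_cohort(cfg).data
        scatter = moderation_scatter_data(wide, "dnam_latent")
        assert abs(scatter["adult_iq_residual"].mean()) < 1e-8
        assert set(scatter["ses_group"]) == {"low", "high"}
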