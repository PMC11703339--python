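"""Twin correlations and ACE variance decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from twinclock import (ace_loglik, falconer, fit_ace, loglik_profile_ci,
                       recovery_config, simulate_cohort, twin_correlations)
from twinclock.ace import _prepare
from twinclock.errors import EstimationError


def ace_cohort(va, vc, ve, n_mz, n_dz, seed, singleton_fraction=0.0):
    cfg = recovery_config(n_mz, n_dz, rng_seed=seed)
    cfg.singleton_fraction = singleton_fraction
    cfg.structural = cfg.structural.replace(
        b_sx=0, b_sm=0, b_sy=0, b_p1=0, b_p2=0, b_p3=0, b_int=0,
        b_a1=0, b_c1=0, b_a2=0, b_c2=0, b_a3=0, b_c3=0,
        va_x=va, vc_x=vc, ve_x=ve)
    return simulate_cohort(cfg)


def exact_correlation_pairs(r, n, mu=0.0, sd=1.0, seed=0):
    """Pairs whose sample moments match (mu, sd, r) exactly (whitening)."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 2))
    Z -= Z.mean(axis=0)
    L = np.linalg.cholesky(np.cov(Z, rowvar=False, ddof=1))
    Z = Z @ np.linalg.inv(L).T          # exact identity sample covariance
    target = np.array([[1.0, r], [r, 1.0]])
    return mu + sd * (Z @ np.linalg.cholesky(target).T)


def exact_cohort(r_mz, r_dz, n=2000, seed=0):
    rows = []
    fid = 0
    for zyg, r, s in (("MZ", r_mz, seed), ("DZ", r_dz, seed + 1)):
        pairs = exact_correlation_pairs(r, n, seed=s)
        for v1, v2 in pairs:
            fid += 1
            rows.append({"family_id": fid, "zygosity": zyg, "ses": 50.0,
                         "y_1": v1, "y_2": v2})
    return pd.DataFrame(rows)


class TestTwinCorrelations:
    def test_duplicated_cotwin_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=60)
        df = pd.DataFrame({
            "family_id": np.arange(120), "zygosity": ["MZ"] * 60 + ["DZ"] * 60,
            "ses": 50.0, "y_1": np.tile(v, 2), "y_2": np.tile(v, 2)})
        tc = twin_correlations(df, "y")
        assert tc.r_mz > 0.999 and tc.r_dz > 0.999

    def test_permuted_cotwins_uncorrelated(self):
        rng = np.random.default_rng(1)
        df = exact_cohort(0.6, 0.3, n=400, seed=2)
        for col in ("y_1", "y_2"):
            df[col] = rng.permutation(df[col].to_numpy())
        tc = twin_correlations(df, "y")
        assert abs(tc.r_mz) < 3 * tc.se_mz + 0.05
        assert abs(tc.r_dz) < 3 * tc.se_dz + 0.05

    def test_ml_matches_double_entry_icc(self):
        df = exact_cohort(0.71, 0.42, n=1500, seed=3)
        tc = twin_correlations(df, "y")
        for zyg, r_hat in (("MZ", tc.r_mz), ("DZ", tc.r_dz)):
            sub = df[df["zygosity"] == zyg]
            double = np.corrcoef(
                np.concatenate([sub["y_1"], sub["y_2"]]),
                np.concatenate([sub["y_2"], sub["y_1"]]))[0, 1]
            assert abs(r_hat - double) < 1e-3

    def test_invariant_to_slot_order(self):
        df = exact_cohort(0.6, 0.3, n=300, seed=4)
        swapped = df.rename(columns={"y_1": "y_2", "y_2": "y_1"})
        a, b = twin_correlations(df, "y"), twin_correlations(swapped, "y")
        assert np.isclose(a.r_mz, b.r_mz, atol=1e-6)
        assert np.isclose(a.r_dz, b.r_dz, atol=1e-6)

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({
            "family_id": [1, 2, 3, 4],
            "zygosity": ["MZ", "MZ", "DZ", "DZ"],
            "ses": 50.0,
            "y_1": [1.0, 2.0, 3.0, 4.0],
            "y_2": [1.5, 2.5, 3.5, 4.5]})
        with pytest.raises(EstimationError):
            twin_correlations(df, "y")


class TestFitACE:
    def test_no_familiality_gives_pure_e(self):
        cohort = ace_cohort(0.0, 0.0, 1.0, 1000, 1000, seed=6)
        fit = fit_ace(cohort, "child_iq", constrain_c_nonneg=False)
        for key in ("a2", "c2"):
            assert abs(fit.standardized[key]) < 3 * fit.standardized_se[key]
        assert fit.standardized["e2"] > 0.85

    def test_parameter_recovery_within_monte_carlo_error(self):
        cohort = ace_cohort(0.6, 0.0, 0.4, 2500, 2500, seed=7)
        fit = fit_ace(cohort, "child_iq")
        for key, truth in (("a2", 0.6), ("c2", 0.0), ("e2", 0.4)):
            se = max(fit.standardized_se[key], 1e-3)
            assert abs(fit.standardized[key] - truth) < 3 * se

    def test_ml_reproduces_falconer_on_exact_correlation_data(self):
        """Falconer closed forms at r_MZ=0.71, r_DZ=0.42: a2=0.58, c2=0.13,
        e2=0.29; ML on data generated at exactly those sample correlations
        agrees within 0.02."""
        expected = falconer(0.71, 0.42)
        assert np.isclose(expected["a2"], 0.58)
        assert np.isclose(expected["c2"], 0.13)
        assert np.isclose(expected["e2"], 0.29)
        df = exact_cohort(0.71, 0.42, n=2000, seed=8)
        fit = fit_ace(df, "y")
        for key in ("a2", "c2", "e2"):
            assert abs(fit.standardized[key] - expected[key]) < 0.02

    def test_cholesky_and_variance_parameterizations_agree(self):
        for seed in range(3):
            cohort = ace_cohort(0.5, 0.2, 0.3, 150, 150, seed=20 + seed)
            a = fit_ace(cohort, "child_iq", parameterization="variance")
            b = fit_ace(cohort, "child_iq", parameterization="cholesky")
            assert abs(a.loglik - b.loglik) < 1e-6

    def test_fiml_equals_direct_density_without_singletons(self):
        cohort = ace_cohort(0.5, 0.2, 0.3, 100, 100, seed=30)
        fit = fit_ace(cohort, "child_iq")
        v = fit.variances
        ll = ace_loglik(cohort, "child_iq", fit.mu,
                        v["V_A"], v["V_C"], v["V_E"])
        # independent direct evaluation with scipy densities
        direct = 0.0
        total = v["V_A"] + v["V_C"] + v["V_E"]
        for zyg, rg in (("MZ", 1.0), ("DZ", 0.5)):
            sub = cohort.data[cohort.data["zygosity"] == zyg]
            pairs = sub[["child_iq_1", "child_iq_2"]].to_numpy()
            cov = rg * v["V_A"] + v["V_C"]
            sigma = np.array([[total, cov], [cov, total]])
            direct += multivariate_normal.logpdf(
                pairs, [fit.mu, fit.mu], sigma).sum()
        assert abs(ll - direct) < 1e-8
        assert abs(fit.loglik - direct) < 1e-6

    def test_singletons_contribute_marginals(self):
        cohort = ace_cohort(0.5, 0.2, 0.3, 400, 400, seed=31,
                            singleton_fraction=0.3)
        fit = fit_ace(cohort, "child_iq")
        assert fit.n_singletons == 0  # childhood IQ observed for everyone
        fit2 = fit_ace(cohort, "adult_iq")
        assert fit2.n_singletons > 0
        assert fit2.converged

    def test_estimates_invariant_to_slot_swap(self):
        cohort = ace_cohort(0.5, 0.2, 0.3, 200, 200, seed=32)
        df = cohort.data.copy()
        swap = df.index % 2 == 0
        for c in ("child_iq",):
            df.loc[swap, [f"{c}_1", f"{c}_2"]] = \
                df.loc[swap, [f"{c}_2", f"{c}_1"]].to_numpy()
        a = fit_ace(cohort, "child_iq")
        b = fit_ace(df, "child_iq")
        assert abs(a.loglik - b.loglik) < 1e-6
        assert abs(a.variances["V_A"] - b.variances["V_A"]) < 1e-4

    def test_negative_c_triggers_ae_constraint(self):
        # r_DZ < r_MZ/2 pushes the shared-environment variance negative
        df = exact_cohort(0.6, 0.1, n=800, seed=33)
        unconstrained = fit_ace(df, "y", constrain_c_nonneg=False)
        assert unconstrained.variances["V_C"] < 0
        fit = fit_ace(df, "y", constrain_c_nonneg=True)
        assert fit.status == "AE-constrained"
        assert fit.variances["V_C"] == 0.0
        assert fit.loglik <= unconstrained.loglik + 1e-9

    def test_model_nesting_orders_logliks(self):
        cohort = ace_cohort(0.5, 0.2, 0.3, 200, 200, seed=34)
        ace = fit_ace(cohort, "child_iq", constrain_c_nonneg=False)
        prep = _prepare(cohort, "child_iq")
        # E-only model: iid normal; closed-form ML
        vals = np.concatenate([prep[z]["pairs"].ravel() for z in ("MZ", "DZ")])
        mu, v = vals.mean(), vals.var()
        ll_e = ace_loglik(cohort, "child_iq", mu, 0.0, 0.0, v)
        assert ace.loglik >= ll_e - 1e-9

    def test_standardized_shares_sum_to_one(self):
        cohort = ace_cohort(0.5, 0.2, 0.3, 150, 150, seed=35)
        fit = fit_ace(cohort, "child_iq")
        assert abs(sum(fit.standardized.values()) - 1.0) < 1e-6


class TestProfileCI:
    @pytest.fixture(scope="class")
    def fitted(self):
        cohort = ace_cohort(0.6, 0.15, 0.25, 400, 400, seed=40)
        return fit_ace(cohort, "child_iq")

    def test_interval_contains_point_estimate(self, fitted):
        lo, hi, flags = loglik_profile_ci(fitted, "V_A")
        assert lo <= fitted.variances["V_A"] <= hi

    def test_profile_close_to_wald_at_large_n(self, fitted):
        lo, hi, _ = loglik_profile_ci(fitted, "V_A")
        half = (hi - lo) / 2
        wald_half = 1.96 * fitted.variance_se["V_A"]
        assert abs(half - wald_half) / wald_half < 0.10

    def test_boundary_parameter_flagged(self):
        df = exact_cohort(0.6, 0.1, n=800, seed=41)
        fit = fit_ace(df, "y")
        assert fit.status == "AE-constrained"
        lo, hi, flags = loglik_profile_ci(fit, "V_C")
        assert lo == 0.0
        assert flags["lower_boundary"]
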