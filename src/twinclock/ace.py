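"""Classical twin-model machinery: MZ/DZ pair correlations and univariate
ACE variance decomposition by two-group full-information ML.

The ACE model writes the phenotypic variance as V = V_A + V_C + V_E with
implied pair covariance matrices

    Sigma_MZ = [[V, V_A + V_C], [V_A + V_C, V]]
    Sigma_DZ = [[V, 0.5*V_A + V_C], [0.5*V_A + V_C, V]]

(the additive-genetic component is correlated 1.0 within MZ and 0.5 within
DZ pairs; the shared environment is common to both twins). Means and
variances are equated across twin slots and zygosity groups. Singleton
twins contribute their univariate marginal likelihood. The shared-
environment variance may go negative during unconstrained estimation; the
conventional workflow then refits with V_C = 0 and reports the constrained
AE model, which this module automates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._numdiff import hessian
from .cohort import TwinCohort
from .errors import EstimationError

_BIG = 1e12


# ---------------------------------------------------------------------------
# data preparation

def _wide(data) -> pd.DataFrame:
    return data.data if isinstance(data, TwinCohort) else data


def _prepare(data, variable: str) -> dict:
    """Sufficient statistics per zygosity: complete pairs and singletons."""
    df = _wide(data)
    c1, c2 = f"{variable}_1", f"{variable}_2"
    out = {}
    for zyg, rg in (("MZ", 1.0), ("DZ", 0.5)):
        sub = df[df["zygosity"] == zyg]
        v1, v2 = sub[c1].to_numpy(float), sub[c2].to_numpy(float)
        both = np.isfinite(v1) & np.isfinite(v2)
        pairs = np.column_stack([v1[both], v2[both]])
        singles = np.concatenate([
            v1[np.isfinite(v1) & ~both], v2[np.isfinite(v2) & ~both]])
        out[zyg] = {
            "rg": rg,
            "n_pairs": len(pairs),
            "pair_sum": pairs.sum(axis=0),
            "pair_sq": pairs.T @ pairs,
            "n_singles": len(singles),
            "single_sum": singles.sum(),
            "single_sq": float(singles @ singles),
            "pairs": pairs,
        }
    return out


def _pair_loglik(stats_g: dict, mu: float, v: float, c: float) -> float:
    """Bivariate-normal loglik with equal means/variances from suffstats."""
    n = stats_g["n_pairs"]
    ll = 0.0
    if n:
        det = v * v - c * c
        if det <= 0 or v <= 0:
            return -_BIG
        S = (stats_g["pair_sq"]
             - np.outer(mu * np.ones(2), stats_g["pair_sum"])
             - np.outer(stats_g["pair_sum"], mu * np.ones(2))
             + n * mu * mu)
        inv = np.array([[v, -c], [-c, v]]) / det
        ll += (-n * np.log(2 * np.pi) - 0.5 * n * np.log(det)
               - 0.5 * float(np.sum(inv * S)))
    m = stats_g["n_singles"]
    if m:
        if v <= 0:
            return -_BIG
        rss = stats_g["single_sq"] - 2 * mu * stats_g["single_sum"] + m * mu * mu
        ll += -0.5 * m * np.log(2 * np.pi * v) - 0.5 * rss / v
    return ll


def ace_loglik(data_or_prep, variable: str | None, mu: float,
               va: float, vc: float, ve: float) -> float:
    """Two-group FIML log-likelihood of an ACE parameter point."""
    prep = data_or_prep if isinstance(data_or_prep, dict) \
        else _prepare(data_or_prep, variable)
    v = va + vc + ve
    ll = 0.0
    for g in prep.values():
        ll += _pair_loglik(g, mu, v, g["rg"] * va + vc)
    return ll


# ---------------------------------------------------------------------------
# results

@dataclass
class TwinCorrelations:
    """ML cross-twin correlations per zygosity (complete pairs only)."""

    variable: str
    r_mz: float
    se_mz: float
    r_dz: float
    se_dz: float
    n_mz: int
    n_dz: int


@dataclass
class ACEEstimate:
    variable: str
    mu: float
    variances: dict            # raw V_A, V_C, V_E
    variance_se: dict
    standardized: dict         # a2, c2, e2
    standardized_se: dict
    standardized_ci: dict      # 95% Wald intervals
    loglik: float
    converged: bool
    status: str                # "ACE" or "AE-constrained"
    n_pairs: dict
    n_singletons: int
    _ctx: dict = field(repr=False, default_factory=dict)

    @property
    def total_variance(self) -> float:
        return sum(self.variances.values())


# ---------------------------------------------------------------------------
# twin correlations

def _fit_corr_group(pairs: np.ndarray):
    if len(pairs) < 3:
        raise EstimationError("need at least 3 complete pairs per zygosity")
    g = {
        "n_pairs": len(pairs),
        "pair_sum": pairs.sum(axis=0),
        "pair_sq": pairs.T @ pairs,
        "n_singles": 0, "single_sum": 0.0, "single_sq": 0.0,
    }

    def nll(theta):
        mu, logv, z = theta
        v = np.exp(logv)
        r = np.tanh(z)
        return -_pair_loglik(g, mu, v, r * v)

    x0 = np.array([pairs.mean(), np.log(pairs.var() + 1e-12),
                   np.arctanh(np.clip(np.corrcoef(pairs.T)[0, 1], -0.95, 0.95))])
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 500})
    mu, logv, z = res.x
    H = hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
        se_z = np.sqrt(max(cov[2, 2], 0.0))
    except np.linalg.LinAlgError:
        se_z = np.nan
    r = np.tanh(z)
    se_r = se_z * (1 - r ** 2)  # delta method through tanh
    return float(r), float(se_r)


def twin_correlations(data, variable: str) -> TwinCorrelations:
    """ML cross-twin correlation per zygosity with equated means/variances.

    Estimated under a bivariate normal per zygosity; singletons are
    excluded. Standard errors come from the observed information (delta
    method through the Fisher-z parameterization).
    """
    prep = _prepare(data, variable)
    r_mz, se_mz = _fit_corr_group(prep["MZ"]["pairs"])
    r_dz, se_dz = _fit_corr_group(prep["DZ"]["pairs"])
    return TwinCorrelations(variable, r_mz, se_mz, r_dz, se_dz,
                            prep["MZ"]["n_pairs"], prep["DZ"]["n_pairs"])


# ---------------------------------------------------------------------------
# ACE fit

def _moment_start(prep) -> np.ndarray:
    vals = []
    for g in prep.values():
        vals.append(g["pairs"].ravel())
    allv = np.concatenate(vals)
    mu0, v0 = allv.mean(), allv.var() + 1e-12

    def corr(g):
        if g["n_pairs"] < 3:
            return 0.0
        return float(np.clip(np.corrcoef(g["pairs"].T)[0, 1], -0.9, 0.9))

    r_mz, r_dz = corr(prep["MZ"]), corr(prep["DZ"])
    a2 = np.clip(2 * (r_mz - r_dz), 0.0, 0.95)
    c2 = np.clip(2 * r_dz - r_mz, 0.0, 0.95 - a2)
    e2 = max(1.0 - a2 - c2, 0.05)
    return np.array([mu0, a2 * v0, c2 * v0, e2 * v0])


def _optimize_ace(prep, x0, fix_c: bool, parameterization: str, n_starts: int = 10,
                  seed: int = 0):
    rng = np.random.default_rng(seed)
    scale = max(x0[1] + x0[2] + x0[3], 1e-8)

    if parameterization == "variance":
        def unpack(theta):
            va, vc = theta[1], (0.0 if fix_c else theta[2])
            return theta[0], va, vc, theta[-1]
        n_par = 3 if fix_c else 4
        bounds = ([(None, None), (0.0, None), (1e-12, None)] if fix_c else
                  [(None, None), (0.0, None), (None, None), (1e-12, None)])

        def pack(x):
            return np.array([x[0], x[1], x[3]]) if fix_c else x
    elif parameterization == "cholesky":
        def unpack(theta):
            a, c = theta[1], (0.0 if fix_c else theta[2])
            return theta[0], a ** 2, c ** 2, theta[-1] ** 2
        n_par = 3 if fix_c else 4
        bounds = [(None, None)] * n_par

        def pack(x):
            s = np.sqrt(np.clip(x[1:], 1e-10, None))
            return (np.array([x[0], s[0], s[2]]) if fix_c
                    else np.array([x[0], s[0], s[1], s[2]]))
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")

    def nll(theta):
        mu, va, vc, ve = unpack(theta)
        if ve <= 0 or va < 0:  # only the C variance may go negative
            return _BIG
        ll = 0.0
        v = va + vc + ve
        for g in prep.values():
            ll += _pair_loglik(g, mu, v, g["rg"] * va + vc)
        return -ll

    best = None
    for k in range(n_starts):
        x = pack(x0).astype(float)
        if k:
            x = x + rng.normal(scale=0.1, size=n_par) * np.maximum(
                np.abs(x), 0.1 * scale)
            x[-1] = abs(x[-1]) + 1e-4 * scale
        res = optimize.minimize(nll, x, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-14, "gtol": 1e-9,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is not None and np.isfinite(best.fun):
        polish = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 4000})
        if polish.fun < best.fun:
            best = polish
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("ACE estimation failed",
                              {"best": None if best is None else best.fun})
    return best, unpack, nll


def fit_ace(data, variable: str, constrain_c_nonneg: bool = True,
            parameterization: str = "variance", seed: int = 0) -> ACEEstimate:
    """Univariate ACE decomposition by two-group FIML.

    ``constrain_c_nonneg`` reproduces the conventional workflow: the model
    is first fit with V_C unconstrained (negative values allowed); if the
    estimate is negative the model is refit with V_C = 0 and reported as
    AE-constrained. V_A is kept nonnegative in both parameterizations. ``parameterization`` selects direct variance estimation
    or the Cholesky-style standard-deviation-path reparameterization (same
    maximized likelihood; used as an internal cross-check).
    """
    prep = _prepare(data, variable)
    n_pairs = {z: prep[z]["n_pairs"] for z in ("MZ", "DZ")}
    n_singletons = prep["MZ"]["n_singles"] + prep["DZ"]["n_singles"]
    if sum(n_pairs.values()) < 10:
        raise EstimationError("need at least 10 twin pairs for an ACE model")

    x0 = _moment_start(prep)
    best, unpack, nll = _optimize_ace(prep, x0, fix_c=False,
                                      parameterization=parameterization,
                                      seed=seed)
    mu, va, vc, ve = unpack(best.x)
    status = "ACE"
    if vc < 0 and constrain_c_nonneg:
        best, unpack, nll = _optimize_ace(prep, x0, fix_c=True,
                                          parameterization=parameterization,
                                          seed=seed)
        mu, va, vc, ve = unpack(best.x)
        status = "AE-constrained"
    if ve <= 0:
        raise EstimationError("nonshared-environment variance collapsed to zero")

    # observed information on the (mu, V_A, V_C, V_E) scale
    def nll_var(theta):
        m, a, c, e = theta
        if e <= 0:
            return _BIG
        ll = 0.0
        for g in prep.values():
            ll += _pair_loglik(g, m, a + c + e, g["rg"] * a + c)
        return -ll

    point = np.array([mu, va, vc, ve])
    free = [0, 1, 3] if status == "AE-constrained" else [0, 1, 2, 3]

    def nll_free(th):
        full = point.copy()
        full[free] = th
        return nll_var(full)

    H = hessian(nll_free, point[free])
    try:
        cov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_free = np.full((len(free), len(free)), np.nan)
    cov = np.zeros((4, 4))
    for a, i in enumerate(free):
        for b, j in enumerate(free):
            cov[i, j] = cov_free[a, b]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    V = va + vc + ve
    shares = np.array([va, vc, ve]) / V
    # delta method: d(h_i)/d(V_j) = (delta_ij * V - V_i) / V^2
    J = (np.eye(3) * V - np.outer([va, vc, ve], np.ones(3))) / V ** 2
    cov_v = cov[1:, 1:]
    cov_h = J @ cov_v @ J.T
    se_h = np.sqrt(np.clip(np.diag(cov_h), 0.0, None))
    z = stats.norm.ppf(0.975)
    ci = {k: (float(shares[i] - z * se_h[i]), float(shares[i] + z * se_h[i]))
          for i, k in enumerate(("a2", "c2", "e2"))}

    if abs(shares.sum() - 1.0) > 1e-6:
        warnings.warn("standardized shares do not sum to 1", stacklevel=2)

    return ACEEstimate(
        variable=variable, mu=float(mu),
        variances={"V_A": float(va), "V_C": float(vc), "V_E": float(ve)},
        variance_se={"V_A": float(se[1]), "V_C": float(se[2]), "V_E": float(se[3])},
        standardized={"a2": float(shares[0]), "c2": float(shares[1]),
                      "e2": float(shares[2])},
        standardized_se={k: float(s) for k, s in zip(("a2", "c2", "e2"), se_h)},
        standardized_ci=ci,
        loglik=float(-best.fun), converged=bool(best.success or best.fun < _BIG),
        status=status, n_pairs=n_pairs, n_singletons=int(n_singletons),
        _ctx={"prep": prep, "parameterization": parameterization, "seed": seed},
    )


def loglik_profile_ci(fit: ACEEstimate, parameter: str, level: float = 0.95):
    """Profile-likelihood interval for one raw variance (or the mean).

    Profiles the chosen parameter against the chi-square(1) cutoff,
    re-optimizing the remaining parameters at each point. Returns
    ``(lo, hi, flags)``; a boundary flag marks a side truncated at the
    parameter's domain edge (e.g. V_C pinned at 0 in an AE fit).
    """
    prep = fit._ctx["prep"]
    names = ("mu", "V_A", "V_C", "V_E")
    idx = names.index(parameter)
    point = np.array([fit.mu, fit.variances["V_A"], fit.variances["V_C"],
                      fit.variances["V_E"]])
    cutoff = stats.chi2.ppf(level, 1) / 2.0
    ll_max = fit.loglik

    def profile_ll(value):
        def nll(th_free):
            full = np.empty(4)
            full[idx] = value
            full[[i for i in range(4) if i != idx]] = th_free
            if full[3] <= 0:
                return _BIG
            ll = 0.0
            for g in prep.values():
                ll += _pair_loglik(g, full[0], full[1] + full[2] + full[3],
                                   g["rg"] * full[1] + full[2])
            return -ll

        x0 = point[[i for i in range(4) if i != idx]]
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 4000})
        return -res.fun

    scale = max(fit.total_variance, 1e-6)
    flags = {"lower_boundary": False, "upper_boundary": False}

    def search(direction):
        lo_bound = 0.0 if parameter == "V_E" else -np.inf
        step = 0.1 * scale
        value = point[idx]
        prev = value
        for _ in range(60):
            cand = value + direction * step
            if parameter in ("V_A", "V_C", "V_E") and cand < 0 and \
                    fit.status == "AE-constrained" and parameter == "V_C":
                return 0.0, True
            if parameter == "V_E" and cand <= lo_bound:
                cand = lo_bound + 1e-10
            if ll_max - profile_ll(cand) >= cutoff:
                # bracket found: bisect between prev and cand
                a, b = prev, cand
                for _ in range(60):
                    mid = 0.5 * (a + b)
                    if ll_max - profile_ll(mid) >= cutoff:
                        b = mid
                    else:
                        a = mid
                    if abs(b - a) < 1e-6 * scale:
                        break
                return 0.5 * (a + b), False
            prev = cand
            value = cand
            step *= 1.6
        return value, True  # failed to bracket; report last point, flagged

    hi, fu = search(+1)
    if fit.status == "AE-constrained" and parameter == "V_C":
        lo, fl = 0.0, True
    else:
        lo, fl = search(-1)
    flags["lower_boundary"], flags["upper_boundary"] = fl, fu
    return float(lo), float(hi), flags


def falconer(r_mz: float, r_dz: float) -> dict:
    """Closed-form moment estimators from the two twin correlations."""
    return {"a2": 2.0 * (r_mz - r_dz), "c2": 2.0 * r_dz - r_mz, "e2": 1.0 - r_mz}
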