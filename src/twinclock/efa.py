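"""Maximum-likelihood exploratory factor analysis of the adjusted clocks.

Implements the classical Wishart-likelihood EFA (Lawley/Joreskog): for
fixed uniquenesses the profile loadings come from the eigenstructure of the
uniqueness-scaled correlation matrix, and the discrepancy

    F = sum_{k>m} (lambda_k - log lambda_k - 1)

is minimized over log-uniquenesses by quasi-Newton. Oblique geomin rotation
uses gradient projection with random starts. Missing clock rows are handled
either listwise or by full-information ML in two stages: an EM fit of the
saturated multivariate-normal mean/covariance, then Wishart ML on the
implied correlation matrix.

Model fit is summarized by chi-square against the saturated model,
df = ((p - m)^2 - (p + m)) / 2, and RMSEA with noncentral-chi-square
confidence limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cohort import CLOCKS, GEN1_CLOCKS
from .errors import DegenerateDataError, EstimationError

_PSI_FLOOR = 1e-4


@dataclass
class FactorSolution:
    """ML EFA solution on the correlation metric."""

    n_factors: int
    loadings: np.ndarray            # p x m, geomin-rotated for m >= 2
    factor_corr: np.ndarray         # m x m
    uniquenesses: np.ndarray        # p
    loglik: float                   # Wishart loglik, constants shared across m
    chi2: float
    df: int
    rmsea: float
    rmsea_ci: tuple                 # (lo, hi) at ci_level
    rmsea_ci_90: tuple
    ci_level: float
    eigenvalues: np.ndarray         # of the input correlation matrix
    rotation_criterion: float | None
    n_obs: int
    heywood: bool
    unrotated_loadings: np.ndarray = field(repr=False, default=None)
    variable_names: tuple = tuple(CLOCKS)

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    def implied_correlation(self) -> np.ndarray:
        lam, phi = self.loadings, self.factor_corr
        sigma = lam @ phi @ lam.T
        np.fill_diagonal(sigma, 1.0)
        return sigma


def model_df(p: int, m: int) -> int:
    """Residual degrees of freedom of an m-factor model on p indicators."""
    return ((p - m) ** 2 - (p + m)) // 2


def _profile_loadings(R: np.ndarray, psi: np.ndarray, m: int):
    """Optimal loadings and discrepancy for fixed uniquenesses."""
    p = R.shape[0]
    sp = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(sp, sp)
    vals, vecs = np.linalg.eigh(Rs)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    top = np.clip(vals[:m] - 1.0, 0.0, None)
    lam = np.sqrt(psi)[:, None] * vecs[:, :m] * np.sqrt(top)
    tail = np.clip(vals[m:], 1e-12, None)
    F = float(np.sum(tail - np.log(tail) - 1.0))
    return lam, F


def _fit_ml(R: np.ndarray, m: int):
    p = R.shape[0]

    def objective(logpsi):
        psi = np.exp(logpsi)
        return _profile_loadings(R, psi, m)[1]

    start_h2 = np.clip(1.0 - 1.0 / np.diag(np.linalg.inv(R)), 0.05, 0.95)
    best = None
    for jitter in (0.0, 0.3, -0.3):
        x0 = np.log(np.clip(1.0 - start_h2 + jitter * 0.1, _PSI_FLOOR, 1.0))
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(np.log(_PSI_FLOOR), np.log(1.0))] * p,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("EFA did not converge",
                              {"criterion": None if best is None else best.fun})
    psi = np.exp(best.x)
    lam, F = _profile_loadings(R, psi, m)
    heywood = bool(np.any(psi <= _PSI_FLOOR * (1 + 1e-6)))
    if heywood:
        warnings.warn("Heywood case: uniqueness bounded at 1e-4", stacklevel=2)
    return lam, psi, F, heywood


def _geomin_criterion(L: np.ndarray, eps: float):
    L2 = L ** 2 + eps
    pro = np.exp(np.log(L2).sum(axis=1) / L.shape[1])
    Q = pro.sum()
    Gq = (2.0 / L.shape[1]) * (L / L2) * pro[:, None]
    return Q, Gq


def geomin_rotate(A: np.ndarray, eps: float = 0.01, n_starts: int = 30,
                  max_iter: int = 1000, tol: float = 1e-8, seed: int = 0):
    """Oblique geomin rotation by gradient projection (GPFoblq).

    Rotates the unrotated loadings ``A`` over oblique transformations,
    keeping the best criterion across ``n_starts`` random starts (the first
    start is the identity). Returns ``(loadings, factor_corr, criterion)``.
    """
    p, m = A.shape
    if m == 1:
        return A.copy(), np.ones((1, 1)), None
    rng = np.random.default_rng(seed)

    def gpf(T0):
        T = T0.copy()
        al = 1.0
        Ti = np.linalg.inv(T)
        L = A @ Ti.T
        Q, Gq = _geomin_criterion(L, eps)
        G = -(L.T @ Gq @ Ti).T
        for _ in range(max_iter):
            Gp = G - T * (T * G).sum(axis=0, keepdims=True)
            s = np.sqrt((Gp ** 2).sum())
            if s < tol:
                break
            al *= 2.0
            for _ in range(60):
                X = T - al * Gp
                X /= np.sqrt((X ** 2).sum(axis=0, keepdims=True))
                try:
                    Xi = np.linalg.inv(X)
                except np.linalg.LinAlgError:
                    al /= 2.0
                    continue
                Lx = A @ Xi.T
                Qx, Gqx = _geomin_criterion(Lx, eps)
                if Qx < Q - 0.5 * s ** 2 * al:
                    T, L, Q = X, Lx, Qx
                    G = -(L.T @ Gqx @ Xi).T
                    break
                al /= 2.0
            else:
                break
        return L, T, Q

    best = None
    for k in range(max(1, n_starts)):
        T0 = np.eye(m) if k == 0 else rng.standard_normal((m, m))
        T0 = T0 / np.sqrt((T0 ** 2).sum(axis=0, keepdims=True))
        try:
            L, T, Q = gpf(T0)
        except np.linalg.LinAlgError:
            continue
        if best is None or Q < best[2]:
            best = (L, T, Q)
    if best is None:
        raise EstimationError("geomin rotation failed for all starts")
    L, T, Q = best
    phi = T.T @ T
    # deterministic orientation: dominant loading of each factor positive
    for j in range(m):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1
            phi[j] *= -1
            phi[:, j] *= -1
    return L, phi, float(Q)


def em_mvn(X: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """EM estimate of a saturated MVN mean/covariance with missing entries."""
    X = np.asarray(X, dtype=float)
    X = X[np.isfinite(X).any(axis=1)]
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    filled = np.where(np.isfinite(X), X, mu)
    S = np.cov(filled, rowvar=False, ddof=0) + 1e-6 * np.eye(p)
    patterns = {}
    finite = np.isfinite(X)
    for i in range(n):
        patterns.setdefault(tuple(finite[i]), []).append(i)
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for pat, idx in patterns.items():
            obs = np.array(pat)
            rows = X[idx]
            if obs.all():
                sum_x += rows.sum(axis=0)
                sum_xx += rows.T @ rows
                continue
            o, mis = np.where(obs)[0], np.where(~obs)[0]
            Soo = S[np.ix_(o, o)]
            B = np.linalg.solve(Soo, S[np.ix_(o, mis)])
            cond_cov = S[np.ix_(mis, mis)] - S[np.ix_(mis, o)] @ B
            xo = rows[:, o]
            xm = mu[mis] + (xo - mu[o]) @ B
            full = np.empty((len(idx), p))
            full[:, o], full[:, mis] = xo, xm
            sum_x += full.sum(axis=0)
            xx = full.T @ full
            xx[np.ix_(mis, mis)] += len(idx) * cond_cov
            sum_xx += xx
        mu_new = sum_x / n
        S_new = sum_xx / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(S_new - S).max())
        mu, S = mu_new, S_new
        if delta < tol:
            break
    return mu, S, n


def rmsea(chi2: float, df: int, n: int, ci_level: float = 0.95):
    """RMSEA point estimate and noncentral-chi-square confidence limits."""
    if df <= 0:
        warnings.warn("df = 0: RMSEA undefined", stacklevel=2)
        return {"point": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}
    scale = df * (n - 1)
    point = float(np.sqrt(max(0.0, (chi2 - df) / scale)))
    alpha = 1.0 - ci_level

    def bound(target):
        # noncentrality lambda with cdf(chi2; df, lambda) = target
        if stats.chi2.cdf(chi2, df) < target:
            return 0.0
        hi = max(chi2 * 2, df * 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > target and hi < 1e8:
            hi *= 2
        return optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - target, 0.0, hi)

    lo = np.sqrt(bound(1.0 - alpha / 2) / scale)
    hi = np.sqrt(bound(alpha / 2) / scale)
    return {"point": point, "ci_lo": float(lo), "ci_hi": float(hi)}


def fit_efa(clock_matrix, m: int, missing: str = "fiml", rotate: bool = True,
            geomin_eps: float = 0.01, n_starts: int = 30, ci_level: float = 0.95,
            rotation_seed: int = 0, variable_names=tuple(CLOCKS)) -> FactorSolution:
    """Fit an m-factor ML EFA to an n x p matrix of adjusted clock values.

    ``missing='fiml'`` (default) estimates the input correlation matrix by
    EM over partially observed rows; ``'listwise'`` drops incomplete rows.
    The unrotated solution is ordered by sum-of-squared loadings and geomin-
    rotated when ``m >= 2`` and ``rotate`` is set.
    """
    X = np.asarray(clock_matrix, dtype=float)
    p = X.shape[1]
    if m < 1 or m > p:
        raise ValueError(f"factor count m={m} invalid for p={p}")
    if missing == "listwise":
        Xc = X[np.isfinite(X).all(axis=1)]
        n = Xc.shape[0]
        S = np.cov(Xc, rowvar=False, ddof=1)
    elif missing == "fiml":
        _, S, n = em_mvn(X)
    else:
        raise ValueError(f"unknown missing-data mode {missing!r}")
    if n <= 20:
        raise DegenerateDataError(f"EFA needs n > 20 usable rows, got {n}")
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise DegenerateDataError("zero-variance clock column")
    R = S / np.outer(d, d)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]

    lam, psi, F, heywood = _fit_ml(R, m)

    # canonical order by explained variance, dominant sign positive
    ss = (lam ** 2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    lam = lam[:, order]
    for j in range(m):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            lam[:, j] *= -1

    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise DegenerateDataError("input correlation matrix is singular")
    sigma = lam @ lam.T + np.diag(psi)
    _, logdet_sig = np.linalg.slogdet(sigma)
    tr = float(np.trace(np.linalg.solve(sigma, R)))
    loglik = -0.5 * (n - 1) * (logdet_sig + tr)
    chi2 = (n - 1) * F
    df = model_df(p, m)

    if rotate and m >= 2:
        L, phi, Q = geomin_rotate(lam, eps=geomin_eps, n_starts=n_starts,
                                  seed=rotation_seed)
        # canonical column order after rotation as well
        order2 = np.argsort((L ** 2).sum(axis=0))[::-1]
        L = L[:, order2]
        phi = phi[np.ix_(order2, order2)]
    else:
        L, phi, Q = lam.copy(), np.eye(m), None

    fit = rmsea(chi2, df, n, ci_level=ci_level) if df > 0 else {
        "point": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}
    fit90 = rmsea(chi2, df, n, ci_level=0.90) if df > 0 else fit

    return FactorSolution(
        n_factors=m, loadings=L, factor_corr=phi, uniquenesses=psi,
        loglik=float(loglik), chi2=float(chi2), df=df,
        rmsea=fit["point"], rmsea_ci=(fit["ci_lo"], fit["ci_hi"]),
        rmsea_ci_90=(fit90["ci_lo"], fit90["ci_hi"]), ci_level=ci_level,
        eigenvalues=eigenvalues, rotation_criterion=Q, n_obs=n,
        heywood=heywood, unrotated_loadings=lam,
        variable_names=tuple(variable_names),
    )


def lrt_factors(sol1: FactorSolution, sol2: FactorSolution) -> dict:
    """Likelihood-ratio test of a smaller against a larger factor model."""
    if sol2.n_factors <= sol1.n_factors:
        raise ValueError("sol2 must have more factors than sol1")
    if sol1.n_obs != sol2.n_obs:
        raise ValueError("solutions were not fit to the same data")
    chi2_diff = max(0.0, -2.0 * (sol1.loglik - sol2.loglik))
    df_diff = sol1.df - sol2.df
    if df_diff > 0:
        p = float(stats.chi2.sf(chi2_diff, df_diff))
    else:
        p = 1.0 if chi2_diff < 1e-10 else np.nan
    return {"chi2_diff": float(chi2_diff), "df_diff": int(df_diff), "p": p}


def assign_generations(solution: FactorSolution) -> dict:
    """Label the factor loading most on the chronological-age clocks Gen 1.

    Returns ``{'gen1': j1, 'gen2': j2}`` column indices. For m = 1 both
    labels point at the single factor.
    """
    names = list(solution.variable_names)
    idx = [names.index(c) for c in GEN1_CLOCKS if c in names]
    if solution.n_factors == 1:
        return {"gen1": 0, "gen2": 0}
    sums = np.abs(solution.loadings[idx]).sum(axis=0)
    j1 = int(np.argmax(sums))
    rest = [j for j in range(solution.n_factors) if j != j1]
    return {"gen1": j1, "gen2": int(rest[0])}


def clock_groups_from_loadings(solution: FactorSolution,
                               threshold: float = 0.3) -> dict:
    """Data-driven sensitivity grouping: clocks with |loading| >= threshold."""
    gens = assign_generations(solution)
    out = {}
    for label, j in gens.items():
        out[label] = tuple(
            name for i, name in enumerate(solution.variable_names)
            if abs(solution.loadings[i, j]) >= threshold
        )
    return out
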