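"""Phenotypic-association and quasi-causal co-twin regression models.

Both models are fit by full-information maximum likelihood over MZ/DZ
groups on the wide-by-pair data, with coefficients equated across twin
slots and singleton families contributing the likelihood of whatever they
observed. The observed vector per family is (X1, M1, Y1, X2, M2, Y2):
childhood IQ, the DNAm-age variable and adult IQ for each twin slot, with
family-level centered SES ``s`` as an exogenous regressor.

Quasi-causal model: the full structural model of :mod:`twinclock.params`.
Each phenotype carries latent A/C/E components (unit paths, estimated
variances; A correlated 1.0 / 0.5 across MZ / DZ co-twins, C shared),
and the predictor's A and C components regress on downstream phenotypes
(b_a*, b_c*), so the phenotypic coefficients b_p1/b_p2/b_p3 are purged of
family-level genetic and shared-environmental confounding. The SES x
DNAmAge interaction is a per-family definition variable: the M -> Y slope
is b_p3 + b_int * s, entering both the mean and the implied covariance of
that family.

Phenotypic-association model: the same regression system with no latent
A/C structure; within-pair residual covariance per phenotype is carried by
the shared component (pooled across zygosity by default), making the model
an exact submodel of the quasi-causal one.

The implied per-family moments are assembled from the structural factor
matrix T(q) = T0 + q*T1 mapping the 15 latent components to the 6 observed
slots, so Sigma(q) = A0 + q*A1 + q^2*A2 with A_k built from T0, T1 and the
latent covariance. T0, T1 and the latent covariance are affine in the
canonical parameters, which yields exact analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._numdiff import jacobian_of_grad
from .cohort import TwinCohort
from .errors import EstimationError
from .params import PARAM_NAMES, StructuralParams

_NP = len(PARAM_NAMES)
_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}
_BIG = 1e10

_OBS = ("x1", "m1", "y1", "x2", "m2", "y2")


# ---------------------------------------------------------------------------
# structural matrices (affine in the canonical parameter vector)

def _structure(p: np.ndarray):
    """T0, T1 (6 x 15) for canonical parameters ``p``; T(q) = T0 + q*T1."""
    g = dict(zip(PARAM_NAMES, p))
    T0 = np.zeros((6, 15))
    T1 = np.zeros((6, 15))
    for j in (0, 1):
        ax, ex = 0 + j, 3 + j
        am, em = 5 + j, 8 + j
        ay, ey = 10 + j, 13 + j
        cx, cm, cy = 2, 7, 12
        rx, rm, ry = 3 * j, 3 * j + 1, 3 * j + 2
        T0[rx, [ax, cx, ex]] = 1.0
        T0[rm, ax] = g["b_p2"] + g["b_a2"]
        T0[rm, cx] = g["b_p2"] + g["b_c2"]
        T0[rm, ex] = g["b_p2"]
        T0[rm, [am, cm, em]] = 1.0
        T0[ry, ax] = g["b_p1"] + g["b_a1"]
        T0[ry, cx] = g["b_p1"] + g["b_c1"]
        T0[ry, ex] = g["b_p1"]
        T0[ry, am] = g["b_a3"]
        T0[ry, cm] = g["b_c3"]
        T0[ry, [ay, cy, ey]] = 1.0
        T1[ry] = T0[rm]
    return T0, T1


def _latent_cov(p: np.ndarray, rg: float) -> np.ndarray:
    g = dict(zip(PARAM_NAMES, p))
    Phi = np.zeros((15, 15))
    for base, (va, vc, ve) in zip(
            (0, 5, 10),
            ((g["va_x"], g["vc_x"], g["ve_x"]),
             (g["va_m"], g["vc_m"], g["ve_m"]),
             (g["va_y"], g["vc_y"], g["ve_y"]))):
        a1, a2, c, e1, e2 = base, base + 1, base + 2, base + 3, base + 4
        Phi[a1, a1] = Phi[a2, a2] = va
        Phi[a1, a2] = Phi[a2, a1] = rg * va
        Phi[c, c] = vc
        Phi[e1, e1] = Phi[e2, e2] = ve
    return Phi


def _derivative_tables():
    """Constant dT0/dtheta, dT1/dtheta, dPhi/dtheta (affine structure)."""
    zero = np.zeros(_NP)
    T0_0, T1_0 = _structure(zero)
    phi0 = {rg: _latent_cov(zero, rg) for rg in (1.0, 0.5)}
    dT0, dT1, dPhi = [], [], []
    for j in range(_NP):
        e = zero.copy()
        e[j] = 1.0
        t0, t1 = _structure(e)
        dT0.append(t0 - T0_0)
        dT1.append(t1 - T1_0)
        dPhi.append({rg: _latent_cov(e, rg) - phi0[rg] for rg in (1.0, 0.5)})
    return dT0, dT1, dPhi


_DT0, _DT1, _DPHI = _derivative_tables()
_HAS_COV_DERIV = [
    bool(_DT0[j].any() or _DT1[j].any() or _DPHI[j][1.0].any())
    for j in range(_NP)
]

# canonical indices whose mean derivative is nonzero
_MEAN_PARAMS = {"mu_x", "mu_m", "mu_y", "b_sx", "b_sm", "b_sy",
                "b_p1", "b_p2", "b_p3", "b_int"}


def _means(p: np.ndarray, s: np.ndarray):
    g = dict(zip(PARAM_NAMES, p))
    mx = g["mu_x"] + g["b_sx"] * s
    mm = g["mu_m"] + g["b_sm"] * s + g["b_p2"] * mx
    q = g["b_p3"] + g["b_int"] * s
    my = g["mu_y"] + g["b_sy"] * s + g["b_p1"] * mx + q * mm
    return mx, mm, my, q


def _mean_derivs(p: np.ndarray, s: np.ndarray, mx, mm, q):
    """d(mu_X, mu_M, mu_Y)/dtheta for the mean-active parameters."""
    g = dict(zip(PARAM_NAMES, p))
    one = np.ones_like(s)
    zero = np.zeros_like(s)
    out = {
        "mu_x": (one, g["b_p2"] * one, (g["b_p1"] + q * g["b_p2"])),
        "mu_m": (zero, one, q),
        "mu_y": (zero, zero, one),
        "b_sx": (s, g["b_p2"] * s, (g["b_p1"] + q * g["b_p2"]) * s),
        "b_sm": (zero, s, q * s),
        "b_sy": (zero, zero, s),
        "b_p1": (zero, zero, mx),
        "b_p2": (zero, mx, q * mx),
        "b_p3": (zero, zero, mm),
        "b_int": (zero, zero, s * mm),
    }
    return out


# ---------------------------------------------------------------------------
# data grouping

@dataclass
class _Group:
    rg: float
    obs_idx: np.ndarray   # observed slot indices within (x1,m1,y1,x2,m2,y2)
    data: np.ndarray      # k x len(obs_idx)
    s: np.ndarray         # centered SES, k


def _build_groups(wide: pd.DataFrame, dnam_variable: str, ses_center: float,
                  scales: dict) -> list[_Group]:
    cols = [("child_iq_1", "x"), (f"{dnam_variable}_1", "m"), ("adult_iq_1", "y"),
            ("child_iq_2", "x"), (f"{dnam_variable}_2", "m"), ("adult_iq_2", "y")]
    missing = [c for c, _ in cols if c not in wide.columns]
    if missing:
        raise EstimationError(f"columns absent from cohort table: {missing}")
    mat = wide[[c for c, _ in cols]].to_numpy(float)
    vscale = np.array([scales[v] for _, v in cols])
    mat = mat / vscale
    s = (wide["ses"].to_numpy(float) - ses_center) / scales["s"]
    finite = np.isfinite(mat)
    groups = []
    for zyg, rg in (("MZ", 1.0), ("DZ", 0.5)):
        in_z = (wide["zygosity"] == zyg).to_numpy()
        pats = {}
        for i in np.where(in_z)[0]:
            key = tuple(finite[i])
            pats.setdefault(key, []).append(i)
        for key, idx in pats.items():
            obs = np.where(key)[0]
            if len(obs) == 0:
                continue
            groups.append(_Group(rg=rg, obs_idx=obs,
                                 data=mat[np.ix_(idx, obs)],
                                 s=s[idx]))
    return groups


# ---------------------------------------------------------------------------
# likelihood and gradient

def _nll_and_grad(theta: np.ndarray, groups: list[_Group],
                  fixed: np.ndarray, gmaps: list[np.ndarray],
                  want_grad: bool = True):
    nll = 0.0
    grad = np.zeros_like(theta)
    for g, gmap in zip(groups, gmaps):
        p = fixed.copy()
        sel = gmap >= 0
        p[sel] = theta[gmap[sel]]
        T0, T1 = _structure(p)
        Phi = _latent_cov(p, g.rg)
        PT0, PT1 = Phi @ T0.T, Phi @ T1.T
        A0 = T0 @ PT0
        A1 = T0 @ PT1 + T1 @ PT0
        A2 = T1 @ PT1
        o = g.obs_idx
        A0s, A1s, A2s = (A[np.ix_(o, o)] for A in (A0, A1, A2))
        mx, mm, my, q = _means(p, g.s)
        mean6 = np.stack([mx, mm, my, mx, mm, my], axis=1)
        r = g.data - mean6[:, o]
        sig = (A0s[None] + q[:, None, None] * A1s[None]
               + (q ** 2)[:, None, None] * A2s[None])
        try:
            chol = np.linalg.cholesky(sig)
        except np.linalg.LinAlgError:
            return _BIG, np.zeros_like(theta)
        k, d = r.shape
        logdet = 2.0 * np.log(np.einsum("nii->ni", chol)).sum()
        W = np.linalg.inv(sig)
        alpha = np.einsum("nij,nj->ni", W, r)
        quad = np.einsum("ni,ni->", r, alpha)
        nll += 0.5 * (k * d * np.log(2 * np.pi) + logdet + quad)
        if not want_grad:
            continue

        B = W - np.einsum("ni,nj->nij", alpha, alpha)
        B0 = B.sum(axis=0)
        B1 = np.einsum("n,nij->ij", q, B)
        B2 = np.einsum("n,nij->ij", q ** 2, B)
        BS = np.einsum("n,nij->ij", g.s, B)
        BSq = np.einsum("n,nij->ij", g.s * q, B)
        mder = _mean_derivs(p, g.s, mx, mm, q)

        for j in range(_NP):
            tj = gmap[j]
            if tj < 0:
                continue
            val = 0.0
            if _HAS_COV_DERIV[j]:
                dT0, dT1, dP = _DT0[j], _DT1[j], _DPHI[j][g.rg]
                dPT0 = dP @ T0.T
                dPT1 = dP @ T1.T
                dA0 = dT0 @ PT0 + T0 @ dPT0 + (T0 @ (Phi @ dT0.T))
                dA1 = (dT0 @ PT1 + T0 @ dPT1 + T0 @ (Phi @ dT1.T)
                       + dT1 @ PT0 + T1 @ dPT0 + T1 @ (Phi @ dT0.T))
                dA2 = dT1 @ PT1 + T1 @ dPT1 + T1 @ (Phi @ dT1.T)
                val += 0.5 * (np.sum(B0 * dA0[np.ix_(o, o)])
                              + np.sum(B1 * dA1[np.ix_(o, o)])
                              + np.sum(B2 * dA2[np.ix_(o, o)]))
            name = PARAM_NAMES[j]
            if name == "b_p3":
                val += 0.5 * (np.sum(B0 * A1s) + 2.0 * np.sum(B1 * A2s))
            elif name == "b_int":
                val += 0.5 * (np.sum(BS * A1s) + 2.0 * np.sum(BSq * A2s))
            if name in _MEAN_PARAMS:
                dmx, dmm, dmy = mder[name]
                dmean6 = np.stack([dmx, dmm, dmy, dmx, dmm, dmy], axis=1)
                val -= np.einsum("ni,ni->", dmean6[:, o], alpha)
            grad[tj] += val
    return nll, grad


def family_loglik(params: StructuralParams, wide: pd.DataFrame,
                  dnam_variable: str, ses_center: float | None = None) -> float:
    """Log-likelihood of the structural model at a given parameter point.

    Evaluated on the natural data scale with no internal standardization;
    exposed for cross-checks against direct per-family multivariate-normal
    densities.
    """
    if ses_center is None:
        ses_center = float(wide["ses"].mean())
    scales = {"x": 1.0, "m": 1.0, "y": 1.0, "s": 1.0}
    groups = _build_groups(wide, dnam_variable, ses_center, scales)
    gmaps = [np.arange(_NP) for _ in groups]
    nll, _ = _nll_and_grad(params.to_array(), groups,
                           np.zeros(_NP), gmaps, want_grad=False)
    return -float(nll)


# ---------------------------------------------------------------------------
# public fit results

@dataclass
class PathModelFit:
    """Fitted path model: coefficients, Wald SEs, and fit metadata."""

    model: str                      # "phenotypic" | "quasi-causal"
    dnam_variable: str
    params: StructuralParams
    se: dict
    pvalues: dict
    loglik: float
    converged: bool
    n_families: int
    n_pairs: dict
    n_singletons: int
    ses_center: float
    ses_sd: float
    constraints: dict               # phenotype -> True if V_C fixed at 0
    free_names: tuple
    cov: pd.DataFrame = field(repr=False, default=None)
    zygosity_specific_residuals: bool = False

    def coef(self, name: str) -> float:
        return getattr(self.params, name)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name in PARAM_NAMES:
            rows.append({
                "parameter": name,
                "estimate": getattr(self.params, name),
                "se": self.se.get(name, np.nan),
                "p": self.pvalues.get(name, np.nan),
                "free": name in self.free_names,
            })
        return pd.DataFrame(rows)


@dataclass
class ModeratedEffect:
    """Simple slopes of the DNAmAge -> adult-IQ effect at SES levels."""

    split: str
    levels: dict          # label -> SES value (original units)
    slopes: dict          # label -> slope
    slope_se: dict
    interaction: float
    interaction_se: float


# ---------------------------------------------------------------------------
# fitting

_SCALE_FACTOR = {
    # canonical parameter -> exponents of (sx, sm, sy, ss) mapping the
    # standardized-scale estimate back to the native scale
    "mu_x": (1, 0, 0, 0), "mu_m": (0, 1, 0, 0), "mu_y": (0, 0, 1, 0),
    "b_sx": (1, 0, 0, -1), "b_sm": (0, 1, 0, -1), "b_sy": (0, 0, 1, -1),
    "b_p1": (-1, 0, 1, 0), "b_p2": (-1, 1, 0, 0), "b_p3": (0, -1, 1, 0),
    "b_int": (0, -1, 1, -1),
    "b_a1": (-1, 0, 1, 0), "b_c1": (-1, 0, 1, 0),
    "b_a2": (-1, 1, 0, 0), "b_c2": (-1, 1, 0, 0),
    "b_a3": (0, -1, 1, 0), "b_c3": (0, -1, 1, 0),
    "va_x": (2, 0, 0, 0), "vc_x": (2, 0, 0, 0), "ve_x": (2, 0, 0, 0),
    "va_m": (0, 2, 0, 0), "vc_m": (0, 2, 0, 0), "ve_m": (0, 2, 0, 0),
    "va_y": (0, 0, 2, 0), "vc_y": (0, 0, 2, 0), "ve_y": (0, 0, 2, 0),
}


def _native_factor(name: str, sx, sm, sy, ss) -> float:
    ex = _SCALE_FACTOR[name]
    return sx ** ex[0] * sm ** ex[1] * sy ** ex[2] * ss ** ex[3]


def _start_values(wide: pd.DataFrame, dnam_variable: str, ses_center: float,
                  scales: dict, quasi: bool) -> StructuralParams:
    """Moment / OLS starting values on the standardized scale."""
    rows = []
    for slot in (1, 2):
        sub = pd.DataFrame({
            "x": wide[f"child_iq_{slot}"] / scales["x"],
            "m": wide[f"{dnam_variable}_{slot}"] / scales["m"],
            "y": wide[f"adult_iq_{slot}"] / scales["y"],
            "s": (wide["ses"] - ses_center) / scales["s"],
        })
        rows.append(sub)
    d = pd.concat(rows, ignore_index=True)

    def ols(y, X):
        sub = pd.concat([y, X], axis=1).dropna()
        yy = sub.iloc[:, 0].to_numpy()
        XX = np.column_stack([np.ones(len(sub)), sub.iloc[:, 1:].to_numpy()])
        beta, *_ = np.linalg.lstsq(XX, yy, rcond=None)
        resid_var = np.var(yy - XX @ beta)
        return beta, resid_var

    bx, vx = ols(d["x"], d[["s"]])
    bm, vm = ols(d["m"], d[["x", "s"]])
    dd = d.assign(sm=d["s"] * d["m"])
    by, vy = ols(d["y"], dd[["x", "m", "s", "sm"]])
    p = StructuralParams(
        mu_x=bx[0], b_sx=bx[1],
        mu_m=bm[0], b_p2=bm[1], b_sm=bm[2],
        mu_y=by[0], b_p1=by[1], b_p3=by[2], b_sy=by[3], b_int=by[4],
    )
    if quasi:
        for ph, v in (("x", vx), ("m", vm), ("y", vy)):
            setattr(p, f"va_{ph}", 0.5 * v)
            setattr(p, f"vc_{ph}", 0.1 * v)
            setattr(p, f"ve_{ph}", 0.4 * v)
    else:
        for ph, v in (("x", vx), ("m", vm), ("y", vy)):
            setattr(p, f"va_{ph}", 0.0)
            setattr(p, f"vc_{ph}", 0.2 * v)
            setattr(p, f"ve_{ph}", 0.8 * v)
    return p


def _fit_engine(groups, fixed, gmaps, theta0, bounds, n_starts=3, seed=0):
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        x0 = theta0.copy()
        if k:
            x0 = x0 + rng.normal(scale=0.05, size=len(x0)) * np.maximum(
                np.abs(x0), 0.2)
            x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in bounds],
                         [b[1] if b[1] is not None else np.inf for b in bounds])
        res = optimize.minimize(
            _nll_and_grad, x0, args=(groups, fixed, gmaps), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 3000, "maxfun": 10000, "maxcor": 40,
                     "ftol": 1e-13, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < _BIG and best.success:
            break
    if best is None or best.fun >= _BIG:
        raise EstimationError(
            "path-model estimation failed to find a feasible optimum",
            {"criterion": None if best is None else float(best.fun)})
    return best


def _fit_path_model(data, dnam_variable: str, quasi: bool,
                    constrain_c: str = "auto",
                    zygosity_specific_residuals: bool = False,
                    seed: int = 0) -> PathModelFit:
    wide = data.data if isinstance(data, TwinCohort) else data

    # analysis scales and centering
    def col(v, slot):
        name = {"x": "child_iq", "m": dnam_variable, "y": "adult_iq"}[v]
        return wide[f"{name}_{slot}"]

    pooled = {v: pd.concat([col(v, 1), col(v, 2)]).dropna() for v in "xmy"}
    for v, series in pooled.items():
        if series.std() == 0 or len(series) < 10:
            raise EstimationError(f"variable '{v}' lacks usable variation")
    ses = wide["ses"].astype(float)
    ses_center = float(ses.mean())
    ses_sd = float(ses.std(ddof=1)) or 1.0
    scales = {v: float(pooled[v].std(ddof=1)) for v in "xmy"}
    scales["s"] = ses_sd

    groups = _build_groups(wide, dnam_variable, ses_center, scales)
    n_pairs = {z: int(((wide["zygosity"] == z)
                       & wide[f"adult_iq_1"].notna()
                       & wide[f"adult_iq_2"].notna()).sum())
               for z in ("MZ", "DZ")}

    start = _start_values(wide, dnam_variable, ses_center, scales, quasi)

    def assemble(constrained: set[str]):
        """Free-parameter list, fixed base, per-group maps and bounds."""
        fixed = np.zeros(_NP)
        free: list[str] = []
        if quasi:
            for name in PARAM_NAMES:
                ph = name[-1]
                if name.startswith("vc_") and ph in constrained:
                    continue
                if name == "b_c3" and "m" in constrained:
                    continue
                if name in ("b_c1", "b_c2") and "x" in constrained:
                    continue
                free.append(name)
        else:
            for name in PARAM_NAMES:
                if name.startswith(("b_a", "b_c")) or name.startswith("va_"):
                    continue
                if name.startswith("vc_") and name[-1] in constrained:
                    continue
                free.append(name)
        dup = []
        if zygosity_specific_residuals and not quasi:
            dup = [n for n in free if n.startswith("vc_")]
        theta_names = free + [f"{n}__dz" for n in dup]
        gmaps = []
        for g in groups:
            gmap = np.full(_NP, -1, dtype=int)
            for t, n in enumerate(free):
                gmap[_IDX[n]] = t
            if g.rg == 0.5:
                for n in dup:
                    gmap[_IDX[n]] = theta_names.index(f"{n}__dz")
            gmaps.append(gmap)
        theta0 = np.empty(len(theta_names))
        sarr = start.to_array()
        for t, n in enumerate(theta_names):
            theta0[t] = sarr[_IDX[n.removesuffix("__dz")]]
        bounds = []
        for n in theta_names:
            base = n.removesuffix("__dz")
            if base.startswith("ve_"):
                bounds.append((1e-8, None))
            elif base.startswith("va_") and quasi:
                bounds.append((0.0, None))
            else:
                bounds.append((None, None))
        return theta_names, fixed, gmaps, theta0, bounds

    constrained: set[str] = set()
    if constrain_c == "always":
        constrained = {"x", "m", "y"}
    elif not isinstance(constrain_c, str):
        constrained = set(constrain_c)
        constrain_c = "explicit"
    warm: dict[str, float] = {}
    for _ in range(4):
        theta_names, fixed, gmaps, theta0, bounds = assemble(constrained)
        for t, n in enumerate(theta_names):
            if n in warm:
                theta0[t] = warm[n]
        res = _fit_engine(groups, fixed, gmaps, theta0, bounds, seed=seed)
        warm = {n: float(v) for n, v in zip(theta_names, res.x)
                if not (n.startswith("vc_") and v < 0)}
        if constrain_c != "auto":
            break
        neg = {n[-1] for n, v in zip(theta_names, res.x)
               if n.startswith("vc_") and not n.endswith("__dz") and v < 0}
        neg |= {n[3] for n, v in zip(theta_names, res.x)
                if n.startswith("vc_") and n.endswith("__dz") and v < 0}
        if quasi and neg - constrained:
            constrained |= neg
            continue
        break

    # scaled -> native parameters
    p_scaled = fixed.copy()
    for t, n in enumerate(theta_names):
        j = _IDX[n.removesuffix("__dz")]
        if not n.endswith("__dz"):
            p_scaled[j] = res.x[t]
    sx, sm, sy, ss = scales["x"], scales["m"], scales["y"], scales["s"]
    p_native = np.array([
        p_scaled[j] * _native_factor(PARAM_NAMES[j], sx, sm, sy, ss)
        for j in range(_NP)
    ])

    # observed information on the scaled metric, mapped by the diagonal
    # native-scale transformation
    def grad_only(th):
        return _nll_and_grad(th, groups, fixed, gmaps)[1]

    H = jacobian_of_grad(grad_only, res.x)
    try:
        cov_scaled = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_scaled = np.full((len(res.x), len(res.x)), np.nan)
    factors = np.array([
        _native_factor(n.removesuffix("__dz"), sx, sm, sy, ss)
        for n in theta_names
    ])
    cov_native = cov_scaled * np.outer(factors, factors)
    cov_df = pd.DataFrame(cov_native, index=theta_names, columns=theta_names)

    se = {}
    pvals = {}
    for t, n in enumerate(theta_names):
        if n.endswith("__dz"):
            continue
        s_val = float(np.sqrt(max(cov_native[t, t], 0.0)))
        se[n] = s_val
        est = p_native[_IDX[n]]
        pvals[n] = float(2 * stats.norm.sf(abs(est) / s_val)) if s_val > 0 else np.nan

    # native-scale log-likelihood: subtract the Jacobian of the scaling
    n_obs_vals = {v: 0 for v in "xmy"}
    for g in groups:
        for oi in g.obs_idx:
            n_obs_vals["xmy"[oi % 3]] += g.data.shape[0]
    ll_native = -res.fun - sum(
        n_obs_vals[v] * np.log(scales[v]) for v in "xmy")

    return PathModelFit(
        model="quasi-causal" if quasi else "phenotypic",
        dnam_variable=dnam_variable,
        params=StructuralParams.from_array(p_native),
        se=se, pvalues=pvals, loglik=float(ll_native),
        converged=bool(res.success),
        n_families=len(wide), n_pairs=n_pairs,
        n_singletons=int(len(wide) - sum(n_pairs.values())),
        ses_center=ses_center, ses_sd=ses_sd,
        constraints={ph: ph in constrained for ph in "xmy"},
        free_names=tuple(n for n in theta_names if not n.endswith("__dz")),
        cov=cov_df,
        zygosity_specific_residuals=zygosity_specific_residuals,
    )


def fit_phenotypic(data, dnam_variable: str, constrain_c: str = "never",
                   zygosity_specific_residuals: bool = False,
                   seed: int = 0) -> PathModelFit:
    """Phenotypic-association model (no latent A/C control).

    Regression system X ~ S; M ~ X, S; Y ~ X, M, S, S*M with coefficients
    equated across twin slots, FIML over missingness patterns, and
    within-pair residual covariance per phenotype (pooled across zygosity
    unless ``zygosity_specific_residuals``).
    """
    return _fit_path_model(data, dnam_variable, quasi=False,
                           constrain_c=constrain_c,
                           zygosity_specific_residuals=zygosity_specific_residuals,
                           seed=seed)


def fit_quasicausal(data, dnam_variable: str, constrain_c: str = "auto",
                    seed: int = 0) -> PathModelFit:
    """Quasi-causal regression model with latent A/C control.

    ``constrain_c``: 'auto' refits with V_C = 0 for any phenotype whose
    unconstrained shared-environment variance goes negative (fixing the
    corresponding b_c paths, which lose identification); 'never' keeps all
    V_C free; 'always' fixes all three at zero; an iterable of phenotype
    letters (e.g. ``{'m', 'y'}``) fixes exactly those up front.
    """
    wide = data.data if isinstance(data, TwinCohort) else data
    for z in ("MZ", "DZ"):
        n = int(((wide["zygosity"] == z) & wide["adult_iq_1"].notna()
                 & wide["adult_iq_2"].notna()).sum())
        if n < 10:
            raise EstimationError(
                f"quasi-causal model needs >= 10 complete {z} pairs, found {n}")
    return _fit_path_model(data, dnam_variable, quasi=True,
                           constrain_c=constrain_c, seed=seed)


# ---------------------------------------------------------------------------
# post-fit utilities

def wald_test(fit: PathModelFit, coefficient: str) -> dict:
    """Two-sided normal test of a fitted coefficient."""
    se = fit.se.get(coefficient, np.nan)
    if not np.isfinite(se) or se <= 0:
        raise EstimationError(f"no positive SE available for '{coefficient}'")
    z = fit.coef(coefficient) / se
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def simple_slopes(fit: PathModelFit, data, split: str = "median") -> ModeratedEffect:
    """Simple slopes of M on adult IQ (conditional on childhood IQ) by SES.

    ``split='median'`` evaluates the slope at the mean SES of each half of
    the sample; ``'plus_minus_1sd'`` at the centering constant +/- 1 SD.
    The slope at the centering constant equals b_p3 exactly.
    """
    wide = data.data if isinstance(data, TwinCohort) else data
    ses = wide["ses"].astype(float).dropna()
    if split == "median":
        med = float(ses.median())
        levels = {"low_ses": float(ses[ses <= med].mean()),
                  "high_ses": float(ses[ses > med].mean())}
    elif split == "plus_minus_1sd":
        levels = {"low_ses": fit.ses_center - fit.ses_sd,
                  "high_ses": fit.ses_center + fit.ses_sd}
    else:
        raise ValueError(f"unknown split {split!r}")

    b3, bi = fit.coef("b_p3"), fit.coef("b_int")
    names = list(fit.cov.index) if fit.cov is not None else []
    have_cov = "b_p3" in names and "b_int" in names
    slopes, slope_se = {}, {}
    for label, s_val in levels.items():
        sc = s_val - fit.ses_center
        slopes[label] = float(b3 + bi * sc)
        if have_cov:
            v = (fit.cov.loc["b_p3", "b_p3"] + sc ** 2 * fit.cov.loc["b_int", "b_int"]
                 + 2 * sc * fit.cov.loc["b_p3", "b_int"])
            slope_se[label] = float(np.sqrt(max(v, 0.0)))
        else:
            slope_se[label] = np.nan
    return ModeratedEffect(
        split=split, levels=levels, slopes=slopes, slope_se=slope_se,
        interaction=float(bi), interaction_se=fit.se.get("b_int", np.nan),
    )


def moderation_scatter_data(data, dnam_variable: str) -> pd.DataFrame:
    """Adult-IQ residuals (on childhood IQ and SES) against the DNAm variable.

    One row per individual with adult-phase data, tagged by an SES median
    split — the data behind the moderation display.
    """
    wide = data.data if isinstance(data, TwinCohort) else data
    rows = []
    for slot in (1, 2):
        rows.append(pd.DataFrame({
            "family_id": wide["family_id"],
            "twin": slot,
            "ses": wide["ses"].astype(float),
            "child_iq": wide[f"child_iq_{slot}"],
            "adult_iq": wide[f"adult_iq_{slot}"],
            "dnam": wide[f"{dnam_variable}_{slot}"],
        }))
    d = pd.concat(rows, ignore_index=True).dropna()
    X = np.column_stack([np.ones(len(d)), d["child_iq"], d["ses"]])
    beta, *_ = np.linalg.lstsq(X, d["adult_iq"].to_numpy(), rcond=None)
    d["adult_iq_residual"] = d["adult_iq"].to_numpy() - X @ beta
    med = d["ses"].median()
    d["ses_group"] = np.where(d["ses"] <= med, "low", "high")
    return d.reset_index(drop=True)
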