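"""Clock preprocessing: age residualization, cell adjustment, winsorization,
and the Gen 1 / Gen 2 composite scores.

The preparation chain turns raw DNAm-age estimates (years) into age-
acceleration scores: each clock is residualized on chronological age at the
adult assessment (OLS), further residualized on the leading principal
components of the six blood-cell proportions, winsorized at ±k sample SDs,
z-standardized, and summed into generation composites (Gen 1: Horvath,
Horvath Skin & Blood, Hannum; Gen 2: PhenoAge, GrimAge). Composites are
sums of member z-scores and are deliberately *not* re-standardized, so a
composite of m highly correlated members has SD approaching m.

All fits use the full analysis sample (both zygosities pooled) and the
sample SD with the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .cohort import CELLS, CLOCKS, GEN1_CLOCKS, GEN2_CLOCKS, TwinCohort
from .errors import DegenerateDataError

AGEADJ, CELLADJ, WINS, ZSUF = "_ageadj", "_celladj", "_wins", "_z"


def residualize_on_age(clock_values, ages) -> np.ndarray:
    """OLS residuals of clock estimates on chronological age.

    Rows where either value is missing get NaN residuals; the regression is
    fit on the complete rows. Residuals have exact zero mean and zero
    correlation with age over the fitting sample.
    """
    y = np.asarray(clock_values, dtype=float)
    x = np.asarray(ages, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise DegenerateDataError("need at least 3 complete (clock, age) rows")
    if np.ptp(x[ok]) == 0:
        raise DegenerateDataError("chronological age is constant; slope undefined")
    fit = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    out = np.full_like(y, np.nan)
    out[ok] = fit.resid
    return out


def cell_pcs(cell_proportions, k: int = 2, var_threshold: float | None = None):
    """Principal components of the blood-cell proportion matrix.

    Returns ``(scores, explained)`` where ``scores`` is n x k and
    ``explained`` the variance-explained fractions of *all* components
    (summing to 1). ``var_threshold`` optionally overrides ``k`` with the
    smallest count whose cumulative variance reaches the threshold. The sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(cell_proportions, dtype=float)
    if (X < 0).any():
        raise DegenerateDataError("cell proportions must be nonnegative")
    if X.shape[0] <= X.shape[1]:
        raise DegenerateDataError("need more individuals than cell types")
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateDataError("cell proportions carry no variance; PCs undefined")
    pca = PCA(n_components=min(X.shape[1], X.shape[0] - 1))
    scores_full = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    if var_threshold is not None:
        k = int(np.searchsorted(np.cumsum(explained), var_threshold) + 1)
    k = min(k, scores_full.shape[1])
    # deterministic sign: largest-|loading| entry positive
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores_full[:, j] *= -1
    return scores_full[:, :k], explained


def adjust_for_cells(residuals, pc_scores) -> np.ndarray:
    """Residualize age-adjusted clock values on the cell-composition PCs."""
    y = np.asarray(residuals, dtype=float)
    Z = np.asarray(pc_scores, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    ok = np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    Zc = Z[ok]
    if np.any(np.isclose(Zc.std(axis=0), 0)):
        raise DegenerateDataError("zero-variance PC column in cell adjustment")
    if np.linalg.matrix_rank(Zc - Zc.mean(axis=0)) < Zc.shape[1]:
        raise DegenerateDataError("collinear PC columns in cell adjustment")
    fit = sm.OLS(y[ok], sm.add_constant(Z[ok])).fit()
    out = np.full_like(y, np.nan)
    out[ok] = fit.resid
    return out


def winsorize(values, k_sd: float = 2.0):
    """Clamp values beyond mean ± k·SD to the boundary.

    Bounds use the pre-winsorization mean and the n-1 sample SD and are not
    re-estimated. Returns ``(winsorized, flags)``; flags mark replaced
    entries. Zero-SD input is returned unchanged with all-False flags.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise DegenerateDataError("winsorization needs at least 2 values")
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    if sd == 0:
        import warnings

        warnings.warn("zero SD: winsorization is a no-op", stacklevel=2)
        return x.copy(), np.zeros_like(x, dtype=bool)
    lo, hi = mu - k_sd * sd, mu + k_sd * sd
    flags = ok & ((x < lo) | (x > hi))
    out = x.copy()
    out[ok] = np.clip(x[ok], lo, hi)
    return out, flags


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (n-1 denominator) over finite entries."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    sd = x[ok].std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("cannot z-score a constant vector")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def composite_scores(z_table: pd.DataFrame):
    """Gen 1 and Gen 2 composites as sums of member z-scores.

    ``z_table`` must hold one ``<clock>_z`` column per clock. Individuals
    missing any member z-score get a missing composite.
    """
    gen1 = z_table[[c + ZSUF for c in GEN1_CLOCKS]].sum(axis=1, skipna=False)
    gen2 = z_table[[c + ZSUF for c in GEN2_CLOCKS]].sum(axis=1, skipna=False)
    return gen1, gen2


@dataclass
class ClockPanel:
    """Per-individual adjusted clocks, composites and preprocessing metadata."""

    data: pd.DataFrame
    pc_variance_explained: np.ndarray
    k_pcs: int
    winsor_k: float

    @property
    def cumulative_pc_variance(self) -> float:
        return float(self.pc_variance_explained[: self.k_pcs].sum())


def build_clock_panel(cohort: TwinCohort, k_pcs: int = 2,
                      winsor_k: float = 2.0) -> ClockPanel:
    """Run the full preparation chain on a cohort.

    Returns a panel keyed by (family_id, twin) with, per clock, the
    ``_ageadj``, ``_celladj``, ``_wins`` and ``_z`` stages plus winsor
    flags, and the ``gen1`` / ``gen2`` composites. Only individuals with
    adult-phase data contribute; z-standardization is computed over the
    composite analysis sample (rows with all five clocks) so composites
    have exact zero mean.
    """
    ind = cohort.to_individuals()
    panel = ind[["family_id", "twin", "zygosity", "ses", "sex",
                 "child_age", "adult_age", "child_iq", "adult_iq"]].copy()

    has_cells = ind[[c for c in CELLS]].notna().all(axis=1)
    scores = np.full((len(ind), k_pcs), np.nan)
    pcs, explained = cell_pcs(ind.loc[has_cells, list(CELLS)].to_numpy(), k=k_pcs)
    scores[has_cells.to_numpy()] = pcs
    for j in range(k_pcs):
        panel[f"cell_pc{j + 1}"] = scores[:, j]

    for clock in CLOCKS:
        ageadj = residualize_on_age(ind[clock], ind["adult_age"])
        celladj = adjust_for_cells(ageadj, scores)
        wins, flags = winsorize(celladj, k_sd=winsor_k)
        panel[clock + AGEADJ] = ageadj
        panel[clock + CELLADJ] = celladj
        panel[clock + WINS] = wins
        panel[clock + "_winsflag"] = flags

    complete = panel[[c + WINS for c in CLOCKS]].notna().all(axis=1)
    for clock in CLOCKS:
        z = np.full(len(panel), np.nan)
        z[complete.to_numpy()] = zscore(panel.loc[complete, clock + WINS])
        panel[clock + ZSUF] = z

    panel["gen1"], panel["gen2"] = composite_scores(panel)
    return ClockPanel(panel, explained, k_pcs, winsor_k)
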