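"""End-to-end orchestration: simulate/load -> prep -> EFA -> ACE -> path models.

Stages are pure functions of (input, config, seed); a run writes a cohort
snapshot, the clock panel, factor-analysis summaries, ACE tables for all
five clocks and both composites, both path-model fits per requested
composite, a moderation display, and a manifest with content hashes so a
re-run under the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ace import fit_ace, twin_correlations
from .clockprep import WINS, build_clock_panel
from .cohort import CLOCKS, TwinCohort, attach_composites, read_cohort, write_cohort
from .efa import assign_generations, fit_efa, lrt_factors
from .errors import ConfigError, TwinclockError
from .quasicausal import (fit_phenotypic, fit_quasicausal,
                          moderation_scatter_data, simple_slopes)
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("twinclock")

_COMPOSITES = ("gen1", "gen2")


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, one seed, one output dir."""

    outdir: str | Path = "twinclock_run"
    seed: int = 0
    input_csv: str | Path | None = None
    simulation: SimulationConfig | None = None
    composite: str = "both"          # gen1 | gen2 | both
    k_pcs: int = 2
    winsor_k: float = 2.0
    constrain_c: str = "auto"
    make_plots: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigError(
                "input_csv",
                "exactly one of input_csv / simulation must be given")
        if self.composite not in ("gen1", "gen2", "both"):
            raise ConfigError("composite", f"unknown composite {self.composite!r}")

    @property
    def composites(self) -> tuple:
        return _COMPOSITES if self.composite == "both" else (self.composite,)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def descriptives_table(cohort: TwinCohort, wide_aug: pd.DataFrame,
                       variables) -> pd.DataFrame:
    """Sample-characteristics report: mean (SD) plus MZ/DZ pair correlations."""
    rows = []
    ind_frames = []
    for slot in (1, 2):
        ind_frames.append(wide_aug[[f"{v}_{slot}" for v in variables]]
                          .rename(columns={f"{v}_{slot}": v for v in variables}))
    ind = pd.concat(ind_frames, ignore_index=True)
    for v in variables:
        vals = ind[v].dropna()
        try:
            tc = twin_correlations(wide_aug, v)
            r_mz, se_mz, r_dz, se_dz = tc.r_mz, tc.se_mz, tc.r_dz, tc.se_dz
        except TwinclockError:
            r_mz = se_mz = r_dz = se_dz = np.nan
        rows.append({
            "variable": v, "n": int(vals.size),
            "mean": vals.mean(), "sd": vals.std(ddof=1),
            "r_mz": r_mz, "se_mz": se_mz, "r_dz": r_dz, "se_dz": se_dz,
        })
    return pd.DataFrame(rows)


def path_model_table(fits: dict) -> pd.DataFrame:
    """Two-panel coefficient report (phenotypic and quasi-causal columns)."""
    frames = []
    for label, fit in fits.items():
        t = fit.summary_table()
        t.insert(0, "model", label)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns in-memory results and writes the bundle."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        stage = "cohort"
        if config.simulation is not None:
            sim = config.simulation
            sim = SimulationConfig(**{**sim.__dict__, "rng_seed": config.seed})
            cohort = simulate_cohort(sim)
            log.info("simulated %d families (%d singletons)",
                     cohort.n_families, cohort.n_singletons)
        else:
            cohort = read_cohort(config.input_csv)
            log.info("read %d families from %s", cohort.n_families,
                     config.input_csv)
        write_cohort(cohort, outdir / "cohort.csv")
        results["cohort"] = cohort

        stage = "prep"
        panel = build_clock_panel(cohort, k_pcs=config.k_pcs,
                                  winsor_k=config.winsor_k)
        panel.data.to_csv(outdir / "clock_panel.csv", index=False, na_rep="NA")
        results["panel"] = panel
        wide = attach_composites(
            cohort, panel.data,
            columns=[c + WINS for c in CLOCKS] + list(_COMPOSITES)).data
        results["wide"] = wide

        stage = "efa"
        X = panel.data[[c + WINS for c in CLOCKS]].to_numpy()
        sol1 = fit_efa(X, 1)
        sol2 = fit_efa(X, 2)
        lrt = lrt_factors(sol1, sol2)
        gens = assign_generations(sol2)
        loadings = pd.DataFrame(
            sol2.loadings,
            index=list(CLOCKS),
            columns=[f"factor_{j + 1}" for j in range(2)])
        loadings.to_csv(outdir / "efa_loadings.csv", index_label="clock")
        efa_summary = {
            "eigenvalues": sol2.eigenvalues,
            "one_factor": {"chi2": sol1.chi2, "df": sol1.df, "rmsea": sol1.rmsea},
            "two_factor": {"chi2": sol2.chi2, "df": sol2.df, "rmsea": sol2.rmsea,
                           "rmsea_ci95": sol2.rmsea_ci,
                           "rmsea_ci90": sol2.rmsea_ci_90},
            "factor_corr": float(sol2.factor_corr[0, 1]),
            "lrt": lrt,
            "generation_factors": gens,
            "n_obs": sol2.n_obs,
        }
        _write_json(efa_summary, outdir / "efa_summary.json")
        results["efa"] = {"one_factor": sol1, "two_factor": sol2, "lrt": lrt,
                          "summary": efa_summary}

        stage = "descriptives"
        desc_vars = (["child_iq", "adult_iq"] + [c + WINS for c in CLOCKS]
                     + list(_COMPOSITES))
        desc = descriptives_table(cohort, wide, desc_vars)
        desc.to_csv(outdir / "descriptives.csv", index=False)
        results["descriptives"] = desc

        stage = "ace"
        ace_rows = []
        ace_fits = {}
        for v in [c + WINS for c in CLOCKS] + list(_COMPOSITES):
            fit = fit_ace(wide, v, seed=config.seed)
            ace_fits[v] = fit
            ace_rows.append({
                "variable": v, "status": fit.status,
                **{k: fit.variances[k] for k in ("V_A", "V_C", "V_E")},
                **{f"{k}_se": fit.variance_se[k] for k in ("V_A", "V_C", "V_E")},
                **fit.standardized,
                **{f"{k}_ci_lo": fit.standardized_ci[k][0] for k in ("a2", "c2", "e2")},
                **{f"{k}_ci_hi": fit.standardized_ci[k][1] for k in ("a2", "c2", "e2")},
                "loglik": fit.loglik,
            })
        ace_table = pd.DataFrame(ace_rows)
        ace_table.to_csv(outdir / "ace_estimates.csv", index=False)
        results["ace"] = ace_fits
        results["ace_table"] = ace_table

        stage = "models"
        results["models"] = {}
        for comp in config.composites:
            pheno = fit_phenotypic(wide, comp, seed=config.seed)
            quasi = fit_quasicausal(wide, comp, constrain_c=config.constrain_c,
                                    seed=config.seed)
            slopes = simple_slopes(quasi, wide, split="median")
            table = path_model_table({"phenotypic": pheno, "quasi-causal": quasi})
            table.to_csv(outdir / f"path_model_{comp}.csv", index=False)
            _write_json({
                "composite": comp,
                "constraints": quasi.constraints,
                "ses_center": quasi.ses_center,
                "loglik": {"phenotypic": pheno.loglik, "quasi": quasi.loglik},
                "simple_slopes": {"levels": slopes.levels,
                                  "slopes": slopes.slopes,
                                  "se": slopes.slope_se},
            }, outdir / f"path_model_{comp}.json")
            scatter = moderation_scatter_data(wide, comp)
            scatter.to_csv(outdir / f"moderation_scatter_{comp}.csv", index=False)
            if config.make_plots:
                _moderation_plot(scatter, comp,
                                 outdir / f"moderation_{comp}.png")
            results["models"][comp] = {
                "phenotypic": pheno, "quasi_causal": quasi,
                "simple_slopes": slopes,
            }

        stage = "manifest"
        files = sorted(f for f in outdir.iterdir()
                       if f.is_file() and f.name != "manifest.json")
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "composite": config.composite,
            "k_pcs": config.k_pcs,
            "winsor_k": config.winsor_k,
            "constrain_c": config.constrain_c,
            "input": str(config.input_csv) if config.input_csv else "simulated",
            "outputs": {f.name: _sha256(f) for f in files},
        }
        _write_json(manifest, outdir / "manifest.json")
        results["manifest"] = manifest
    except TwinclockError as exc:
        raise TwinclockError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results


def _moderation_plot(scatter: pd.DataFrame, comp: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for group, color in (("low", "tab:red"), ("high", "tab:blue")):
        sub = scatter[scatter["ses_group"] == group]
        ax.scatter(sub["dnam"], sub["adult_iq_residual"], s=12, alpha=0.5,
                   color=color, label=f"{group} SES")
        if len(sub) > 2:
            b = np.polyfit(sub["dnam"], sub["adult_iq_residual"], 1)
            xs = np.linspace(sub["dnam"].min(), sub["dnam"].max(), 20)
            ax.plot(xs, np.polyval(b, xs), color=color)
    ax.set_xlabel(f"{comp} DNAmAge composite (age/cell adjusted)")
    ax.set_ylabel("Adult IQ residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "twinclock"})
    plt.close(fig)
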