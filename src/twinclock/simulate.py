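"""Synthetic twin-cohort generator.

Emulates a midlife twin cohort with prospective childhood records: childhood
IQ, adult IQ, family-level childhood SES (Duncan-type 0-100 index), five raw
DNAm-age clock estimates per adult twin and six blood-cell proportions. The
phenotypes follow the structural twin model of :mod:`twinclock.params`
(childhood IQ -> DNAm-age factor -> adult IQ, each with ACE components and
SES effects, plus an SES x DNAmAge moderation of the adult-IQ equation).

Clock readouts are generated at the "years of DNAm age" level, downstream of
any laboratory processing: each clock tracks chronological age with a unit
slope, is shifted by blood-cell composition, loads on one of two correlated
latent generation factors (first-generation clocks trained on chronological
age; second-generation clocks trained on phenotypic aging, driven by the
structural M variable), and carries clock-specific residual variation that
is itself partly heritable.

A configurable fraction of families are "singleton" twins: the slot-2
co-twin retains childhood records but contributes no adult-phase data
(adult IQ, clocks, cells), mirroring cohorts where both members were studied
as children but only one returned in midlife.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import (ADULT_PHASE, CELLS, CLOCKS, COLUMNS, TwinCohort,
                     _PER_TWIN)
from .errors import ConfigError
from .params import StructuralParams, reference_structural_params


@dataclass
class ClockModel:
    """Measurement model mapping the latent DNAm factors to clock readouts.

    ``loadings`` is a 5 x 2 matrix (clock by [gen1 factor, gen2 factor]) in
    years per factor SD. The gen2 factor is the standardized structural M
    variable; the gen1 factor correlates ``factor_corr`` with it, its
    independent part having heritability ``gen1_unique_a2``. Clock-specific
    residuals have SD ``unique_sd`` (years) with heritable share
    ``unique_a2``. ``age_slope`` multiplies (adult age - cohort mean age) and
    ``cell_effect`` multiplies the centered granulocyte fraction.
    """

    loadings: tuple = (
        (2.70, 0.0),    # horvath
        (2.87, 0.0),    # horvath_sb
        (2.60, 0.0),    # hannum
        (0.0, 3.36),    # phenoage
        (0.0, 2.74),    # grimage
    )
    factor_corr: float = 0.57
    gen1_unique_a2: float = 0.55
    gen1_unique_c2: float = 0.0
    age_slope: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    cell_effect: tuple = (4.0, 4.0, 5.0, 8.0, 3.0)
    unique_sd: tuple = (2.02, 2.15, 1.95, 2.52, 2.05)
    unique_a2: float = 0.6
    unique_c2: float = 0.0

    def validate(self) -> None:
        if not -1.0 < self.factor_corr < 1.0:
            raise ConfigError("factor_corr", f"must lie in (-1, 1), got {self.factor_corr}")
        if len(self.loadings) != len(CLOCKS):
            raise ConfigError("loadings", "need one (gen1, gen2) loading pair per clock")
        for name in ("age_slope", "cell_effect", "unique_sd"):
            if len(getattr(self, name)) != len(CLOCKS):
                raise ConfigError(name, "need one entry per clock")
        if any(s < 0 for s in self.unique_sd):
            raise ConfigError("unique_sd", "must be nonnegative")
        for name in ("gen1_unique_a2", "gen1_unique_c2", "unique_a2", "unique_c2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"variance share must lie in [0, 1], got {v}")
        if self.gen1_unique_a2 + self.gen1_unique_c2 > 1.0:
            raise ConfigError("gen1_unique_a2", "A + C shares of the gen1 factor exceed 1")
        if self.unique_a2 + self.unique_c2 > 1.0:
            raise ConfigError("unique_a2", "A + C shares of clock residuals exceed 1")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    ``singleton_fraction`` is the expected share of *midlife individuals*
    whose co-twin contributes no adult-phase data (the scale on which twin
    studies report "individual twins", e.g. 85 of 287); it is converted
    internally to the per-family deletion probability 2f / (1 + f).
    ``ses_mean`` / ``ses_sd`` are the target marginal moments *after*
    truncation to ``ses_bounds``; the parent normal parameters are solved to
    match them.
    """

    n_mz_pairs: int = 110
    n_dz_pairs: int = 76
    singleton_fraction: float = 85 / 287
    ses_mean: float = 47.3
    ses_sd: float = 25.7
    ses_bounds: tuple = (0.0, 100.0)
    child_age_mean: float = 14.42
    child_age_sd: float = 1.93
    adult_age_mean: float = 51.87
    adult_age_sd: float = 7.03
    female_prob: float = 0.589
    structural: StructuralParams = field(default_factory=StructuralParams)
    clock_model: ClockModel = field(default_factory=ClockModel)
    cell_alpha: tuple = (5.4, 9.6, 3.3, 3.9, 4.8, 33.0)  # cd8t, cd4t, nk, b, mono, gran
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ConfigError("n_mz_pairs", "pair counts must be nonnegative")
        if self.n_mz_pairs + self.n_dz_pairs == 0:
            raise ConfigError("n_mz_pairs", "at least one family is required")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ConfigError(
                "singleton_fraction",
                f"must lie in [0, 1], got {self.singleton_fraction}",
            )
        for name in ("ses_sd", "child_age_sd", "adult_age_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "standard deviation must be nonnegative")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ConfigError("female_prob", "must lie in [0, 1]")
        if len(self.cell_alpha) != len(CELLS):
            raise ConfigError("cell_alpha", f"need {len(CELLS)} Dirichlet concentrations")
        if any(a <= 0 for a in self.cell_alpha):
            raise ConfigError("cell_alpha", "concentrations must be positive")
        self.structural.validate()
        self.clock_model.validate()

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["structural"] = StructuralParams(**payload.get("structural", {}))
        clock = payload.get("clock_model", {})
        for key, value in list(clock.items()):
            if isinstance(value, list):
                clock[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        payload["clock_model"] = ClockModel(**clock)
        for key in ("ses_bounds", "cell_alpha"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def default_config(**overrides) -> SimulationConfig:
    """Native-unit study conditions emulating the midlife cohort.

    Marginals target the published demographics: childhood IQ mean 102.7,
    SD 13.4; adult IQ mean 105.4, SD ~13.8; Duncan SES mean 47.3, SD 25.7;
    testing ages 14.4 (1.93) and 51.9 (7.03); ~30% singleton twins. ACE
    variances reproduce childhood-IQ twin correlations near 0.88 (MZ) /
    0.58 (DZ) and second-generation clock-composite correlations near
    0.71 / 0.42 once the SES contribution to cross-twin covariance is
    accounted for. The latent M variable is scaled to unit variance.
    """
    structural = StructuralParams(
        mu_x=102.7, mu_m=0.0, mu_y=43.6,
        b_sx=0.156, b_sm=-0.008, b_sy=0.02,
        b_p1=0.60, b_p2=0.0, b_p3=-1.8, b_int=0.03,
        b_a1=0.25, b_c1=0.30, b_a2=0.0, b_c2=0.0, b_a3=0.5, b_c3=0.0,
        va_x=107.6, vc_x=34.2, ve_x=21.6,
        va_m=0.62, vc_m=0.0, ve_m=0.33,
        va_y=28.0, vc_y=6.0, ve_y=22.0,
    )
    cfg = SimulationConfig(structural=structural)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def recovery_config(n_mz_pairs: int = 2500, n_dz_pairs: int = 2500,
                    rng_seed: int = 0, **structural_overrides) -> SimulationConfig:
    """Rescaled-unit conditions for parameter-recovery studies.

    Uses the published-scale structural truth (standardized SES, compressed
    IQ metric), no singletons, and clocks generated but unused: recovery
    fits read the exact latent M (``dnam_latent`` columns), so measurement
    error does not attenuate the structural coefficients under study.
    """
    structural = reference_structural_params().replace(**structural_overrides)
    return SimulationConfig(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        singleton_fraction=0.0,
        ses_mean=0.0,
        ses_sd=1.0,
        ses_bounds=(-1e6, 1e6),
        structural=structural,
        rng_seed=rng_seed,
    )


def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent normal (mu, sigma) whose [lo, hi]-truncation has the target moments."""
    if sd == 0:
        return mean, 0.0
    z_lo = (lo - mean) / sd
    z_hi = (hi - mean) / sd
    if z_lo < -8 and z_hi > 8:  # truncation is immaterial
        return mean, sd

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, [mean, np.log(sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_ace(rng, zyg: np.ndarray, va: float, vc: float, ve: float):
    """Latent A/C/E draws for both twin slots.

    Returns per-slot totals (A_1 + C + E_1, ...) is NOT done here; the three
    components are returned separately because structural paths address A
    and C individually. A is correlated 1.0 within MZ and 0.5 within DZ
    pairs, C is shared, E is independent.
    """
    n = len(zyg)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a1 = np.sqrt(va) * z1
    a2 = np.where(zyg == "MZ", a1, np.sqrt(va) * (0.5 * z1 + np.sqrt(0.75) * z2))
    c = np.sqrt(vc) * rng.standard_normal(n)
    e1 = np.sqrt(ve) * rng.standard_normal(n)
    e2 = np.sqrt(ve) * rng.standard_normal(n)
    return (a1, a2), c, (e1, e2)


def simulate_cohort(config: SimulationConfig) -> TwinCohort:
    """Draw one cohort under ``config``; byte-reproducible given the seed."""
    config.validate()
    p = config.structural
    cm = config.clock_model
    rng = np.random.default_rng(config.rng_seed)

    n = config.n_mz_pairs + config.n_dz_pairs
    zyg = np.array(["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs)

    # family-level SES, centered at the sample mean (the fitting convention)
    mu_s, sigma_s = _truncnorm_parent(config.ses_mean, config.ses_sd, *config.ses_bounds)
    if sigma_s == 0:
        ses = np.full(n, mu_s)
    else:
        a, b = [(x - mu_s) / sigma_s for x in config.ses_bounds]
        ses = stats.truncnorm.rvs(a, b, loc=mu_s, scale=sigma_s, size=n, random_state=rng)
    s_c = ses - ses.mean()

    child_age = config.child_age_mean + config.child_age_sd * rng.standard_normal(n)
    adult_age = config.adult_age_mean + config.adult_age_sd * rng.standard_normal(n)

    sex_mz = rng.random(n) < config.female_prob  # one draw reused for MZ slot 2
    sex2_dz = rng.random(n) < config.female_prob
    sex1 = np.where(sex_mz, "F", "M")
    sex2 = np.where(np.where(zyg == "MZ", sex_mz, sex2_dz), "F", "M")

    (ax1, ax2), cx, (ex1, ex2) = _draw_ace(rng, zyg, p.va_x, p.vc_x, p.ve_x)
    (am1, am2), cmm, (em1, em2) = _draw_ace(rng, zyg, p.va_m, p.vc_m, p.ve_m)
    (ay1, ay2), cy, (ey1, ey2) = _draw_ace(rng, zyg, p.va_y, p.vc_y, p.ve_y)

    def phenotypes(ax, ex, am, em, ay, ey):
        x = p.mu_x + p.b_sx * s_c + ax + cx + ex
        m = (p.mu_m + p.b_sm * s_c + p.b_p2 * x + p.b_a2 * ax + p.b_c2 * cx
             + am + cmm + em)
        q = p.b_p3 + p.b_int * s_c
        y = (p.mu_y + p.b_sy * s_c + p.b_p1 * x + q * m
             + p.b_a1 * ax + p.b_c1 * cx + p.b_a3 * am + p.b_c3 * cmm
             + ay + cy + ey)
        return x, m, y

    x1, m1, y1 = phenotypes(ax1, ex1, am1, em1, ay1, ey1)
    x2, m2, y2 = phenotypes(ax2, ex2, am2, em2, ay2, ey2)

    # blood-cell composition
    cells1 = rng.dirichlet(config.cell_alpha, size=n)
    cells2 = rng.dirichlet(config.cell_alpha, size=n)
    gran_idx = CELLS.index("gran")
    gran_mean = config.cell_alpha[gran_idx] / sum(config.cell_alpha)

    # latent generation factors: gen2 = standardized M, gen1 correlated with it
    m_all = np.concatenate([m1, m2])
    m_mu, m_sd = m_all.mean(), m_all.std()
    if m_sd == 0:
        m_sd = 1.0
    z_m1, z_m2 = (m1 - m_mu) / m_sd, (m2 - m_mu) / m_sd
    ew = 1.0 - cm.gen1_unique_a2 - cm.gen1_unique_c2
    (wa1, wa2), wc, (we1, we2) = _draw_ace(rng, zyg, cm.gen1_unique_a2,
                                           cm.gen1_unique_c2, ew)
    phi = cm.factor_corr
    g1_1 = phi * z_m1 + np.sqrt(1 - phi ** 2) * (wa1 + wc + we1)
    g1_2 = phi * z_m2 + np.sqrt(1 - phi ** 2) * (wa2 + wc + we2)

    clock_values = {1: {}, 2: {}}
    for k, clock in enumerate(CLOCKS):
        lam1, lam2 = cm.loadings[k]
        u2 = cm.unique_sd[k] ** 2
        eu = 1.0 - cm.unique_a2 - cm.unique_c2
        (ua1, ua2), uc, (ue1, ue2) = _draw_ace(
            rng, zyg, u2 * cm.unique_a2, u2 * cm.unique_c2, u2 * eu)
        for slot, (g1, g2, age, cells, u) in {
            1: (g1_1, z_m1, adult_age, cells1, ua1 + uc + ue1),
            2: (g1_2, z_m2, adult_age, cells2, ua2 + uc + ue2),
        }.items():
            clock_values[slot][clock] = (
                config.adult_age_mean
                + cm.age_slope[k] * (age - config.adult_age_mean)
                + cm.cell_effect[k] * (cells[:, gran_idx] - gran_mean)
                + lam1 * g1 + lam2 * g2 + u
            )

    wide = {
        "family_id": np.arange(1, n + 1),
        "zygosity": zyg,
        "ses": ses,
    }
    per_slot = {
        1: dict(sex=sex1, child_age=child_age, adult_age=adult_age,
                child_iq=x1, adult_iq=y1, dnam_latent=m1,
                **clock_values[1],
                **{c: cells1[:, i] for i, c in enumerate(CELLS)}),
        2: dict(sex=sex2, child_age=child_age, adult_age=adult_age,
                child_iq=x2, adult_iq=y2, dnam_latent=m2,
                **clock_values[2],
                **{c: cells2[:, i] for i, c in enumerate(CELLS)}),
    }
    for slot in (1, 2):
        for name in _PER_TWIN:
            wide[f"{name}_{slot}"] = per_slot[slot][name]

    df = pd.DataFrame(wide)[list(COLUMNS)]

    # singleton deletion: slot-2 adult-phase fields removed, childhood kept
    f = config.singleton_fraction
    p_fam = 2.0 * f / (1.0 + f)
    singleton = rng.random(n) < p_fam
    for name in ADULT_PHASE:
        df.loc[singleton, f"{name}_2"] = np.nan

    return TwinCohort(df)
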