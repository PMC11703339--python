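"""Wide-by-pair twin cohort container and CSV round-trip.

Schema (version 1): one row per family. Family-level columns are
``family_id``, ``zygosity`` (MZ/DZ) and ``ses`` (Duncan-type index, shared
by both twins). Per-twin columns carry the suffix ``_1`` / ``_2``: sex,
child_age, adult_age, child_iq, adult_iq, the five raw clock estimates
(years), six blood-cell proportions summing to one, and ``dnam_latent``,
the generator's error-free DNAm-age factor score (kept for validation
studies; absent-by-construction in real data). Missing values are written
with the ``NA`` token. Slot 2 may lack all adult-phase fields (a singleton
twin whose co-twin has childhood records only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortValidationError

SCHEMA_VERSION = 1

CLOCKS = ("horvath", "horvath_sb", "hannum", "phenoage", "grimage")
GEN1_CLOCKS = ("horvath", "horvath_sb", "hannum")
GEN2_CLOCKS = ("phenoage", "grimage")
CELLS = ("cd8t", "cd4t", "nk", "bcell", "mono", "gran")

_PER_TWIN = (
    ("sex",) + ("child_age", "adult_age", "child_iq", "adult_iq")
    + CLOCKS + CELLS + ("dnam_latent",)
)

FAMILY_COLUMNS = ("family_id", "zygosity", "ses")
COLUMNS = tuple(FAMILY_COLUMNS) + tuple(
    f"{c}_{slot}" for slot in (1, 2) for c in _PER_TWIN
)

#: Adult-phase fields blanked for the non-participating co-twin of a singleton.
ADULT_PHASE = ("adult_iq",) + CLOCKS + CELLS + ("dnam_latent",)

_CELL_SUM_TOL = 1e-6


@dataclass
class TwinCohort:
    """A validated wide-by-pair cohort table."""

    data: pd.DataFrame

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)

    @property
    def n_families(self) -> int:
        return len(self.data)

    def families(self, zygosity: str) -> pd.DataFrame:
        return self.data[self.data["zygosity"] == zygosity]

    def is_complete_member(self, slot: int) -> pd.Series:
        """Twins in ``slot`` with full childhood + adult-phase records."""
        d = self.data
        cols = [f"{c}_{slot}" for c in ("child_iq", "adult_iq") + CLOCKS]
        return d[cols].notna().all(axis=1)

    @property
    def n_singletons(self) -> int:
        """Families whose slot-2 twin lacks adult-phase data."""
        return int((~self.is_complete_member(2)).sum())

    @property
    def n_complete_pairs(self) -> int:
        return int((self.is_complete_member(1) & self.is_complete_member(2)).sum())

    @property
    def n_adult_individuals(self) -> int:
        """Individuals contributing adult-phase data (the midlife sample)."""
        return int(self.is_complete_member(1).sum() + self.is_complete_member(2).sum())

    def to_individuals(self) -> pd.DataFrame:
        """Long table, one row per twin, for individual-level preprocessing."""
        frames = []
        for slot in (1, 2):
            cols = {f"{c}_{slot}": c for c in _PER_TWIN}
            sub = self.data[list(FAMILY_COLUMNS) + list(cols)].rename(columns=cols)
            sub.insert(1, "twin", slot)
            frames.append(sub)
        out = pd.concat(frames, ignore_index=True)
        # drop phantom slot-2 rows that carry no data at all
        payload = [c for c in _PER_TWIN if c != "sex"]
        return out[out[payload].notna().any(axis=1)].reset_index(drop=True)


def validate_cohort(df: pd.DataFrame) -> None:
    """Check the schema invariants, reporting 1-based CSV row numbers."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory columns: {missing}")

    def rownum(idx) -> int:
        return int(idx) + 2  # header is row 1

    bad_zyg = ~df["zygosity"].isin(["MZ", "DZ"])
    if bad_zyg.any():
        idx = df.index[bad_zyg][0]
        raise CohortValidationError(
            f"zygosity must be MZ or DZ, got {df.loc[idx, 'zygosity']!r}",
            row=rownum(idx),
        )

    if df["ses"].isna().any():
        idx = df.index[df["ses"].isna()][0]
        raise CohortValidationError("family-level SES is missing", row=rownum(idx))

    for slot in (1, 2):
        cells = df[[f"{c}_{slot}" for c in CELLS]]
        present = cells.notna().all(axis=1)
        if (cells.to_numpy() < 0).any():
            idx = df.index[(cells < 0).any(axis=1)][0]
            raise CohortValidationError(
                f"negative cell proportion in twin {slot}", row=rownum(idx)
            )
        sums = cells[present].sum(axis=1)
        off = sums[(sums - 1.0).abs() > _CELL_SUM_TOL]
        if len(off):
            idx = off.index[0]
            raise CohortValidationError(
                f"cell proportions of twin {slot} sum to {off.iloc[0]:.6f}, expected 1",
                row=rownum(idx),
            )
        partial = cells.notna().any(axis=1) & ~present
        if partial.any():
            idx = df.index[partial][0]
            raise CohortValidationError(
                f"twin {slot} has an incomplete cell-proportion record",
                row=rownum(idx),
            )

    cohort = TwinCohort(df)
    complete = cohort.is_complete_member(1) | cohort.is_complete_member(2)
    if (~complete).any():
        idx = df.index[~complete][0]
        raise CohortValidationError(
            "family has no member with complete childhood and adult-phase data",
            row=rownum(idx),
        )


def write_cohort(cohort: TwinCohort, path) -> None:
    """Write the cohort as UTF-8 CSV with ``NA`` missing-value tokens."""
    cohort.data.to_csv(path, index=False, na_rep="NA", columns=list(COLUMNS))


def read_cohort(path) -> TwinCohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortValidationError(f"malformed cohort CSV: {exc}") from exc
    for col in ("ses",) + tuple(
        f"{c}_{s}" for s in (1, 2)
        for c in ("child_age", "adult_age", "child_iq", "adult_iq")
        + CLOCKS + CELLS + ("dnam_latent",)
    ):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    validate_cohort(df)
    return TwinCohort(df)


def attach_composites(cohort: TwinCohort, panel: pd.DataFrame,
                      columns=("gen1", "gen2")) -> TwinCohort:
    """Merge per-individual panel columns back onto the wide pair table.

    ``panel`` must carry ``family_id`` and ``twin`` keys (as produced by the
    clock-preparation chain); each requested column is appended with the
    usual ``_1`` / ``_2`` slot suffix.
    """
    wide = cohort.data.copy()
    for slot in (1, 2):
        sub = panel[panel["twin"] == slot].set_index("family_id")
        for col in columns:
            wide[f"{col}_{slot}"] = wide["family_id"].map(sub[col])
    return TwinCohort(wide)
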