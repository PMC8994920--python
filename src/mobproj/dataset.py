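"""Assembly of the analysis dataset and ADL/IADL score derivation.

The analysis dataset is the wide panel restricted to individuals who were
at least 50 years old at the grid's first year and who participated at
their study's first configured wave.  A study observed at a single
follow-up occasion between the two final waves (the Finnish Health 2011
design) has each participant's follow-up randomly assigned to one of the
two final waves by a fair, seeded coin.

Scores are the sum of six dichotomous items (1 = no difficulty), so they
live in {0,...,6} with 0 indicating severe disability.  They are derived
only after imputation, and the item columns are then dropped, so every
downstream model sees scores rather than items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .rng import stable_uniform
from .schema import (
    ADL_ITEMS,
    IADL_ITEMS,
    ID_COLS,
    ITEMS,
    OUTCOMES,
    RISK_FACTORS,
    SUBSTANTIVE,
    col,
)


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class StudyRules:
    """Per-study assembly rules.

    ``first_wave``: the study's baseline wave (participation there is the
    eligibility condition).  ``single_followup``: pair of final waves the
    single follow-up occasion is split across, or ``None``.
    ``structural_missing``: (years, variables) pairs blanked with certainty.
    """

    first_wave: int
    single_followup: tuple[int, int] | None = None
    structural_missing: tuple[tuple[tuple[int, ...], tuple[str, ...]], ...] = ()


def default_rules(wave_years=(2000, 2002, 2004, 2006, 2008, 2010, 2012)) -> dict[str, StudyRules]:
    """Assembly rules mirroring the three-study design."""
    y = tuple(wave_years)
    return {
        "HRS": StudyRules(first_wave=y[0]),
        "ELSA": StudyRules(first_wave=y[1]),
        "H2000": StudyRules(first_wave=y[0], single_followup=(y[-2], y[-1])),
    }


def _participated(table: pd.DataFrame, year: int) -> pd.Series:
    """A row participated at a wave if any substantive variable is observed."""
    cols = [c for c in (col(v, year) for v in SUBSTANTIVE) if c in table.columns]
    return table[cols].notna().any(axis=1)


def assemble(
    raw: pd.DataFrame,
    rules: Mapping[str, StudyRules],
    wave_years: Iterable[int],
    seed: int,
    min_baseline_age: int = 50,
) -> pd.DataFrame:
    """Build the analysis dataset from a raw cohort table.

    Deterministic and idempotent for a fixed seed: the follow-up wave
    assignment is keyed to the individual id, not to row order.
    """
    years = tuple(wave_years)
    studies = set(raw["study"].unique())
    unknown = set(rules) - studies
    if unknown:
        raise AssemblyError(f"rules reference unknown studies: {sorted(unknown)}")
    for label, r in rules.items():
        waves = {r.first_wave}
        if r.single_followup:
            waves |= set(r.single_followup)
        for yrs, _ in r.structural_missing:
            waves |= set(yrs)
        bad = waves - set(years)
        if bad:
            raise AssemblyError(f"rules[{label}] reference unknown waves: {sorted(bad)}")
    missing_rules = studies - set(rules)
    if missing_rules:
        raise AssemblyError(f"no rules for studies: {sorted(missing_rules)}")

    out = raw.copy()

    # structural blanking (idempotent)
    for label, r in rules.items():
        rows = out["study"] == label
        for yrs, variables in r.structural_missing:
            for y in yrs:
                for v in variables:
                    out.loc[rows, col(v, y)] = np.nan

    # eligibility: baseline age and first-wave participation
    keep = out[col("age", years[0])] >= min_baseline_age
    for label, r in rules.items():
        rows = out["study"] == label
        keep &= ~rows | _participated(out, r.first_wave)
    out = out.loc[keep].reset_index(drop=True)

    # single-follow-up assignment: keep one of the two final waves per individual
    for label, r in rules.items():
        if r.single_followup is None:
            continue
        early, late = r.single_followup
        rows = out["study"] == label
        u = out.loc[rows, "id"].map(
            lambda i: stable_uniform(seed, "followup", label, i)
        )
        keep_early = u < 0.5
        out.loc[keep_early.index[keep_early], [col(v, late) for v in SUBSTANTIVE]] = np.nan
        out.loc[keep_early.index[~keep_early], [col(v, early) for v in SUBSTANTIVE]] = np.nan
    return out


def derive_score(items) -> int:
    """Sum of six 0/1 items; 0 = severe disability, 6 = no difficulty."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (6,):
        raise ValueError("a score is derived from exactly six items")
    if np.isnan(arr).any():
        raise ValueError("cannot derive a score from incomplete items")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("items must be binary 0/1")
    return int(arr.sum())


def attach_scores(imputed: pd.DataFrame, wave_years: Iterable[int]) -> pd.DataFrame:
    """Derive per-wave ADL/IADL scores and drop the item columns.

    Requires complete items at every wave where the individual is alive
    (i.e. it is called on post-imputation data); scores are missing at
    waves where the individual is dead.
    """
    years = tuple(wave_years)
    out = imputed.copy()
    for y in years:
        live = out[col("alive", y)] == 1
        for score_name, item_set in (("adl_score", ADL_ITEMS), ("iadl_score", IADL_ITEMS)):
            item_cols = [col(v, y) for v in item_set]
            block = out.loc[live, item_cols]
            if block.isna().any().any():
                bad_col = block.columns[block.isna().any()][0]
                bad_id = out.loc[live].loc[block[bad_col].isna(), "id"].iloc[0]
                raise ValueError(
                    f"residual missingness: {bad_col} for individual {bad_id}"
                )
            vals = np.full(len(out), np.nan)
            vals[live.to_numpy()] = block.to_numpy(dtype=float).sum(axis=1)
            out[col(score_name, y)] = vals
    out = out.drop(columns=[col(v, y) for y in years for v in ITEMS])
    return out


def to_long(panel: pd.DataFrame, wave_years: Iterable[int]) -> pd.DataFrame:
    """One row per (individual, wave) with unsuffixed variable columns."""
    years = tuple(wave_years)
    per_wave = ["age", "alive"] + [
        v for v in (*OUTCOMES, "adl_score", "iadl_score", *ITEMS, *RISK_FACTORS)
        if col(v, years[0]) in panel.columns or col(v, years[-1]) in panel.columns
    ]
    rows = []
    for y in years:
        cols = {v: col(v, y) for v in per_wave if col(v, y) in panel.columns}
        chunk = panel[list(ID_COLS) + list(cols.values())].copy()
        chunk.columns = list(ID_COLS) + list(cols)
        chunk.insert(len(ID_COLS), "year", y)
        rows.append(chunk)
    return pd.concat(rows, ignore_index=True)
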