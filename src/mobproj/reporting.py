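"""Monte-Carlo summaries of the bootstrap ensemble.

Point estimates are replicate averages, predictive variances are replicate
variances, and 95% credible intervals are 2.5th/97.5th percentiles of the
replicate distribution (a normal approximation, mean +/- 1.96 SD, is
available by flag).  Scenario contrasts are paired within replicate, which
preserves the shared-history correlation between scenarios.  Predictor
selection proportions are reported per outcome, suppressing rows under
10%; forced predictors are flagged (they are selected by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .projection import ResultStore


@dataclass(frozen=True)
class SummaryEstimate:
    """Mean, predictive variance and 95% CrI of one reporting cell."""

    cell: tuple
    mean: float
    variance: float
    cri_low: float
    cri_high: float

    def __post_init__(self):
        if not (self.cri_low <= self.mean <= self.cri_high):
            raise ValueError("credible interval must bracket the mean")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def prevalence(
    panel: pd.DataFrame,
    year: int,
    outcome: str,
    study: str = "ALL",
    min_age: int = 76,
) -> float:
    """Proportion with the limitation among survivors aged >= ``min_age``.

    ``panel`` is long-format (one row per individual-wave with columns
    ``year``, ``study``, ``age``, ``alive`` and the outcome).
    """
    sub = panel[(panel["year"] == year) & (panel["alive"] == 1)]
    if study != "ALL":
        sub = sub[sub["study"] == study]
    sub = sub[sub["age"] >= min_age]
    if len(sub) == 0:
        raise ValueError(
            f"empty denominator: year={year}, study={study}, min_age={min_age}"
        )
    return float(sub[outcome].mean())


def _summaries(values: np.ndarray, cell, normal_approx: bool) -> SummaryEstimate:
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    if normal_approx:
        half = 1.96 * np.sqrt(var)
        lo, hi = mean - half, mean + half
    else:
        lo, hi = np.percentile(values, [2.5, 97.5])
    return SummaryEstimate(
        cell=tuple(cell), mean=mean, variance=var,
        cri_low=float(min(lo, mean)), cri_high=float(max(hi, mean)),
    )


def _cell_values(store: ResultStore, cell) -> pd.Series:
    scenario, year, study, outcome = cell
    df = store.prevalence
    sub = df[
        (df["scenario"] == scenario) & (df["year"] == year)
        & (df["study"] == study) & (df["outcome"] == outcome)
    ].sort_values("replicate")
    return sub.set_index("replicate")["prevalence"]


def summarize(store: ResultStore, cell, normal_approx: bool = False) -> SummaryEstimate:
    """Monte-Carlo summary of one (scenario, year, study, outcome) cell."""
    vals = _cell_values(store, cell)
    if len(vals) < 2:
        raise ValueError(f"need >= 2 replicates to summarise {cell}")
    return _summaries(vals.to_numpy(), cell, normal_approx)


def contrast(store: ResultStore, cell_a, cell_b, normal_approx: bool = False) -> SummaryEstimate:
    """Summary of the within-replicate paired difference A - B."""
    va = _cell_values(store, cell_a)
    vb = _cell_values(store, cell_b)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need >= 2 replicates for a contrast")
    if not va.index.equals(vb.index):
        raise ValueError("contrast cells must share replicate indexing")
    diff = (va - vb).to_numpy()
    return _summaries(diff, (cell_a, cell_b), normal_approx)


def summary_table(
    store: ResultStore, normal_approx: bool = False, percent: bool = True
) -> pd.DataFrame:
    """Every (scenario, year, study, outcome) cell summarised, one row each.

    Percentages to one decimal when ``percent``.
    """
    df = store.prevalence
    rows = []
    keys = df[["scenario", "year", "study", "outcome"]].drop_duplicates()
    for _, k in keys.iterrows():
        est = summarize(
            store, (k["scenario"], k["year"], k["study"], k["outcome"]), normal_approx
        )
        scale = 100.0 if percent else 1.0
        rows.append(
            {
                "scenario": k["scenario"], "year": k["year"], "study": k["study"],
                "outcome": k["outcome"],
                "mean": round(est.mean * scale, 1) if percent else est.mean,
                "variance": est.variance * scale**2,
                "cri_low": round(est.cri_low * scale, 1) if percent else est.cri_low,
                "cri_high": round(est.cri_high * scale, 1) if percent else est.cri_high,
            }
        )
    return pd.DataFrame(rows)


def selection_table(
    store: ResultStore,
    targets: list[str] | None = None,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Selection proportions across bootstrap replicates.

    One row per (target, predictor) with the fraction of replicates in
    which the predictor appeared in the target's final model; rows under
    ``threshold`` are suppressed (exactly 10% is retained).  Forced
    predictors appear with ``forced = True`` and proportion 1 by
    construction.
    """
    n_reps = len(store.model_specs)
    if n_reps == 0:
        return pd.DataFrame(columns=["target", "predictor", "proportion", "forced"])
    if targets is None:
        targets = sorted({t for specs in store.model_specs for t in specs})
    rows = []
    for target in targets:
        counts: dict[str, int] = {}
        forced: set[str] = set()
        for specs in store.model_specs:
            spec = specs[target]
            for p in spec.predictors:
                counts[p] = counts.get(p, 0) + 1
            forced |= set(spec.forced)
        for p, c in sorted(counts.items()):
            prop = c / n_reps
            is_forced = p in forced
            if prop < threshold and not is_forced:
                continue
            rows.append(
                {"target": target, "predictor": p, "proportion": prop,
                 "forced": is_forced}
            )
    return pd.DataFrame(rows)


def pooled_identity_check(store: ResultStore, cell) -> tuple[float, float]:
    """Pooled prevalence vs denominator-weighted average of study cells.

    Returns the pair (pooled, weighted-average); they agree exactly, which
    is the invariant the reporting layer relies on.
    """
    scenario, year, _, outcome = cell
    df = store.prevalence
    sub = df[
        (df["scenario"] == scenario) & (df["year"] == year)
        & (df["outcome"] == outcome)
    ]
    pooled = sub[sub["study"] == "ALL"]
    per_study = sub[sub["study"] != "ALL"]
    merged = per_study.groupby("replicate").apply(
        lambda g: np.average(g["prevalence"], weights=g["n"]),
        include_groups=False,
    )
    return (
        float(pooled["prevalence"].mean()),
        float(merged.mean()),
    )
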