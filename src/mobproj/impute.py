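"""Chained-equations imputation with CART conditional models.

Each incomplete variable gets a classification or regression tree fitted
on the rows where it is observed; a row with a missing value is routed to
its terminal node and receives one observed donor value drawn uniformly
from that node.  Imputed values are therefore always observed values of
the same variable in the same dataset (donor closure), which keeps binary
variables binary and scores inside {0,...,6} with no extra bookkeeping.

Predictor pre-selection is also tree-based: a single CART of the target on
its candidate predictors is grown, and the variables appearing in at least
one split form the selected set; the forced predictors (age, sex and
education at the anchor wave) are merged in afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

EDUCATION_CODES = {"low": 0, "medium": 1, "high": 2}


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class CartParams:
    """Tree and chained-loop controls.

    ``min_leaf`` is the minimum number of donors per terminal node;
    ``complexity`` the minimum impurity decrease for a split (the
    conventional CART-MICE defaults); ``n_chained_iters`` the number of
    sweeps of the chained-equations loop.
    """

    min_leaf: int = 5
    complexity: float = 1e-4
    max_depth: int | None = None
    n_chained_iters: int = 5

    def __post_init__(self):
        if self.min_leaf < 2:
            raise ValueError("min_leaf must be >= 2 (a node needs donors)")
        if self.n_chained_iters < 1:
            raise ValueError("n_chained_iters must be >= 1")


@dataclass
class ImputationModelSpec:
    """Predictor set of one imputation model (one target variable)."""

    target: str
    candidates: tuple[str, ...] = ()
    selected: tuple[str, ...] = ()
    forced: tuple[str, ...] = ()

    def __post_init__(self):
        if self.target in self.selected:
            raise ValueError(f"{self.target}: target cannot predict itself")

    @property
    def predictors(self) -> tuple[str, ...]:
        extra = tuple(s for s in self.selected if s not in self.forced)
        return self.forced + extra

    def to_json(self) -> str:
        return json.dumps(
            {"target": self.target, "selected": list(self.selected),
             "forced": list(self.forced)}
        )

    @classmethod
    def from_json(cls, s: str) -> "ImputationModelSpec":
        d = json.loads(s)
        return cls(target=d["target"], selected=tuple(d["selected"]),
                   forced=tuple(d["forced"]))


def _encode_column(s: pd.Series, fill: bool) -> np.ndarray:
    """Numeric design column; categoricals get stable integer codes.

    With ``fill`` (selection only), missing numerics take the observed
    median and missing categoricals their own code (-1).  Without it, any
    missing value is a contract violation.
    """
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        if set(s.dropna().unique()) <= set(EDUCATION_CODES):
            x = s.map(EDUCATION_CODES).astype(float)
        else:
            cats = sorted(map(str, s.dropna().unique()))
            x = s.map({c: i for i, c in enumerate(cats)}).astype(float)
    else:
        x = s.astype(float)
    vals = x.to_numpy(dtype=float, copy=True)
    mask = np.isnan(vals)
    if mask.any():
        if not fill:
            raise ImputationError(f"predictor {s.name!r} has missing values")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            vals[mask] = -1.0
        elif mask.all():
            vals[:] = 0.0
        else:
            vals[mask] = np.median(vals[~mask])
    return vals


def _design(data: pd.DataFrame, cols: Sequence[str], fill: bool) -> np.ndarray:
    return np.column_stack([_encode_column(data[c], fill) for c in cols])


def _is_classification(y: pd.Series) -> bool:
    """Binary and nominal targets get classification trees; integer scores
    and age get regression trees (donor draws keep them in-support)."""
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        return True
    vals = np.unique(y.dropna().to_numpy(dtype=float))
    return len(vals) <= 2 and np.isin(vals, (0.0, 1.0)).all()


def _fit_tree(X: np.ndarray, y: pd.Series, params: CartParams):
    y_enc = _encode_column(y, fill=False)
    cls = _is_classification(y)
    Tree = DecisionTreeClassifier if cls else DecisionTreeRegressor
    tree = Tree(
        min_samples_leaf=params.min_leaf,
        min_impurity_decrease=params.complexity,
        max_depth=params.max_depth,
        random_state=0,
    )
    tree.fit(X, y_enc.astype(int) if cls else y_enc)
    return tree


def select_predictors(
    data: pd.DataFrame,
    target: str,
    candidates: Sequence[str],
    forced: Sequence[str],
    params: CartParams,
) -> ImputationModelSpec:
    """Choose predictors for ``target`` with a single selection tree.

    Fitted over rows where the target is observed; candidate missing
    values are handled (during selection only) by missing-as-own-category
    for categoricals and median fill for numerics.  Selected = variables
    appearing in >= 1 split.
    """
    candidates = tuple(c for c in candidates if c != target and c not in forced)
    obs = data[target].notna()
    if not obs.any():
        raise ImputationError(f"target {target!r} is fully missing")
    if not candidates:
        return ImputationModelSpec(target=target, candidates=(),
                                   selected=(), forced=tuple(forced))
    sub = data.loc[obs]
    X = _design(sub, candidates, fill=True)
    tree = _fit_tree(X, sub[target], params)
    used = np.unique(tree.tree_.feature)
    used = used[used >= 0]
    selected = tuple(candidates[i] for i in sorted(used))
    return ImputationModelSpec(
        target=target, candidates=candidates, selected=selected, forced=tuple(forced)
    )


def impute_variable(
    data: pd.DataFrame,
    spec: ImputationModelSpec,
    params: CartParams,
    rng: np.random.Generator,
    fit_mask: pd.Series | None = None,
    impute_mask: pd.Series | None = None,
) -> int:
    """Fill the target's missing cells by CART donor draws, in place.

    ``fit_mask`` restricts the donor/training rows (default: target
    observed); ``impute_mask`` the rows to fill (default: target missing).
    Returns the number of cells imputed.
    """
    target = spec.target
    if fit_mask is None:
        fit_mask = data[target].notna()
    else:
        fit_mask = fit_mask & data[target].notna()
    if impute_mask is None:
        impute_mask = data[target].isna()
    if not impute_mask.any():
        return 0
    if not fit_mask.any():
        raise ImputationError(f"target {target!r}: no donor rows")

    fit = data.loc[fit_mask]
    mis = data.loc[impute_mask]
    y_fit = fit[target].to_numpy()

    predictors = [p for p in spec.predictors if p != target]
    if not predictors:
        picks = rng.integers(0, len(y_fit), size=len(mis))
        data.loc[impute_mask, target] = y_fit[picks]
        return len(mis)

    # one shared encoding for fit and impute rows (stable categorical codes)
    both = pd.concat([fit, mis])
    X_both = _design(both, predictors, fill=False)
    X_fit, X_mis = X_both[: len(fit)], X_both[len(fit):]
    tree = _fit_tree(X_fit, fit[target], params)
    leaves_fit = tree.apply(X_fit)
    leaves_mis = tree.apply(X_mis)

    order = np.argsort(leaves_fit, kind="stable")
    sorted_leaves = leaves_fit[order]
    lo = np.searchsorted(sorted_leaves, leaves_mis, "left")
    hi = np.searchsorted(sorted_leaves, leaves_mis, "right")
    picks = lo + (rng.random(len(mis)) * (hi - lo)).astype(int)
    data.loc[impute_mask, target] = y_fit[order[picks]]
    return len(mis)


def chained_impute(
    data: pd.DataFrame,
    specs: Sequence[ImputationModelSpec],
    params: CartParams,
    rng: np.random.Generator,
    imputable: Mapping[str, pd.Series] | None = None,
    fit_masks: Mapping[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """One complete dataset from chained CART sweeps.

    Missing cells are initialised by uniform draws from each variable's
    observed marginal, then ``n_chained_iters`` sweeps revisit the targets
    in order of increasing missingness fraction, re-imputing each from the
    current completed data.  Multiplicity comes from bootstrap replicates,
    not from repeated imputations here.

    ``imputable`` (column -> boolean mask) limits which missing cells are
    filled; cells missing for structural reasons (e.g. after death) are
    excluded by the caller and are never touched.
    """
    out = data.copy()
    spec_by_target = {s.target: s for s in specs}

    if imputable is None:
        miss_masks = {t: out[t].isna() for t in spec_by_target}
        uncovered = [
            c for c in out.columns
            if c not in spec_by_target and out[c].isna().any()
        ]
        if uncovered:
            raise ImputationError(
                f"variables with missingness but no imputation model: {uncovered}"
            )
    else:
        miss_masks = {
            t: (out[t].isna() & imputable.get(t, out[t].isna() & False))
            for t in spec_by_target
        }
        uncovered = [
            c for c, m in imputable.items()
            if c not in spec_by_target and (out[c].isna() & m).any()
        ]
        if uncovered:
            raise ImputationError(
                f"variables with missingness but no imputation model: {uncovered}"
            )

    targets = [t for t in spec_by_target if miss_masks[t].any()]
    if not targets:
        return out

    # initialise from observed marginals
    obs_masks = {t: out[t].notna() for t in targets}
    if fit_masks:
        for t in targets:
            if t in fit_masks:
                obs_masks[t] = obs_masks[t] & fit_masks[t]
    for t in targets:
        obs_vals = out.loc[obs_masks[t], t].to_numpy()
        if len(obs_vals) == 0:
            raise ImputationError(f"target {t!r} is fully missing")
        n_mis = int(miss_masks[t].sum())
        out.loc[miss_masks[t], t] = obs_vals[rng.integers(0, len(obs_vals), n_mis)]

    # visit order: increasing missingness fraction, ties by column order
    col_order = {c: i for i, c in enumerate(out.columns)}
    targets.sort(key=lambda t: (int(miss_masks[t].sum()), col_order.get(t, 0)))

    for _ in range(params.n_chained_iters):
        for t in targets:
            impute_variable(
                out, spec_by_target[t], params, rng,
                fit_mask=obs_masks[t], impute_mask=miss_masks[t],
            )
    return out
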