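"""Sequential projection engine: bootstrap, observed-data imputation, and
the wave-advancing multiple-imputation loop.

Each bootstrap replicate (Rao-Wu, n - 1 individuals with replacement per
study stratum) gets one chained-equations imputation of the observed
panel, one CART predictor selection for the last-observed-wave variables,
and then a sequence of projection steps.  A step stacks the trailing
seven-wave window of the training block (complete) on the survivors'
window whose newest wave is wholly missing except deterministic age and
constant sex; the selected models, trained on the complete block, impute
the new wave.  The identification assumption is stationarity: variables
change between any two adjacent waves with the same transition law as
over the observed grid, so the same conditional models apply at every
step.  The window width limits the horizon (seven biennial steps from
2012 reach 2026).

Multiplicity in the multiple imputation comes from the 120 bootstrap
replicates: one completed dataset per replicate per scenario, all
scenarios within a replicate sharing the replicate's observed-data
imputation so that scenario contrasts isolate the intervention effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .impute import (
    CartParams,
    ImputationError,
    ImputationModelSpec,
    chained_impute,
    impute_variable,
    select_predictors,
)
from .dataset import attach_scores
from .rng import stream
from .scenario import (
    ScenarioSpec,
    _impute_phase1,
    _impute_phase2,
    anchor_sd,
    scenario_step,
)
from .schema import OUTCOMES, RISK_FACTORS, SCORES, SUBSTANTIVE, SUBSTANTIVE_SCORED, col

#: per-wave variables of the position-labelled window, in column order
WINDOW_VARS = ("age", "alive") + SUBSTANTIVE_SCORED
PHASE1_TARGETS = SCORES + RISK_FACTORS  # everything except outcomes & vital status
PHASE2_TARGETS = OUTCOMES


def pos(var: str, k: int) -> str:
    """Column name of ``var`` at window position ``k`` (1-based)."""
    return f"{var}_p{k}"


@dataclass
class ProjectionFrame:
    """The stacked matrix R_s of one projection step.

    ``data`` holds the training block (``_block`` = 0, complete window)
    stacked on the survivor block (``_block`` = 1) whose newest position
    is missing except age and sex.  ``provenance`` records the order of
    imputation and shift events, so the outcome-after-shift causal order
    is verifiable.
    """

    step: int
    data: pd.DataFrame
    n_positions: int = 7
    provenance: list = field(default_factory=list)

    @property
    def new_wave_pos(self) -> int:
        return self.n_positions

    @property
    def phase1_targets(self) -> list[str]:
        return [pos(v, self.new_wave_pos) for v in PHASE1_TARGETS]

    @property
    def phase2_targets(self) -> list[str]:
        return [pos(v, self.new_wave_pos) for v in PHASE2_TARGETS]

    @property
    def substantive_vars(self) -> tuple[str, ...]:
        return SUBSTANTIVE_SCORED

    def validate(self) -> None:
        T = self.new_wave_pos
        block1 = self.data["_block"] == 1
        if not (self.data.loc[block1, pos("alive", T - 1)] == 1).all():
            raise ValueError("survivor block contains rows dead at the previous wave")
        age_ok = (
            self.data.loc[block1, pos("age", T)]
            == self.data.loc[block1, pos("age", T - 1)] + 2
        ).all()
        if not age_ok:
            raise ValueError("new-wave age must be previous age + 2")
        for v in SUBSTANTIVE_SCORED:
            if not self.data.loc[block1, pos(v, T)].isna().all():
                raise ValueError(f"new wave must be missing before imputation: {v}")


@dataclass(frozen=True)
class ProjectionRun:
    """Specification of a full bootstrap projection run."""

    scenarios: tuple[ScenarioSpec, ...]
    n_bootstrap: int = 120
    horizon_year: int = 2026
    seed: int = 0
    wave_years: tuple[int, ...] = (2000, 2002, 2004, 2006, 2008, 2010, 2012)
    min_age: int = 76

    def __post_init__(self):
        gap = self.horizon_year - self.wave_years[-1]
        if gap <= 0 or gap % 2 != 0:
            raise ValueError(
                "horizon_year must exceed the last observed year by a positive "
                "multiple of 2"
            )
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class ResultStore:
    """Per-replicate prevalence series and imputation-model specs."""

    prevalence: pd.DataFrame  # replicate, scenario, year, study, outcome, prevalence, n
    model_specs: list  # one dict target -> ImputationModelSpec per replicate
    manifest: dict


# ------------------------------------------------------------------ #
# Rao-Wu bootstrap

def rao_wu_resample(dataset: pd.DataFrame, replicate: int, seed: int) -> pd.DataFrame:
    """Draw n - 1 individuals with replacement within each study stratum.

    The m = n - 1 rescaling makes the naive with-replacement bootstrap
    variance consistent under equal-weight simple random sampling.
    Resampled individuals get fresh ids.
    """
    parts = []
    for study, group in dataset.groupby("study", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"stratum {study!r} has fewer than 2 individuals")
        rng = stream(seed, "bootstrap", replicate, study)
        idx = rng.integers(0, n, size=n - 1)
        part = group.iloc[idx].copy()
        part["id"] = [f"{study}-r{replicate}-{i:06d}" for i in range(n - 1)]
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


# ------------------------------------------------------------------ #
# Observed-data imputation (phase a)

def _impute_vital_status(data: pd.DataFrame, years, params, rng) -> pd.DataFrame:
    """Resolve missing vital-status cells before the main chained pass.

    Baseline participants are alive by construction; at later waves a
    missing status is deterministic 0 if already dead, otherwise drawn
    from a CART on the forced demographic predictors.
    """
    out = data.copy()
    forced = ("sex", "education", col("age", years[-1]))
    first = col("alive", years[0])
    out.loc[out[first].isna(), first] = 1.0
    for y_prev, y in zip(years, years[1:]):
        c = col("alive", y)
        miss = out[c].isna()
        if not miss.any():
            continue
        dead_prev = miss & (out[col("alive", y_prev)] == 0)
        out.loc[dead_prev, c] = 0.0
        open_rows = out[c].isna()
        if open_rows.any():
            spec = ImputationModelSpec(target=c, forced=forced)
            fit = (out[col("alive", y_prev)] == 1) & out[c].notna()
            impute_variable(out, spec, params, rng, fit_mask=fit, impute_mask=open_rows)
            newly_dead = open_rows & (out[c] == 0)
            for yy in years[years.index(y):]:
                out.loc[newly_dead & (out[col("alive", yy)] == 0),
                        [col(v, yy) for v in SUBSTANTIVE]] = np.nan
    return out


def observed_specs(
    sample: pd.DataFrame, years, params: CartParams
) -> tuple[list[ImputationModelSpec], dict[str, pd.Series]]:
    """Selection + imputable masks for every incomplete observed cell.

    A cell is imputable if it is missing while the individual is alive at
    that wave; candidate predictors are restricted to the target's wave or
    earlier (plus time-independent variables), which together with
    absorbing mortality guarantees complete tree designs.
    """
    years = tuple(years)
    forced = ("sex", "education", col("age", years[-1]))
    specs: list[ImputationModelSpec] = []
    imputable: dict[str, pd.Series] = {}
    for wi, y in enumerate(years):
        live = sample[col("alive", y)] == 1
        for v in SUBSTANTIVE:
            target = col(v, y)
            mask = sample[target].isna() & live
            if not mask.any():
                continue
            candidates = ["study"] + [
                col(u, yy)
                for yy in years[: wi + 1]
                for u in SUBSTANTIVE
                if col(u, yy) != target
            ]
            specs.append(
                select_predictors(sample, target, candidates, forced, params)
            )
            imputable[target] = mask
    return specs, imputable


def impute_observed(
    sample: pd.DataFrame, years, params: CartParams, rng: np.random.Generator
) -> pd.DataFrame:
    """One completed observed panel (items still at item level)."""
    years = tuple(years)
    work = _impute_vital_status(sample, years, params, rng)
    specs, imputable = observed_specs(work, years, params)
    if not specs:
        return work
    return chained_impute(work, specs, params, rng, imputable=imputable)


# ------------------------------------------------------------------ #
# Position-labelled windows

def position_panel(panel: pd.DataFrame, years) -> pd.DataFrame:
    """Relabel calendar columns to window positions p1..p7."""
    years = tuple(years)
    out = panel[["id", "study", "sex", "education"]].copy()
    for k, y in enumerate(years, start=1):
        for v in WINDOW_VARS:
            out[pos(v, k)] = panel[col(v, y)].to_numpy()
    return out


def anchor_specs(
    train: pd.DataFrame, params: CartParams, n_positions: int = 7
) -> dict[str, ImputationModelSpec]:
    """CART predictor selection for the newest-position variables.

    Trained on the complete block; phase-1 targets exclude the
    contemporaneous outcomes and vital status from their candidates
    (they are imputed later within a step), and vital status is never a
    candidate (constant among rows alive at the new wave).
    """
    T = n_positions
    forced = (pos("age", T), "sex", "education")
    base_candidates = ["study"] + [
        pos(v, k) for k in range(1, T + 1) for v in SUBSTANTIVE_SCORED
    ]
    specs: dict[str, ImputationModelSpec] = {}
    alive_T = train[pos("alive", T)] == 1
    for v in PHASE1_TARGETS:
        target = pos(v, T)
        cands = [
            c for c in base_candidates
            if c != target and c not in (pos(o, T) for o in OUTCOMES)
        ]
        specs[target] = select_predictors(
            train.loc[alive_T], target, cands, forced, params
        )
    for v in PHASE2_TARGETS:
        target = pos(v, T)
        cands = [c for c in base_candidates if c != target]
        specs[target] = select_predictors(
            train.loc[alive_T], target, cands, forced, params
        )
    # vital status: a discrete-time hazard on the trailing waves.  Rows that
    # die at the new wave have no substantive values there, so the mortality
    # model can only condition on lagged history (plus deterministic age).
    alive_target = pos("alive", T)
    lagged = ["study"] + [
        pos(v, k) for k in range(1, T) for v in SUBSTANTIVE_SCORED
    ]
    prev_alive = train[pos("alive", T - 1)] == 1
    specs[alive_target] = select_predictors(
        train.loc[prev_alive], alive_target, lagged, forced, params
    )
    return specs


def make_frame(train: pd.DataFrame, step: int, n_positions: int = 7) -> ProjectionFrame:
    """Build R_s: training block stacked on the shifted survivor block."""
    T = n_positions
    cur = train.loc[train[pos("alive", T)] == 1].copy()
    # slide the window: position k+1 becomes position k
    drop = [pos(v, 1) for v in WINDOW_VARS]
    cur = cur.drop(columns=drop)
    rename = {
        pos(v, k + 1): pos(v, k) for v in WINDOW_VARS for k in range(1, T)
    }
    cur = cur.rename(columns=rename)
    cur[pos("age", T)] = cur[pos("age", T - 1)] + 2
    cur[pos("alive", T)] = np.nan
    for v in SUBSTANTIVE_SCORED:
        cur[pos(v, T)] = np.nan
    cur = cur[train.columns]
    frame = ProjectionFrame(
        step=step,
        data=pd.concat(
            [train.assign(_block=0), cur.assign(_block=1)], ignore_index=True
        ),
        n_positions=T,
    )
    frame.validate()
    return frame


def extract_new_block(frame: ProjectionFrame) -> pd.DataFrame:
    """Completed survivor block of a step (the next step's training block)."""
    out = frame.data.loc[frame.data["_block"] == 1].drop(columns="_block")
    return out.reset_index(drop=True)


# ------------------------------------------------------------------ #
# Replicate-level orchestration

def _step_rngs(seed: int, replicate: int, step: int) -> dict:
    """Scenario-independent streams, so shared-seed scenarios stay paired."""
    return {
        "phase1": stream(seed, "proj", replicate, step, "phase1"),
        "phase2": stream(seed, "proj", replicate, step, "phase2"),
        "vital": stream(seed, "proj", replicate, step, "vital"),
        "shift:iadl_score": stream(seed, "shift", replicate, "iadl_score"),
        "shift:adl_score": stream(seed, "shift", replicate, "adl_score"),
    }


def prepare_replicate(
    sample: pd.DataFrame,
    years,
    params: CartParams,
    seed: int,
    replicate: int = 0,
):
    """Observed-data imputation, score derivation, anchor selection, SDs.

    Shared by all scenarios of one replicate.
    """
    years = tuple(years)
    rng = stream(seed, "obs-mice", replicate)
    completed = impute_observed(sample, years, params, rng)
    scored = attach_scores(completed, years)
    anchor_sds = {
        (study, score): anchor_sd(scored, study, score, years[0])
        for study in sorted(scored["study"].unique())
        for score in SCORES
    }
    train = position_panel(scored, years)
    specs = anchor_specs(train, params, n_positions=len(years))
    return scored, train, specs, anchor_sds


def project_steps(
    train: pd.DataFrame,
    specs: Mapping[str, ImputationModelSpec],
    scenario: ScenarioSpec,
    anchor_sds: Mapping,
    n_steps: int,
    params: CartParams,
    seed: int,
    replicate: int = 0,
    n_positions: int = 7,
) -> list[pd.DataFrame]:
    """Run the sequential steps under one scenario.

    Returns the completed survivor block of every step (newest position =
    projected wave).  The scenario operates at step 1 only; later steps
    impute with no modification under every scenario.
    """
    blocks = []
    for s in range(1, n_steps + 1):
        frame = make_frame(train, step=s, n_positions=n_positions)
        rngs = _step_rngs(seed, replicate, s)
        if s == 1:
            scenario_step(frame, scenario, specs, params, anchor_sds, rngs)
        else:
            _impute_phase1(frame, specs, params, rngs["phase1"])
            _impute_phase2(frame, specs, params, rngs["phase2"], rngs["vital"])
        new = extract_new_block(frame)
        blocks.append(new)
        train = new
    return blocks


def project_replicate(
    sample: pd.DataFrame,
    scenario: ScenarioSpec,
    horizon_year: int,
    params: CartParams,
    seed: int,
    years=(2000, 2002, 2004, 2006, 2008, 2010, 2012),
    replicate: int = 0,
):
    """Full single-replicate trajectory under one scenario.

    Returns (scored observed panel, list of per-step survivor blocks).
    With horizon_year equal to the last observed year no steps are run.
    """
    years = tuple(years)
    gap = horizon_year - years[-1]
    if gap < 0 or gap % 2 != 0:
        raise ValueError("horizon must be reachable by biennial steps")
    scored, train, specs, anchor_sds = prepare_replicate(
        sample, years, params, seed, replicate
    )
    blocks = project_steps(
        train, specs, scenario, anchor_sds, gap // 2, params, seed, replicate,
        n_positions=len(years),
    )
    return scored, blocks


# ------------------------------------------------------------------ #
# Full bootstrap run

def _prevalence_rows(df, year, min_age, age_col, alive_col, out_cols, rows_meta):
    recs = []
    live = df[df[alive_col] == 1]
    live = live[live[age_col] >= min_age]
    for study in ["ALL"] + sorted(df["study"].unique()):
        sub = live if study == "ALL" else live[live["study"] == study]
        if len(sub) == 0:
            raise ValueError(
                f"empty denominator: study={study}, year={year}, min_age={min_age}"
            )
        for outcome, c in out_cols.items():
            recs.append(
                {**rows_meta, "year": year, "study": study, "outcome": outcome,
                 "prevalence": float(sub[c].mean()), "n": len(sub)}
            )
    return recs


def run(
    dataset: pd.DataFrame,
    run_spec: ProjectionRun,
    params: CartParams | None = None,
    out_dir=None,
) -> ResultStore:
    """Bootstrap the full pipeline and collect prevalence series.

    For each replicate: resample, impute the observed data once, then
    project under every scenario from a scenario-copied step-1 frame.
    A failed replicate aborts the run with the replicate index attached.
    ``out_dir`` optionally persists per-(replicate, scenario) trajectories
    as CSV.
    """
    params = params or CartParams()
    years = run_spec.wave_years
    n_steps = (run_spec.horizon_year - years[-1]) // 2
    T = len(years)
    recs = []
    all_specs = []
    for r in range(run_spec.n_bootstrap):
        try:
            sample = rao_wu_resample(dataset, r, run_spec.seed)
            scored, train, specs, anchor_sds = prepare_replicate(
                sample, years, params, run_spec.seed, r
            )
            all_specs.append(specs)
            obs_recs = []
            for y in years:
                obs_recs += _prevalence_rows(
                    scored, y, run_spec.min_age, col("age", y), col("alive", y),
                    {o: col(o, y) for o in OUTCOMES}, {"replicate": r},
                )
            for scen in run_spec.scenarios:
                for rec in obs_recs:
                    recs.append({**rec, "scenario": scen.id})
                blocks = project_steps(
                    train, specs, scen, anchor_sds, n_steps, params,
                    run_spec.seed, r, n_positions=T,
                )
                for s, block in enumerate(blocks, start=1):
                    year = years[-1] + 2 * s
                    recs += _prevalence_rows(
                        block, year, run_spec.min_age, pos("age", T),
                        pos("alive", T), {o: pos(o, T) for o in OUTCOMES},
                        {"replicate": r, "scenario": scen.id},
                    )
                if out_dir is not None:
                    path = Path(out_dir)
                    path.mkdir(parents=True, exist_ok=True)
                    traj = pd.concat(
                        [b.assign(_step=i + 1) for i, b in enumerate(blocks)],
                        ignore_index=True,
                    )
                    traj.to_csv(
                        path / f"trajectories_rep{r:03d}_scen{scen.id}.csv",
                        index=False,
                    )
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc

    prevalence = pd.DataFrame.from_records(recs)[
        ["replicate", "scenario", "year", "study", "outcome", "prevalence", "n"]
    ]
    manifest = {
        "seed": run_spec.seed,
        "n_bootstrap": run_spec.n_bootstrap,
        "horizon_year": run_spec.horizon_year,
        "scenarios": [s.id for s in run_spec.scenarios],
        "min_age": run_spec.min_age,
        "wave_years": list(years),
        "params": {
            "min_leaf": params.min_leaf,
            "complexity": params.complexity,
            "max_depth": params.max_depth,
            "n_chained_iters": params.n_chained_iters,
        },
    }
    return ResultStore(prevalence=prevalence, model_specs=all_specs, manifest=manifest)
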