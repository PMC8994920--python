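"""Rao-Wu resampling and the sequential projection machinery."""

import numpy as np
import pandas as pd
import pytest

import mobproj as m
from mobproj.projection import (
    ProjectionRun,
    make_frame,
    pos,
    position_panel,
    prepare_replicate,
    project_replicate,
    project_steps,
    rao_wu_resample,
    _step_rngs,
)
from mobproj.schema import col

from conftest import two_state_config

PARAMS = m.CartParams(n_chained_iters=2)


def _stratum(n, study="A", seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "id": [f"{study}-{i}" for i in range(n)],
        "study": study,
        "x": rng.normal(size=n),
    })


# ------------------------------------------------------------------ #
# Rao-Wu bootstrap

def test_rao_wu_smallest_stratum():
    ds = _stratum(2)
    out = rao_wu_resample(ds, replicate=0, seed=1)
    assert len(out) == 1
    assert out["x"].iloc[0] in set(ds["x"])
    with pytest.raises(ValueError, match="fewer than 2"):
        rao_wu_resample(_stratum(1), 0, 1)


def test_rao_wu_resamples_within_strata_with_fresh_ids():
    ds = pd.concat([_stratum(10, "A"), _stratum(7, "B", seed=3)], ignore_index=True)
    out = rao_wu_resample(ds, replicate=2, seed=5)
    assert out["study"].value_counts().to_dict() == {"A": 9, "B": 6}
    assert out["id"].is_unique
    a_vals = set(ds.loc[ds["study"] == "A", "x"])
    assert set(out.loc[out["study"] == "A", "x"]) <= a_vals


def test_rao_wu_expected_multiplicity():
    """Each individual is drawn (n-1)/n = 0.9 times on average at n = 10."""
    ds = _stratum(10)
    target = ds["x"].iloc[0]
    n_reps = 3000
    counts = np.array([
        (rao_wu_resample(ds, r, seed=11)["x"] == target).sum()
        for r in range(n_reps)
    ])
    se = np.sqrt(9 * 0.1 * 0.9 / n_reps)
    assert abs(counts.mean() - 0.9) < 4 * se


def test_rao_wu_variance_matches_srs_closed_form():
    """Var of the bootstrap stratum mean ~ s^2/n for an equal-weight SRS."""
    ds = _stratum(10, seed=7)
    n_reps = 6000
    means = np.array([
        rao_wu_resample(ds, r, seed=13)["x"].mean() for r in range(n_reps)
    ])
    expected = ds["x"].var(ddof=1) / len(ds)
    assert abs(means.var(ddof=1) / expected - 1) < 0.05


# ------------------------------------------------------------------ #
# frames and steps

@pytest.fixture(scope="module")
def markov_prep():
    cfg = two_state_config(n=900, seed=29)
    sample = m.generate_cohort(cfg)
    return cfg, prepare_replicate(sample, cfg.wave_years, PARAMS, seed=29)


def test_window_spans_seven_waves(markov_prep):
    cfg, (scored, train, specs, anchor_sds) = markov_prep
    frame = make_frame(train, step=1)
    for k in range(1, 8):
        assert pos("climb", k) in frame.data.columns
    assert pos("climb", 8) not in frame.data.columns


def test_frame_invariants_before_imputation(markov_prep):
    cfg, (scored, train, specs, anchor_sds) = markov_prep
    frame = make_frame(train, step=1)
    frame.validate()
    block1 = frame.data["_block"] == 1
    assert (
        frame.data.loc[block1, pos("age", 7)]
        == frame.data.loc[block1, pos("age", 6)] + 2
    ).all()
    assert frame.data.loc[block1, pos("iadl_score", 7)].isna().all()


def test_zero_step_projection_returns_observed_panel():
    cfg = two_state_config(n=300, seed=31)
    sample = m.generate_cohort(cfg)
    scored, blocks = project_replicate(
        sample, m.scenario_0(), horizon_year=2012, params=PARAMS, seed=31
    )
    assert blocks == []
    assert scored[col("climb", 2012)].notna().sum() == (scored[col("alive", 2012)] == 1).sum()
    with pytest.raises(ValueError, match="biennial"):
        project_replicate(sample, m.scenario_0(), 2013, PARAMS, seed=31)


def test_dead_individuals_never_enter_frames():
    cfg = two_state_config(n=400, seed=37, mortality_coefs=m.MortalityCoefs(
        intercept=-2.2, age=0.0, state={"good": 0.0, "limited": 0.7}
    ))
    sample = m.generate_cohort(cfg)
    scored, train, specs, anchor_sds = prepare_replicate(
        sample, cfg.wave_years, PARAMS, seed=37
    )
    dead_ids = set(scored.loc[scored[col("alive", 2012)] == 0, "id"])
    assert dead_ids, "mortality config must actually kill someone"
    frame = make_frame(train, step=1)
    block1_ids = set(frame.data.loc[frame.data["_block"] == 1, "id"])
    assert not (dead_ids & block1_ids)


def test_survivor_chain_and_age_floor():
    cfg = two_state_config(n=500, seed=41, mortality_coefs=m.MortalityCoefs(
        intercept=-3.0, age=0.0, state={"good": 0.0, "limited": 0.5}
    ))
    sample = m.generate_cohort(cfg)
    scored, train, specs, anchor_sds = prepare_replicate(
        sample, cfg.wave_years, PARAMS, seed=41
    )
    blocks = project_steps(
        train, specs, m.scenario_0(), anchor_sds, n_steps=3,
        params=PARAMS, seed=41,
    )
    prev_alive_ids = None
    for s, block in enumerate(blocks, start=1):
        if prev_alive_ids is not None:
            assert set(block["id"]) <= prev_alive_ids
        prev_alive_ids = set(block.loc[block[pos("alive", 7)] == 1, "id"])
        min_base = cfg.baseline_age_range[0]
        assert block[pos("age", 7)].min() >= min_base + 2 * (6 + s)
        dead = block[pos("alive", 7)] == 0
        assert block.loc[dead, pos("climb", 7)].isna().all()


def test_scenarios_share_observed_history():
    cfg = two_state_config(n=350, seed=43)
    raw = m.generate_cohort(cfg)
    ds = m.assemble(raw, {"HRS": m.StudyRules(first_wave=2000)},
                    cfg.wave_years, seed=43)
    spec = ProjectionRun(
        scenarios=(m.scenario_0(), m.scenario_1()),
        n_bootstrap=1, horizon_year=2014, seed=43, min_age=0,
    )
    store = m.run(ds, spec, PARAMS)
    obs = store.prevalence[store.prevalence["year"] <= 2012]
    wide = obs.pivot_table(
        index=["year", "study", "outcome"], columns="scenario",
        values="prevalence",
    )
    assert (wide[0] == wide[1]).all(), "observed waves are shared across scenarios"


def test_run_is_deterministic_under_seed():
    cfg = two_state_config(n=250, seed=47)
    raw = m.generate_cohort(cfg)
    ds = m.assemble(raw, {"HRS": m.StudyRules(first_wave=2000)},
                    cfg.wave_years, seed=47)
    spec = ProjectionRun(scenarios=(m.scenario_0(),), n_bootstrap=2,
                         horizon_year=2014, seed=47, min_age=0)
    a = m.run(ds, spec, PARAMS)
    b = m.run(ds, spec, PARAMS)
    pd.testing.assert_frame_equal(a.prevalence, b.prevalence)
    assert a.manifest == b.manifest


def test_bootstrap_sd_comparable_to_binomial_se():
    """Between-replicate SD of a baseline prevalence tracks the binomial SE."""
    cfg = two_state_config(n=2000, seed=53, outcome_is_state=False)
    raw = m.generate_cohort(cfg)
    ds = m.assemble(raw, {"HRS": m.StudyRules(first_wave=2000)},
                    cfg.wave_years, seed=53)
    spec = ProjectionRun(scenarios=(m.scenario_0(),), n_bootstrap=30,
                         horizon_year=2014, seed=53, min_age=0)
    store = m.run(ds, spec, PARAMS)
    cell = store.prevalence
    base = cell[(cell["year"] == 2000) & (cell["study"] == "ALL")
                & (cell["outcome"] == "climb")]["prevalence"]
    p = base.mean()
    analytic_se = np.sqrt(p * (1 - p) / len(ds))
    ratio = base.std(ddof=1) / analytic_se
    assert 0.7 < ratio < 1.3


def test_projection_run_contracts():
    with pytest.raises(ValueError, match="positive"):
        ProjectionRun(scenarios=(m.scenario_0(),), horizon_year=2012)
    with pytest.raises(ValueError, match="multiple of 2"):
        ProjectionRun(scenarios=(m.scenario_0(),), horizon_year=2015)
    with pytest.raises(ValueError, match="n_bootstrap"):
        ProjectionRun(scenarios=(m.scenario_0(),), horizon_year=2026, n_bootstrap=0)
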