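"""The SMD shift operator and the two-phase scenario step."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import mobproj as m
from mobproj.projection import _step_rngs, make_frame, pos, prepare_replicate
from mobproj.rng import stream
from mobproj.schema import ADL_ITEMS, IADL_ITEMS

from conftest import two_state_config

PARAMS = m.CartParams(n_chained_iters=2)


def planted_config(n=800, seed=0, adl_constant=True):
    """Two-state world where the IADL score is a perfect outcome predictor.

    ``good`` individuals answer every IADL item with "no difficulty"
    (score 6) and have no limitation; ``limited`` individuals score 0 and
    have the limitation.  ADL items are constant when ``adl_constant``,
    so the ADL baseline SD degenerates to 0.  Most individuals report no
    vigorous physical activity, hence are intervention-eligible.
    """
    item_probs = {
        "good": {v: 1.0 for v in (*ADL_ITEMS, *IADL_ITEMS)},
        "limited": {
            **{v: 1.0 if adl_constant else 0.0 for v in ADL_ITEMS},
            **{v: 0.0 for v in IADL_ITEMS},
        },
    }
    rf = {k: m.RiskFactorDynamics(0.0, 1.0, 0.0) for k in
          ("smoker", "obese", "alcohol", "hypertension")}
    rf["vpa"] = m.RiskFactorDynamics(0.10, 0.85, 0.05)
    return two_state_config(
        n=n, seed=seed, transition=((0.85, 0.15), (0.35, 0.65)),
        baseline=(0.8, 0.2), item_probs=item_probs, risk_factor_probs=rf,
    )


@pytest.fixture(scope="module")
def prepared():
    cfg = planted_config()
    sample = m.generate_cohort(cfg)
    scored, train, specs, anchor_sds = prepare_replicate(
        sample, cfg.wave_years, PARAMS, seed=17
    )
    return cfg, train, specs, anchor_sds


def _run_step(prepared, scenario, seed=17):
    _, train, specs, anchor_sds = prepared
    frame = make_frame(train, step=1)
    rngs = _step_rngs(seed, 0, 1)
    return m.scenario_step(frame, scenario, specs, PARAMS, anchor_sds, rngs)


# ------------------------------------------------------------------ #
# anchor SD

def test_anchor_sd_closed_forms():
    df = pd.DataFrame({
        "study": ["A"] * 4 + ["B"] * 2 + ["C"],
        "iadl_score_2000": [3.0, 3.0, 3.0, 3.0, 0.0, 6.0, 2.0],
    })
    assert m.anchor_sd(df, "A", "iadl_score") == 0.0
    assert m.anchor_sd(df, "B", "iadl_score") == pytest.approx(3 * np.sqrt(2))
    with pytest.raises(ValueError, match="fewer than 2"):
        m.anchor_sd(df, "C", "iadl_score")


def test_anchor_sd_matches_two_pass_oracle():
    rng = stream(0, "sd")
    vals = rng.integers(0, 7, 500).astype(float)
    df = pd.DataFrame({"study": "A", "adl_score_2000": vals})
    mean = vals.sum() / len(vals)
    two_pass = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
    assert m.anchor_sd(df, "A", "adl_score") == pytest.approx(two_pass)


# ------------------------------------------------------------------ #
# shift operator

def test_shift_noop_when_nobody_eligible():
    scores = np.array([1.0, 3.0, 5.0])
    out = m.apply_shift(scores, np.zeros(3, bool), 1.12, 2.0, stream(1, "s"))
    np.testing.assert_array_equal(out, scores)


def test_shift_degenerate_sd_is_identity():
    scores = np.array([0.0, 2.0, 6.0])
    out = m.apply_shift(scores, np.ones(3, bool), 1.12, 0.0, stream(2, "s"))
    np.testing.assert_array_equal(out, scores)
    with pytest.raises(ValueError, match="non-negative"):
        m.apply_shift(scores, np.ones(3, bool), 1.12, -1.0, stream(2, "s"))


def test_shift_truncation_bounds():
    rng = stream(3, "s")
    scores = rng.integers(0, 7, 50_000).astype(float)
    out = m.apply_shift(scores, np.ones_like(scores, bool), 1.12, 2.4, rng)
    assert out.min() >= 0.0 and out.max() <= 6.0


def test_shift_recovers_smd_pre_truncation():
    n, sd, smd = 20_000, 1.0, 1.12
    scores = np.full(n, 3.0)
    out = m.apply_shift(scores, np.ones(n, bool), smd, sd, stream(4, "s"),
                        truncate=False)
    d = (out.mean() - 3.0) / sd
    assert abs(d - smd) < 4 / np.sqrt(n)


def test_shift_beneficial_direction_in_expectation():
    rng = stream(5, "s")
    scores = rng.binomial(6, 0.6, 10_000).astype(float)
    out = m.apply_shift(scores, np.ones_like(scores, bool), 1.12, 1.5, rng)
    assert out.mean() > scores.mean()


# ------------------------------------------------------------------ #
# the two-phase step

def test_scenario_spec_contracts():
    with pytest.raises(ValueError, match="scenario 0 iff"):
        m.ScenarioSpec(id=0, targets=("iadl_score",))
    with pytest.raises(ValueError, match="scenario 0 iff"):
        m.ScenarioSpec(id=1)
    with pytest.raises(ValueError, match="finite"):
        m.ScenarioSpec(id=1, smd=np.inf, targets=("iadl_score",))


def test_null_intervention_equals_scenario_zero(prepared):
    f0 = _run_step(prepared, m.scenario_0())
    f1 = _run_step(prepared, m.ScenarioSpec(id=1, smd=0.0, targets=("iadl_score",)))
    pd.testing.assert_frame_equal(f0.data, f1.data)


def test_outcomes_imputed_strictly_after_shift(prepared):
    frame = _run_step(prepared, m.scenario_1())
    events = frame.provenance
    shift_at = events.index(("shift", "iadl_score"))
    for out in ("climb_p7", "walk_p7", "alive_p7"):
        assert events.index(("impute", out)) > shift_at
    phase1 = [e for e in events[:shift_at] if e[0] == "impute"]
    assert len(phase1) == 7, "all non-outcome variables imputed before the shift"


def test_scenario2_with_degenerate_adl_sd(prepared):
    cfg, train, specs, anchor_sds = prepared
    assert anchor_sds[("HRS", "adl_score")] == 0.0
    f0 = _run_step(prepared, m.scenario_0())
    f2 = _run_step(prepared, m.scenario_2())
    block1 = f2.data["_block"] == 1
    pd.testing.assert_series_equal(
        f2.data.loc[block1, pos("adl_score", 7)],
        f0.data.loc[block1, pos("adl_score", 7)],
    )
    # IADL scores are modified for eligible rows (ceiling rows may clip
    # back to exactly 6), and never for ineligible rows
    eligible = block1 & (f2.data[pos("vpa", 7)] == 0)
    changed = f2.data[pos("iadl_score", 7)] != f0.data[pos("iadl_score", 7)]
    assert changed[eligible].mean() > 0.1
    assert not changed[block1 & ~eligible.reindex(block1.index, fill_value=False)].any()
    # a floor score stays at 0 only when its draw lands below 0 and clips
    # back, which happens with probability Phi(-smd)
    low_before = eligible & (f0.data[pos("iadl_score", 7)] == 0)
    p_move = norm.cdf(1.12)
    se = np.sqrt(p_move * (1 - p_move) / low_before.sum())
    assert abs(changed[low_before].mean() - p_move) < 4 * se


def test_scenario1_shifts_are_subset_of_scenario2():
    cfg = planted_config(adl_constant=False, seed=4)
    sample = m.generate_cohort(cfg)
    _, train, specs, anchor_sds = prepare_replicate(
        sample, cfg.wave_years, PARAMS, seed=23
    )
    prep = (cfg, train, specs, anchor_sds)
    f1 = _run_step(prep, m.scenario_1(), seed=23)
    f2 = _run_step(prep, m.scenario_2(), seed=23)
    pd.testing.assert_series_equal(
        f1.data[pos("iadl_score", 7)], f2.data[pos("iadl_score", 7)]
    )


def test_step_mismatch_rejected(prepared):
    _, train, specs, anchor_sds = prepared
    frame = make_frame(train, step=2)
    with pytest.raises(ValueError, match="step-1"):
        m.scenario_step(frame, m.scenario_0(), specs, PARAMS, anchor_sds,
                        _step_rngs(17, 0, 2))


def test_planted_step_link_gap_matches_normal_integral(prepared):
    """Outcome = 1(score < 3) planted; the scenario-1 prevalence equals the
    normal-CDF integral of the step link over the shifted score law."""
    cfg, train, specs, anchor_sds = prepared
    f0 = _run_step(prepared, m.scenario_0())
    f1 = _run_step(prepared, m.scenario_1())
    block1 = f1.data["_block"] == 1
    pre = f0.data.loc[block1, pos("iadl_score", 7)].to_numpy()
    eligible = (f0.data.loc[block1, pos("vpa", 7)] == 0).to_numpy()
    sd = anchor_sds[("HRS", "iadl_score")]
    smd = 1.12

    prev0 = f0.data.loc[block1, pos("climb", 7)].mean()
    assert prev0 == pytest.approx((pre < 3).mean())

    p_lim = np.where(
        eligible, norm.cdf((3 - pre - smd * sd) / sd), (pre < 3).astype(float)
    )
    expected = p_lim.mean()
    prev1 = f1.data.loc[block1, pos("climb", 7)].mean()
    se = np.sqrt((p_lim * (1 - p_lim)).sum()) / len(p_lim)
    assert abs(prev1 - expected) < 4 * se
    assert prev1 < prev0, "the intervention lowers projected prevalence"
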