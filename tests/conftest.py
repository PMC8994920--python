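"""Shared fixtures: small synthetic cohorts and a tiny full pipeline run."""

from __future__ import annotations

import pandas as pd
import pytest

import mobproj as m
from mobproj.config import MortalityCoefs, MissingnessConfig
from mobproj.projection import ProjectionRun
from mobproj.schema import ITEMS, OUTCOMES, RISK_FACTORS, col

NO_DEATH = MortalityCoefs(intercept=-1000.0, age=0.0,
                          state={"good": 0.0, "limited": 0.0, "severe": 0.0})


def two_state_config(n=1000, seed=0, *, transition=((0.9, 0.1), (0.3, 0.7)),
                     baseline=(0.8, 0.2), outcome_is_state=True, **overrides):
    """Minimal two-state chain where the stair-climbing outcome equals the
    latent state: a directly observable first-order Markov binary outcome."""
    # walk is constant so the two outcomes are not mutually perfect
    # contemporaneous predictors (which would make selection circular)
    p_out = {"good": {"climb": (0.0,), "walk": (0.0,)},
             "limited": {"climb": (1.0,), "walk": (0.0,)}}
    if not outcome_is_state:
        p_out = {"good": {"climb": (0.1,), "walk": (0.05,)},
                 "limited": {"climb": (0.6,), "walk": (0.4,)}}
    defaults = dict(
        n_per_study={"HRS": n},
        latent_states=("good", "limited"),
        latent_baseline=baseline,
        latent_transition=transition,
        item_probs={"good": 1.0, "limited": 1.0},
        outcome_probs=p_out,
        age_band_edges=(),
        risk_factor_probs={
            rf: m.RiskFactorDynamics(0.0, 1.0, 0.0) for rf in RISK_FACTORS
        },
        mortality_coefs=MortalityCoefs(
            intercept=-1000.0, age=0.0, state={"good": 0.0, "limited": 0.0}
        ),
        missingness=MissingnessConfig(0.0, 0.0, ()),
        seed=seed,
    )
    defaults.update(overrides)
    return m.CohortConfig(**defaults)


def toy_raw(n=4, study="HRS", ages=None, years=(2000, 2002, 2004, 2006, 2008, 2010, 2012)):
    """Hand-built complete raw table for assembly edge cases."""
    ages = ages if ages is not None else [55] * n
    data = {
        "id": [f"{study}-{i}" for i in range(n)],
        "study": study,
        "sex": [i % 2 for i in range(n)],
        "education": ["low", "medium", "high", "low"] * (n // 4 + 1),
    }
    data["education"] = data["education"][:n]
    for w, y in enumerate(years):
        data[col("age", y)] = [a + 2 * w for a in ages]
        data[col("alive", y)] = 1
        for v in OUTCOMES:
            data[col(v, y)] = 0.0
        for v in ITEMS:
            data[col(v, y)] = 1.0
        for v in RISK_FACTORS:
            data[col(v, y)] = 0.0
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced n, with its config."""
    cfg = m.default_config({"HRS": 350, "ELSA": 350, "H2000": 220}, seed=11)
    table = m.generate_cohort(cfg)
    return cfg, table


@pytest.fixture(scope="session")
def tiny_store():
    """A small but complete bootstrap run over two studies."""
    cfg = m.default_config(
        {"HRS": 190, "ELSA": 190, "H2000": 150}, seed=5
    )
    raw = m.inject_missingness(m.generate_cohort(cfg), cfg)
    ds = m.assemble(raw, m.default_rules(cfg.wave_years), cfg.wave_years, seed=5)
    run_spec = ProjectionRun(
        scenarios=(m.scenario_0(), m.scenario_1()),
        n_bootstrap=3, horizon_year=2016, seed=5, min_age=70,
    )
    params = m.CartParams(n_chained_iters=2)
    store = m.run(ds, run_spec, params)
    return store
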