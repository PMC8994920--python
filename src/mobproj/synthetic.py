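"""Synthetic three-study cohort generator and its analytic oracles.

Individuals move through a latent disability process (a first-order Markov
chain over ``good``/``limited``/``severe`` by default).  Given the latent
state, ADL/IADL item responses, the two mobility-limitation outcomes and
per-wave mortality are drawn conditionally; binary risk factors follow
their own first-order transitions.  Death is absorbing: from the death
wave onwards every substantive variable is missing, while age (which is
deterministic) and vital status remain recorded, as in register-linked
survey data.

Because the latent process has closed-form marginals, the generator comes
with :func:`analytic_prevalence`, an exact forward-recursion oracle used
as the recovery target for the projection machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .rng import stream
from .schema import ITEMS, OUTCOMES, RISK_FACTORS, SUBSTANTIVE, col


def _sigmoid(x):
    # clipped to keep exp finite for extreme log-odds (e.g. zero-hazard configs)
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


def generate_cohort(config: CohortConfig, return_latent: bool = False):
    """Draw a complete (pre-missingness) cohort table.

    Returns a wide :class:`~pandas.DataFrame` with one row per individual,
    and optionally the latent-state array (n x waves, -1 after death) for
    oracle-based tests.
    """
    config.validate()
    years = config.wave_years
    n_waves = len(years)
    states = config.latent_states
    trans = np.asarray(config.latent_transition, dtype=float)
    base = np.asarray(config.latent_baseline, dtype=float)
    death_state_coef = np.asarray(
        [config.mortality_coefs.state[s] for s in states], dtype=float
    )

    frames = []
    latents = []
    for study, n in config.n_per_study.items():
        rng = stream(config.seed, "generate", study)
        base_age = rng.integers(
            config.baseline_age_range[0], config.baseline_age_range[1] + 1, size=n
        )
        sex = (rng.random(n) < config.female_prob).astype(int)  # 1 = female
        education = rng.choice(
            np.array(["low", "medium", "high"]), size=n, p=config.education_probs
        )

        latent = np.full((n, n_waves), -1, dtype=int)
        alive = np.zeros((n, n_waves), dtype=int)
        latent[:, 0] = rng.choice(len(states), size=n, p=base)
        alive[:, 0] = 1
        cum_trans = np.cumsum(trans, axis=1)
        for w in range(1, n_waves):
            prev_alive = alive[:, w - 1] == 1
            u = rng.random(n)
            new_state = np.full(n, -1, dtype=int)
            idx = np.where(prev_alive)[0]
            new_state[idx] = (
                u[idx, None] > cum_trans[latent[idx, w - 1]]
            ).sum(axis=1)
            age_w = base_age + 2 * w
            logit = (
                config.mortality_coefs.intercept
                + config.mortality_coefs.age * age_w
                + np.where(new_state >= 0, death_state_coef[np.maximum(new_state, 0)], 0.0)
            )
            dies = rng.random(n) < _sigmoid(logit)
            alive[idx, w] = (~dies[idx]).astype(int)
            survived = prev_alive & (alive[:, w] == 1)
            latent[survived, w] = new_state[survived]

        data = {
            "id": [f"{study}-{i:06d}" for i in range(n)],
            "study": study,
            "sex": sex,
            "education": education,
        }
        for w, y in enumerate(years):
            data[col("age", y)] = base_age + 2 * w
            data[col("alive", y)] = alive[:, w]

        item_p = {
            v: np.array([config.item_prob(s, v) for s in states]) for v in ITEMS
        }
        for w, y in enumerate(years):
            live = alive[:, w] == 1
            st = latent[:, w]
            age_w = base_age + 2 * w
            for v in ITEMS:
                vals = np.full(n, np.nan)
                vals[live] = (
                    rng.random(live.sum()) < item_p[v][st[live]]
                ).astype(float)
                data[col(v, y)] = vals
            for out in OUTCOMES:
                p = np.zeros(n)
                for si, s in enumerate(states):
                    mask = live & (st == si)
                    p[mask] = config.outcome_prob(s, out, age_w[mask])
                vals = np.full(n, np.nan)
                vals[live] = (rng.random(live.sum()) < p[live]).astype(float)
                data[col(out, y)] = vals

        for rf in RISK_FACTORS:
            dyn = config.risk_factor_probs[rf]
            cur = (rng.random(n) < dyn.baseline).astype(float)
            for w, y in enumerate(years):
                live = alive[:, w] == 1
                if w > 0:
                    p = np.where(cur == 1, dyn.persist, dyn.onset)
                    cur = (rng.random(n) < p).astype(float)
                vals = np.full(n, np.nan)
                vals[live] = cur[live]
                data[col(rf, y)] = vals

        frames.append(pd.DataFrame(data))
        latents.append(latent)

    table = pd.concat(frames, ignore_index=True)
    if return_latent:
        return table, np.vstack(latents)
    return table


def inject_missingness(table: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Apply structural, wave-non-response and item-level missingness.

    Structural cells are missing with certainty; wave non-response blanks
    every substantive variable of the wave (never age, sex or vital
    status); item-level missingness hits ADL/IADL items independently.
    Reproducible under the config seed.
    """
    config.validate()
    out = table.copy()
    years = config.wave_years
    rng = stream(config.seed, "missingness")

    for rule in config.missingness.structural:
        rows = out["study"] == rule.study
        for y in rule.years:
            for v in rule.resolved_variables():
                out.loc[rows, col(v, y)] = np.nan

    n = len(out)
    if config.missingness.wave_nonresponse > 0:
        nonresp = rng.random((n, len(years))) < config.missingness.wave_nonresponse
        for w, y in enumerate(years):
            rows = nonresp[:, w]
            out.loc[rows, [col(v, y) for v in SUBSTANTIVE]] = np.nan
    if config.missingness.item > 0:
        for y in years:
            drop = rng.random((n, len(ITEMS))) < config.missingness.item
            for j, v in enumerate(ITEMS):
                out.loc[drop[:, j], col(v, y)] = np.nan
    return out


def top_code_ages(
    table: pd.DataFrame,
    wave_years,
    study: str = "ELSA",
    threshold: int = 90,
    code: int = 99,
) -> pd.DataFrame:
    """Disclosure-control age top-coding (ages > threshold set to ``code``).

    Optional post-processing mirroring an anonymisation artefact of one of
    the source studies; off by default because it deliberately breaks the
    deterministic age arithmetic.
    """
    out = table.copy()
    rows = out["study"] == study
    for y in wave_years:
        c = col("age", y)
        out.loc[rows & (out[c] > threshold), c] = code
    return out


# ---------------------------------------------------------------------- #
# Analytic oracles

def latent_forward(config: CohortConfig, wave: int, base_age: int) -> np.ndarray:
    """Mass alive in each latent state at ``wave`` for one baseline age.

    Forward recursion over (latent state x alive); the returned vector sums
    to the survival probability.
    """
    trans = np.asarray(config.latent_transition, dtype=float)
    m = np.asarray(config.latent_baseline, dtype=float).copy()
    coef = config.mortality_coefs
    state_coef = np.asarray([coef.state[s] for s in config.latent_states])
    for w in range(1, wave + 1):
        age_w = base_age + 2 * w
        q = _sigmoid(coef.intercept + coef.age * age_w + state_coef)
        m = (m @ trans) * (1.0 - q)
    return m


def analytic_prevalence(config: CohortConfig, wave: int, outcome: str) -> float:
    """Exact marginal P(outcome = 1 | alive at wave).

    Integrates the latent forward recursion over the uniform baseline-age
    distribution, weighting each baseline age by its survival mass.  The
    wave index may run past the observed grid (ages keep incrementing by
    2), which makes this the recovery target for scenario-0 projections.
    """
    if outcome not in OUTCOMES:
        raise KeyError(f"unknown outcome {outcome!r}")
    lo, hi = config.baseline_age_range
    num = 0.0
    den = 0.0
    for base_age in range(lo, hi + 1):
        m = latent_forward(config, wave, base_age)
        age_w = base_age + 2 * wave
        p_out = np.array(
            [config.outcome_prob(s, outcome, age_w) for s in config.latent_states],
            dtype=float,
        )
        num += float(m @ p_out)
        den += float(m.sum())
    if den == 0.0:
        raise ValueError("no survivors at the requested wave")
    return num / den
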