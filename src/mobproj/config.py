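"""Configuration of the synthetic three-study cohort.

The generator emulates the harmonised longitudinal structure the analysis
assumes: three studies with different baseline waves, biennial waves
2000-2012, individual first-order-Markov transitions driven by a latent
disability process, mortality increasing with age and disability, wave
non-response, and whole-wave / whole-variable structural missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .schema import ITEMS, OUTCOMES, RISK_FACTORS, SUBSTANTIVE


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class StructuralRule:
    """Cells that are missing with certainty (never collected).

    ``variables`` is a tuple of per-wave variable names, or ``"all"`` for
    every substantive variable; ``years`` are the affected waves.
    """

    study: str
    years: tuple[int, ...]
    variables: tuple[str, ...] | str = "all"

    def resolved_variables(self) -> tuple[str, ...]:
        if self.variables == "all":
            return SUBSTANTIVE
        return tuple(self.variables)


@dataclass(frozen=True)
class MissingnessConfig:
    """Stochastic and structural missingness of the raw tables."""

    wave_nonresponse: float = 0.12
    item: float = 0.02
    structural: tuple[StructuralRule, ...] = ()


@dataclass(frozen=True)
class RiskFactorDynamics:
    """Baseline prevalence and first-order transition of a binary factor."""

    baseline: float
    persist: float  # P(1 -> 1) per wave
    onset: float    # P(0 -> 1) per wave


@dataclass(frozen=True)
class MortalityCoefs:
    """Log-odds of death per biennial wave: intercept + age + latent state."""

    intercept: float
    age: float
    state: Mapping[str, float]


@dataclass(frozen=True)
class CohortConfig:
    n_per_study: Mapping[str, int]
    wave_years: tuple[int, ...] = (2000, 2002, 2004, 2006, 2008, 2010, 2012)
    baseline_age_range: tuple[int, int] = (50, 85)
    latent_states: tuple[str, ...] = ("good", "limited", "severe")
    latent_baseline: tuple[float, ...] = (0.70, 0.22, 0.08)
    latent_transition: tuple[tuple[float, ...], ...] = (
        (0.85, 0.12, 0.03),
        (0.25, 0.60, 0.15),
        (0.02, 0.18, 0.80),
    )
    # P(no difficulty) per item given latent state; scalar applies to all items
    item_probs: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"good": 0.97, "limited": 0.78, "severe": 0.40}
    )
    # P(limitation) per outcome given latent state, one value per age band
    outcome_probs: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=lambda: {
            "good": {"climb": (0.06, 0.12), "walk": (0.015, 0.03)},
            "limited": {"climb": (0.40, 0.50), "walk": (0.15, 0.22)},
            "severe": {"climb": (0.80, 0.88), "walk": (0.55, 0.65)},
        }
    )
    age_band_edges: tuple[int, ...] = (76,)
    risk_factor_probs: Mapping[str, RiskFactorDynamics] = field(
        default_factory=lambda: {
            "smoker": RiskFactorDynamics(0.18, 0.90, 0.01),
            "obese": RiskFactorDynamics(0.28, 0.93, 0.03),
            "alcohol": RiskFactorDynamics(0.65, 0.92, 0.08),
            "hypertension": RiskFactorDynamics(0.45, 0.95, 0.06),
            "vpa": RiskFactorDynamics(0.45, 0.75, 0.15),
        }
    )
    mortality_coefs: MortalityCoefs = field(
        default_factory=lambda: MortalityCoefs(
            intercept=-9.74, age=0.09, state={"good": 0.0, "limited": 0.8, "severe": 1.8}
        )
    )
    female_prob: float = 0.55
    education_probs: tuple[float, float, float] = (0.40, 0.38, 0.22)  # low/medium/high
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0

    # ------------------------------------------------------------------ #

    @property
    def study_labels(self) -> tuple[str, ...]:
        return tuple(self.n_per_study)

    @property
    def n_states(self) -> int:
        return len(self.latent_states)

    def item_prob(self, state: str, item: str) -> float:
        p = self.item_probs[state]
        if isinstance(p, Mapping):
            return float(p[item])
        return float(p)

    def age_band(self, age) -> np.ndarray:
        """Index of the age band an age falls into (0 = youngest)."""
        return np.searchsorted(np.asarray(self.age_band_edges), np.asarray(age), "right")

    def outcome_prob(self, state: str, outcome: str, age) -> np.ndarray:
        bands = np.asarray(self.outcome_probs[state][outcome], dtype=float)
        return bands[self.age_band(age)]

    def validate(self) -> None:
        years = self.wave_years
        if len(years) < 2 or any(b - a != 2 for a, b in zip(years, years[1:])):
            raise ConfigError("wave_years: must be strictly increasing with spacing 2")
        for label, n in self.n_per_study.items():
            if n < 1:
                raise ConfigError(f"n_per_study[{label}]: must be positive")
        k = self.n_states
        base = np.asarray(self.latent_baseline, dtype=float)
        if base.shape != (k,) or not np.isclose(base.sum(), 1.0) or (base < 0).any():
            raise ConfigError("latent_baseline: must be a probability vector over latent_states")
        trans = np.asarray(self.latent_transition, dtype=float)
        if trans.shape != (k, k) or (trans < 0).any() or (trans > 1).any():
            raise ConfigError("latent_transition: must be a k x k matrix of probabilities")
        if not np.allclose(trans.sum(axis=1), 1.0):
            raise ConfigError("latent_transition: each row must sum to 1")
        for state in self.latent_states:
            if state not in self.item_probs:
                raise ConfigError(f"item_probs: missing state {state!r}")
            for item in ITEMS:
                p = self.item_prob(state, item)
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"item_probs[{state}][{item}]: not in [0, 1]")
            if state not in self.outcome_probs:
                raise ConfigError(f"outcome_probs: missing state {state!r}")
            for out in OUTCOMES:
                bands = np.asarray(self.outcome_probs[state][out], dtype=float)
                if bands.shape != (len(self.age_band_edges) + 1,):
                    raise ConfigError(
                        f"outcome_probs[{state}][{out}]: need one value per age band"
                    )
                if ((bands < 0) | (bands > 1)).any():
                    raise ConfigError(f"outcome_probs[{state}][{out}]: not in [0, 1]")
            if state not in self.mortality_coefs.state:
                raise ConfigError(f"mortality_coefs.state: missing state {state!r}")
        for rf in RISK_FACTORS:
            if rf not in self.risk_factor_probs:
                raise ConfigError(f"risk_factor_probs: missing factor {rf!r}")
            d = self.risk_factor_probs[rf]
            for name, p in (("baseline", d.baseline), ("persist", d.persist), ("onset", d.onset)):
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"risk_factor_probs[{rf}].{name}: not in [0, 1]")
        m = self.missingness
        if not 0.0 <= m.wave_nonresponse <= 1.0:
            raise ConfigError("missingness.wave_nonresponse: not in [0, 1]")
        if not 0.0 <= m.item <= 1.0:
            raise ConfigError("missingness.item: not in [0, 1]")
        for rule in m.structural:
            if rule.study not in self.n_per_study:
                raise ConfigError(f"missingness.structural: unknown study {rule.study!r}")
            for y in rule.years:
                if y not in years:
                    raise ConfigError(f"missingness.structural: unknown wave {y}")
            for v in rule.resolved_variables():
                if v not in SUBSTANTIVE:
                    raise ConfigError(f"missingness.structural: unknown variable {v!r}")
        lo, hi = self.baseline_age_range
        if lo < 50 or hi < lo:
            raise ConfigError("baseline_age_range: minimum baseline age is 50")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def default_config(n_per_study: Mapping[str, int] | None = None, seed: int = 0) -> CohortConfig:
    """The reference three-study configuration.

    Sample sizes default to the harmonised analysis dataset (HRS 9765,
    ELSA 10815, H2000 4402; N = 24,982).  Structural missingness encodes
    the real layout: ELSA starts in 2002, the Finnish study has no
    2002-2008 waves, HRS never asks the dressing item and the Finnish
    study never asks the managing-money item.
    """
    if n_per_study is None:
        n_per_study = {"HRS": 9765, "ELSA": 10815, "H2000": 4402}
    structural = []
    if "ELSA" in n_per_study:
        structural.append(StructuralRule("ELSA", (2000,), "all"))
    if "H2000" in n_per_study:
        structural.append(StructuralRule("H2000", (2002, 2004, 2006, 2008), "all"))
        structural.append(
            StructuralRule("H2000", (2000, 2010, 2012), ("iadl6",))
        )
    if "HRS" in n_per_study:
        structural.append(
            StructuralRule("HRS", (2000, 2002, 2004, 2006, 2008, 2010, 2012), ("adl2",))
        )
    return CohortConfig(
        n_per_study=dict(n_per_study),
        missingness=MissingnessConfig(structural=tuple(structural)),
        seed=seed,
    )


# ---------------------------------------------------------------------- #
# YAML plumbing

def config_from_dict(d: Mapping) -> CohortConfig:
    d = dict(d)
    if "missingness" in d:
        m = dict(d["missingness"])
        m["structural"] = tuple(
            StructuralRule(
                study=r["study"],
                years=tuple(r["years"]),
                variables="all" if r.get("variables", "all") == "all" else tuple(r["variables"]),
            )
            for r in m.get("structural", ())
        )
        d["missingness"] = MissingnessConfig(**m)
    if "risk_factor_probs" in d:
        d["risk_factor_probs"] = {
            k: v if isinstance(v, RiskFactorDynamics) else RiskFactorDynamics(**v)
            for k, v in d["risk_factor_probs"].items()
        }
    if "mortality_coefs" in d and not isinstance(d["mortality_coefs"], MortalityCoefs):
        d["mortality_coefs"] = MortalityCoefs(**d["mortality_coefs"])
    for key in ("wave_years", "baseline_age_range", "latent_states", "latent_baseline",
                "age_band_edges", "education_probs"):
        if key in d:
            d[key] = tuple(d[key])
    if "latent_transition" in d:
        d["latent_transition"] = tuple(tuple(row) for row in d["latent_transition"])
    if "outcome_probs" in d:
        d["outcome_probs"] = {
            s: {o: tuple(np.atleast_1d(p)) for o, p in probs.items()}
            for s, probs in d["outcome_probs"].items()
        }
    return CohortConfig(**d)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))

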