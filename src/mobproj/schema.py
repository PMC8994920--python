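"""Column naming conventions for the wide cohort panel.

One row per individual; per-wave variables are suffixed with the calendar
year (``iadl3_2006``), time-independent variables (``id``, ``study``,
``sex``, ``education``) are unsuffixed.  Items are coded 1 = no difficulty,
0 = difficulty; outcomes are coded 1 = has the limitation.
"""

from __future__ import annotations

ADL_ITEMS = tuple(f"adl{i}" for i in range(1, 7))
IADL_ITEMS = tuple(f"iadl{i}" for i in range(1, 7))
ITEMS = ADL_ITEMS + IADL_ITEMS

#: ADL item index -> function, mirroring the harmonised short battery
ADL_LABELS = {
    "adl1": "bathing or showering",
    "adl2": "getting dressed",
    "adl3": "using the toilet",
    "adl4": "getting in or out of bed",
    "adl5": "continence",
    "adl6": "eating",
}
IADL_LABELS = {
    "iadl1": "making telephone calls",
    "iadl2": "shopping groceries",
    "iadl3": "preparing meals",
    "iadl4": "doing housework",
    "iadl5": "taking medications",
    "iadl6": "managing money",
}

OUTCOMES = ("climb", "walk")  # stair climbing / walking across a room
RISK_FACTORS = ("smoker", "obese", "alcohol", "hypertension", "vpa")
SCORES = ("adl_score", "iadl_score")

#: per-wave variables blanked by wave non-response (age/sex/vital status are not)
SUBSTANTIVE = OUTCOMES + ITEMS + RISK_FACTORS
#: per-wave variables of the post-score panel (items replaced by scores)
SUBSTANTIVE_SCORED = OUTCOMES + SCORES + RISK_FACTORS

ID_COLS = ("id", "study", "sex", "education")


def col(var: str, year: int) -> str:
    """Wide-panel column name for ``var`` at calendar ``year``."""
    return f"{var}_{year}"


def wave_cols(var: str, years) -> list[str]:
    return [col(var, y) for y in years]
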