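"""Environmental footprint indicators for a person-day of reported foods.

Each reported food is matched by its food code to one of 43 food groups;
six per-serving impact factors (freshwater withdrawals, stress-weighted
water use, acidifying emissions, eutrophying emissions, greenhouse gas
emissions, land use) are scaled by reported servings and summed over the
day.  Unmatched foods contribute zero impact but are tallied, so the
match coverage of every person-day is observable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .resources import load_crosswalk, load_impact_factors

#: Output column for each impact metric, in fixed order.
FOOTPRINT_COLUMNS = [
    "freshwater_l",
    "stress_water_l",
    "acid_g",
    "eutroph_g",
    "ghge_kg",
    "land_m2",
]

UNMATCHED = "__unmatched__"


def match_food(food_code: str, crosswalk: pd.DataFrame) -> str:
    """Deterministic lookup of a food code's group; unmatched is a valid outcome."""
    hits = crosswalk.loc[crosswalk["food_code"] == str(food_code), "group"]
    return str(hits.iloc[0]) if len(hits) else UNMATCHED


def match_items(intake: pd.DataFrame, crosswalk: pd.DataFrame) -> pd.Series:
    """Vectorised group assignment for an intake table (UNMATCHED where absent)."""
    mapping = crosswalk.set_index("food_code")["group"]
    return intake["food_code"].astype(str).map(mapping).fillna(UNMATCHED)


def coverage(intake: pd.DataFrame, crosswalk: pd.DataFrame) -> tuple[float, float]:
    """Fractions of reported items and of servings matched to a food group."""
    if len(intake) == 0:
        raise DomainError("coverage is undefined for an empty intake table")
    groups = match_items(intake, crosswalk)
    matched = groups != UNMATCHED
    item_cov = float(matched.mean())
    total_serv = float(intake["servings"].sum())
    serv_cov = float(intake.loc[matched, "servings"].sum() / total_serv) if total_serv > 0 else 0.0
    return item_cov, serv_cov


def daily_footprints(
    intake: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    crosswalk: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-person daily footprint totals for every person in the intake table.

    Returns one row per person with the six impact columns plus
    ``matched_servings``, ``total_servings`` and item-level ``env_coverage``
    (zero, by convention, for a person with no reported items at all —
    such rows only appear for persons present in the table).
    """
    if factors is None:
        factors = load_impact_factors()
    if crosswalk is None:
        crosswalk = load_crosswalk()
    metric_cols = FOOTPRINT_COLUMNS
    if (intake["servings"] < 0).any():
        raise DomainError("servings must be >= 0")

    work = intake[["person_id", "servings"]].copy()
    work["group"] = match_items(intake, crosswalk).to_numpy()
    work = work.merge(factors, on="group", how="left")
    matched = work["group"] != UNMATCHED
    for col in metric_cols:
        work[col] = np.where(matched, work[col].fillna(0.0) * work["servings"], 0.0)
    work["matched_servings"] = np.where(matched, work["servings"], 0.0)
    work["matched_items"] = matched.astype(float)
    work["n_items"] = 1.0

    agg = work.groupby("person_id", sort=True).agg(
        {**{c: "sum" for c in metric_cols}, "matched_servings": "sum", "servings": "sum", "matched_items": "sum", "n_items": "sum"}
    )
    agg = agg.rename(columns={"servings": "total_servings"})
    agg["env_coverage"] = np.where(agg["n_items"] > 0, agg["matched_items"] / agg["n_items"], 0.0)
    agg = agg.drop(columns=["matched_items", "n_items"])
    return agg.reset_index()


def cohort_environment_indicators(
    persons: pd.DataFrame,
    intake: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    crosswalk: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Six footprint indicator columns aligned to the persons table.

    Persons with no reported items receive zero footprints (empty diet)
    and coverage 0.
    """
    per_day = daily_footprints(intake, factors=factors, crosswalk=crosswalk)
    out = persons[["person_id"]].merge(per_day, on="person_id", how="left")
    fill = {c: 0.0 for c in FOOTPRINT_COLUMNS + ["matched_servings", "total_servings", "env_coverage"]}
    return out.fillna(fill)
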