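"""Economic and sociocultural indicators.

The single economic indicator is the *budget share*: annualised family
food expenditure (12 x the sum of four monthly amounts) divided by a
family-income proxy (midpoint of the reported income band), expressed as
a percentage.  The three sociocultural indicators are the reported
frequencies of fast-food/pizza meals (past 7 days, valid 0-21), ready-
to-eat foods and frozen meals/pizza (past 30 days, valid 0-90 each).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, RangeError
from .resources import load_income_bands

EXPENDITURE_FIELDS = ["supermarket_month", "other_store_month", "eating_out_month", "carryout_month"]

FREQUENCY_BOUNDS = {
    "fastfood_meals_7d": (0, 21),
    "ready_to_eat_30d": (0, 90),
    "frozen_30d": (0, 90),
}


def annual_food_expenditure(monthly_amounts) -> float:
    """Annualised food spending: 12 x the sum of the four monthly amounts.

    Returns NaN (the missing-indicator signal feeding the exclusion
    cascade) when any component is missing.
    """
    arr = np.asarray(monthly_amounts, dtype=float)
    if arr.shape != (4,):
        raise DomainError(f"expected 4 monthly expenditure amounts, got shape {arr.shape}")
    if np.isnan(arr).any():
        return float("nan")
    if (arr < 0).any():
        raise DomainError("expenditure amounts must be >= 0")
    return float(12.0 * arr.sum())


def income_proxy(category: str, bands: pd.DataFrame | None = None) -> tuple[float, bool]:
    """Dollar proxy for a categorical income band.

    Returns ``(proxy, top_coded)``.  Bands with explicit bounds map to
    their midpoint; a top-coded band (no upper bound) maps to the proxy
    column of the band table.
    """
    if bands is None:
        bands = load_income_bands()
    rows = bands[bands["label"] == category]
    if len(rows) != 1:
        raise ConfigError(f"unknown income category {category!r}")
    row = rows.iloc[0]
    if pd.isna(row["upper"]):
        if pd.isna(row["proxy"]):
            raise ConfigError(f"top-coded band {category!r} has no configured proxy")
        return float(row["proxy"]), True
    if not pd.isna(row["proxy"]):
        return float(row["proxy"]), False
    return (float(row["lower"]) + float(row["upper"])) / 2.0, False


def budget_share(annual_food: float, annual_income: float) -> tuple[float, bool]:
    """Percent of income devoted to food; shares above 100% are flagged, kept."""
    if annual_income <= 0:
        raise DomainError(f"annual income must be > 0, got {annual_income}")
    if annual_food < 0:
        raise DomainError("annual food expenditure must be >= 0")
    share = 100.0 * annual_food / annual_income
    return share, share > 100.0


def validate_frequencies(record: pd.Series | dict, away_from_home_meals: float | None = None) -> dict:
    """Check the three ready-made-food frequencies against their valid ranges.

    Raises :class:`RangeError` naming the offending field; when the total
    away-from-home meal count is captured, fast-food meals may not exceed it.
    """
    rec = dict(record)
    out = {}
    for fieldname, (lo, hi) in FREQUENCY_BOUNDS.items():
        value = rec[fieldname]
        if pd.isna(value):
            out[fieldname] = float("nan")
            continue
        value = float(value)
        if not (lo <= value <= hi):
            raise RangeError(f"{fieldname}={value:g} outside valid range {lo}-{hi}")
        out[fieldname] = value
    ff = out["fastfood_meals_7d"]
    if away_from_home_meals is not None and not pd.isna(ff) and ff > away_from_home_meals:
        raise RangeError(
            f"fastfood_meals_7d={ff:g} exceeds away-from-home meals {away_from_home_meals:g}"
        )
    return out


def cohort_economic_sociocultural(
    persons: pd.DataFrame,
    expenditure: pd.DataFrame,
    frequencies: pd.DataFrame,
    bands: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-person ``budget_share_pct`` + three frequency indicator columns.

    Post-exclusion cohorts have complete components by construction, so a
    missing value here raises rather than silently scoring.
    """
    if bands is None:
        bands = load_income_bands()
    exp = persons[["person_id", "income_category"]].merge(expenditure, on="person_id", validate="1:1")
    freq = persons[["person_id"]].merge(frequencies, on="person_id", validate="1:1")

    shares = np.empty(len(exp))
    over_flags = np.zeros(len(exp), dtype=bool)
    top_flags = np.zeros(len(exp), dtype=bool)
    for i, row in enumerate(exp.itertuples(index=False)):
        annual_food = annual_food_expenditure(
            [getattr(row, f) for f in EXPENDITURE_FIELDS]
        )
        if np.isnan(annual_food) or pd.isna(row.income_category):
            raise DomainError(f"person {row.person_id} has missing economic components after exclusions")
        income, top = income_proxy(str(row.income_category), bands)
        shares[i], over_flags[i] = budget_share(annual_food, income)
        top_flags[i] = top

    freq_checked = pd.DataFrame(
        [validate_frequencies(r) for r in freq[list(FREQUENCY_BOUNDS)].to_dict("records")]
    )
    out = pd.DataFrame(
        {
            "person_id": exp["person_id"],
            "budget_share_pct": shares,
            "budget_over_100": over_flags,
            "income_top_coded": top_flags,
            "freq_fastfood": freq_checked["fastfood_meals_7d"].to_numpy(),
            "freq_rte": freq_checked["ready_to_eat_30d"].to_numpy(),
            "freq_frozen": freq_checked["frozen_30d"].to_numpy(),
        }
    )
    return out
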