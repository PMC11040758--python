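"""Nutritional indicators: NRF9.3 nutrient density and mean adequacy ratio.

Two per-person indicators summarise nutritional quality:

* **NRF9.3** — the Nutrient-Rich Foods index: the sum of percent daily
  values (%DV) of nine nutrients to encourage (protein, fiber, vitamins
  A/C/E, calcium, iron, magnesium, potassium), each capped at 100 %DV,
  minus the %DV of three to limit (saturated fat, added sugar, sodium),
  expressed by default per 100 kcal of the day's intake.
* **MAR** — the mean nutrient adequacy ratio over 12 nutrients: 11
  dietary micronutrients (energy-adjusted by the residual method and
  divided by sex/age-specific RDAs, each ratio capped at 1) plus serum
  25-hydroxyvitamin D relative to the 50 nmol/L deficiency cut-point,
  averaged and scaled to a 0-100 percentage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError, DomainError
from .resources import load_dv_table, load_rda_table

#: The 11 dietary nutrients entering the adequacy ratio (the 12th is
#: serum 25(OH)D, which is not energy-adjusted).
NAR_NUTRIENTS = [
    "vitamin_a_ug",
    "thiamin_mg",
    "vitamin_b6_mg",
    "folate_ug",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "calcium_mg",
    "magnesium_mg",
    "iron_mg",
    "zinc_mg",
    "copper_mg",
]

#: Serum 25-hydroxyvitamin D adequacy cut-point (risk of deficiency below).
VITD_CUTPOINT_NMOL_L = 50.0


# ------------------------------------------------------------------ NRF9.3


def percent_dv(amount, reference: float, cap: float | None = None):
    """Percent of a daily value consumed: ``100 * amount / reference``.

    ``amount`` may be a scalar or array; negative intakes and non-positive
    references are rejected.  When ``cap`` is given the result is truncated
    at that percentage.
    """
    if reference <= 0:
        raise DomainError(f"daily value reference must be > 0, got {reference}")
    amount = np.asarray(amount, dtype=float)
    if (amount < 0).any():
        raise DomainError("nutrient amount must be >= 0")
    pct = 100.0 * amount / reference
    if cap is not None:
        pct = np.minimum(pct, cap)
    return float(pct) if pct.ndim == 0 else pct


def nrf93(
    nutrients: pd.DataFrame,
    dv_table: pd.DataFrame | None = None,
    basis: str = "per_100kcal",
    cap_encourage: float | None = 100.0,
    cap_limit: float | None = None,
) -> pd.Series:
    """NRF9.3 nutrient-density score for each row of a nutrient table.

    Parameters
    ----------
    nutrients:
        Frame with ``energy_kcal`` plus the 12 NRF nutrient columns.
    basis:
        ``"per_100kcal"`` (default), ``"per_2000kcal"`` or ``"per_day"``.
        Density bases divide the raw sum-of-%DV difference by the day's
        energy so that isocaloric scaling of a whole diet leaves the
        score unchanged.
    cap_encourage / cap_limit:
        %DV truncation applied before summation (encourage terms capped
        at 100 %DV by default; limit terms uncapped).
    """
    if dv_table is None:
        dv_table = load_dv_table()
    if basis not in {"per_100kcal", "per_2000kcal", "per_day"}:
        raise DomainError(f"unknown NRF basis {basis!r}")
    energy = nutrients["energy_kcal"].to_numpy(dtype=float)
    if (energy <= 0).any():
        raise DomainError("energy_kcal must be > 0 for every person")

    encourage = np.zeros(len(nutrients))
    limit = np.zeros(len(nutrients))
    for _, row in dv_table.iterrows():
        col = row["nutrient"]
        if col not in nutrients.columns:
            raise DomainError(f"nutrient table is missing NRF component {col!r}")
        cap = cap_encourage if row["role"] == "encourage" else cap_limit
        pct = percent_dv(nutrients[col].to_numpy(dtype=float), float(row["dv"]), cap=cap)
        if row["role"] == "encourage":
            encourage += pct
        else:
            limit += pct

    raw = encourage - limit
    if basis == "per_day":
        score = raw
    elif basis == "per_100kcal":
        score = raw * (100.0 / energy)
    else:
        score = raw * (2000.0 / energy)
    return pd.Series(score, index=nutrients.index, name="nrf93")


# ----------------------------------------------------- energy adjustment


def energy_adjust_residual(
    values: pd.Series | np.ndarray,
    energy: pd.Series | np.ndarray,
    reference_energy: float | None = None,
    weights: pd.Series | np.ndarray | None = None,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Residual-method energy adjustment of a nutrient intake series.

    Regresses intake on total energy (weighted least squares when survey
    weights are given) and returns ``residual + fitted(reference_energy)``,
    removing between-person variation that is explained by energy alone.
    ``reference_energy`` defaults to the (weighted) mean energy.
    """
    values = np.asarray(values, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if values.shape != energy.shape or values.ndim != 1:
        raise DomainError("values and energy must be aligned 1-d series")
    if len(values) < 3:
        raise DomainError("residual adjustment needs at least 3 observations")
    if np.var(energy) == 0:
        raise DegenerateDesignError("energy has zero variance; residual fit is degenerate")
    w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    if reference_energy is None:
        reference_energy = float(np.average(energy, weights=w))

    design = sm.add_constant(energy)
    fit = sm.WLS(values, design, weights=w).fit()
    fitted_at_ref = float(fit.params[0] + fit.params[1] * reference_energy)
    adjusted = fit.resid + fitted_at_ref
    if floor_at_zero:
        adjusted = np.maximum(adjusted, 0.0)
    return np.asarray(adjusted)


# ------------------------------------------------------------- NAR / MAR


def nar(intake, recommended: float, cap_at_one: bool = True):
    """Nutrient adequacy ratio: intake over recommendation, capped at 1."""
    if recommended <= 0:
        raise DomainError(f"recommended amount must be > 0, got {recommended}")
    intake = np.asarray(intake, dtype=float)
    if (intake < 0).any():
        raise DomainError("intake must be >= 0")
    ratio = intake / recommended
    if cap_at_one:
        ratio = np.minimum(ratio, 1.0)
    return float(ratio) if ratio.ndim == 0 else ratio


def mar(nars) -> float:
    """Mean adequacy ratio: 100 x the mean of exactly 12 adequacy ratios."""
    arr = np.asarray(nars, dtype=float)
    if arr.shape != (12,):
        raise DomainError(f"MAR requires exactly 12 adequacy ratios, got shape {arr.shape}")
    return float(100.0 * arr.mean())


def rda_lookup(rda_table: pd.DataFrame, nutrient: str, sex: str, age: int) -> float:
    rows = rda_table[
        (rda_table["nutrient"] == nutrient)
        & (rda_table["sex"] == sex)
        & (rda_table["age_min"] <= age)
        & (age <= rda_table["age_max"])
    ]
    if len(rows) != 1:
        raise DomainError(f"RDA lookup for {nutrient!r}, {sex}, age {age} matched {len(rows)} rows")
    return float(rows["rda"].iloc[0])


def cohort_nutrition_indicators(
    persons: pd.DataFrame,
    nutrients: pd.DataFrame,
    dv_table: pd.DataFrame | None = None,
    rda_table: pd.DataFrame | None = None,
    nrf_basis: str = "per_100kcal",
    cap_nar: bool = True,
    energy_adjust: bool = True,
) -> pd.DataFrame:
    """Per-person ``nrf93`` and ``mar`` columns for a post-exclusion cohort.

    The 11 dietary NAR nutrients are energy-adjusted across the cohort
    with survey-weighted residual regression; serum 25(OH)D enters its
    adequacy ratio directly from the lab value.
    """
    if rda_table is None:
        rda_table = load_rda_table()
    merged = persons.merge(nutrients, on="person_id", how="inner", validate="1:1")
    if len(merged) != len(persons):
        raise DomainError("every person must have exactly one nutrient day")

    out = pd.DataFrame({"person_id": merged["person_id"]})
    out["nrf93"] = nrf93(merged, dv_table=dv_table, basis=nrf_basis).to_numpy()

    energy = merged["energy_kcal"].to_numpy(dtype=float)
    weights = merged["weight"].to_numpy(dtype=float)
    nar_matrix = np.empty((len(merged), 12))
    for j, nutrient in enumerate(NAR_NUTRIENTS):
        intake = merged[nutrient].to_numpy(dtype=float)
        if energy_adjust:
            intake = energy_adjust_residual(intake, energy, weights=weights)
        rdas = np.array(
            [
                rda_lookup(rda_table, nutrient, sex, int(age))
                for sex, age in zip(merged["sex"], merged["age_years"])
            ]
        )
        ratio = intake / rdas
        nar_matrix[:, j] = np.minimum(ratio, 1.0) if cap_nar else ratio
    vitd_ratio = merged["serum_25ohd"].to_numpy(dtype=float) / VITD_CUTPOINT_NMOL_L
    nar_matrix[:, 11] = np.minimum(vitd_ratio, 1.0) if cap_nar else vitd_ratio

    out["mar"] = 100.0 * nar_matrix.mean(axis=1)
    return out
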