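"""Loaders for the reference tables shipped with the package.

Every table is an editable CSV under ``sdius/data``; any function here
also accepts a path to a user-supplied replacement with the same columns.
The impact-factor table and crosswalk shipped here are *synthetic*
stand-ins with realistic magnitudes (the true per-serving factors come
from external life-cycle-assessment databases).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataError

_DATA = resources.files("sdius") / "data"


def _resolve(name: str, path: str | Path | None) -> Path:
    if path is not None:
        return Path(path)
    return Path(str(_DATA / name))


def load_dv_table(path: str | Path | None = None) -> pd.DataFrame:
    """Daily-value references for the NRF9.3 index (9 encourage + 3 limit)."""
    frame = pd.read_csv(_resolve("dv_table.csv", path))
    n_enc = (frame["role"] == "encourage").sum()
    n_lim = (frame["role"] == "limit").sum()
    if (n_enc, n_lim) != (9, 3):
        raise DataError(f"DV table must list 9 encourage + 3 limit nutrients, got {n_enc}+{n_lim}")
    if (frame["dv"] <= 0).any():
        raise DataError("DV table has non-positive reference amounts")
    return frame


def load_rda_table(path: str | Path | None = None) -> pd.DataFrame:
    """Recommended dietary allowances by sex and age band (11 nutrients)."""
    frame = pd.read_csv(_resolve("rda_table.csv", path))
    if (frame["rda"] <= 0).any():
        raise DataError("RDA table has non-positive recommendations")
    return frame


def load_cutpoints(path: str | Path | None = None) -> pd.DataFrame:
    """The fixed US scoring rubric: direction, zero rule, and 4 thresholds."""
    frame = pd.read_csv(_resolve("cutpoints_us.csv", path))
    return frame


def load_income_bands(path: str | Path | None = None) -> pd.DataFrame:
    frame = pd.read_csv(_resolve("income_bands.csv", path))
    return frame


def load_impact_factors(path: str | Path | None = None) -> pd.DataFrame:
    """43-food-group x 6-metric per-serving environmental impact table."""
    frame = pd.read_csv(_resolve("impact_factors_synthetic.csv", path))
    metric_cols = [c for c in frame.columns if c != "group"]
    if len(frame) != 43:
        raise DataError(f"impact factor table must have 43 food groups, got {len(frame)}")
    if frame["group"].duplicated().any():
        raise DataError("impact factor table has duplicate group labels")
    if (frame[metric_cols] < 0).any().any():
        raise DataError("impact factor table has negative values")
    return frame


def load_crosswalk(path: str | Path | None = None) -> pd.DataFrame:
    """Food-code -> food-group crosswalk (single-valued per code)."""
    frame = pd.read_csv(_resolve("crosswalk_synthetic.csv", path), dtype={"food_code": str})
    if frame["food_code"].duplicated().any():
        raise DataError("crosswalk maps some food_code more than once")
    return frame


def load_food_group_map(path: str | Path | None = None) -> pd.DataFrame:
    """Roll-up map: food group -> DGA group, aMed and EAT-Lancet components."""
    return pd.read_csv(_resolve("food_group_map.csv", path))


def load_eat_lancet_criteria(path: str | Path | None = None) -> pd.DataFrame:
    frame = pd.read_csv(_resolve("eat_lancet_criteria.csv", path))
    if len(frame) != 14:
        raise DataError(f"EAT-Lancet criteria table must have 14 components, got {len(frame)}")
    return frame
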