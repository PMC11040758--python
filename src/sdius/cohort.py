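"""Cohort data model, CSV ingestion, and the sample exclusion cascade.

A cohort is five linked per-person tables (persons, 24-hour-recall intake
items, daily nutrient totals, monthly food expenditures, ready-made-food
frequencies).  All tables are plain :class:`pandas.DataFrame` objects keyed
by ``person_id``; missing values are empty CSV fields parsed to NaN.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ReferentialError, SchemaError

# ---------------------------------------------------------------- schemas

PERSON_COLUMNS = [
    "person_id",
    "age_years",
    "sex",
    "race_ethnicity",
    "education",
    "household_size",
    "pregnant_or_breastfeeding",
    "income_category",
    "serum_25ohd",
    "weight",
    "stratum",
    "psu",
]

INTAKE_COLUMNS = ["person_id", "food_code", "description", "servings", "grams"]

#: Daily nutrient totals.  The first 13 feed the NRF9.3 nutrient-density
#: score; the 11 listed under NAR_NUTRIENTS (in nutrition.py) feed the MAR.
NUTRIENT_COLUMNS = [
    "person_id",
    "energy_kcal",
    "protein_g",
    "fiber_g",
    "vitamin_a_ug",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "calcium_mg",
    "iron_mg",
    "magnesium_mg",
    "potassium_mg",
    "sat_fat_g",
    "added_sugar_g",
    "sodium_mg",
    "thiamin_mg",
    "vitamin_b6_mg",
    "folate_ug",
    "zinc_mg",
    "copper_mg",
]

#: Optional nutrient columns used only by the comparison diet scores
#: (monounsaturated fat for the fat-quality ratios, alcohol for aMed).
OPTIONAL_NUTRIENT_COLUMNS = ["mufa_g", "alcohol_g"]

EXPENDITURE_COLUMNS = [
    "person_id",
    "supermarket_month",
    "other_store_month",
    "eating_out_month",
    "carryout_month",
]

FREQUENCY_COLUMNS = ["person_id", "fastfood_meals_7d", "ready_to_eat_30d", "frozen_30d"]

TABLE_SCHEMAS: Mapping[str, Sequence[str]] = {
    "persons": PERSON_COLUMNS,
    "intake": INTAKE_COLUMNS,
    "nutrients": NUTRIENT_COLUMNS,
    "expenditure": EXPENDITURE_COLUMNS,
    "frequencies": FREQUENCY_COLUMNS,
}

#: Canonical file name for each table inside a cohort directory.
TABLE_FILES = {
    "persons": "persons.csv",
    "intake": "intake_items.csv",
    "nutrients": "nutrients.csv",
    "expenditure": "expenditure.csv",
    "frequencies": "frequencies.csv",
}


@dataclass
class Cohort:
    """Five linked tables describing one analytic sample."""

    persons: pd.DataFrame
    intake: pd.DataFrame
    nutrients: pd.DataFrame
    expenditure: pd.DataFrame
    frequencies: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.persons)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "intake": self.intake,
            "nutrients": self.nutrients,
            "expenditure": self.expenditure,
            "frequencies": self.frequencies,
        }

    def subset(self, person_ids) -> "Cohort":
        """Restrict every table to the given person ids (order preserved)."""
        keep = pd.Index(person_ids)
        return Cohort(
            persons=self.persons[self.persons["person_id"].isin(keep)].reset_index(drop=True),
            intake=self.intake[self.intake["person_id"].isin(keep)].reset_index(drop=True),
            nutrients=self.nutrients[self.nutrients["person_id"].isin(keep)].reset_index(drop=True),
            expenditure=self.expenditure[self.expenditure["person_id"].isin(keep)].reset_index(drop=True),
            frequencies=self.frequencies[self.frequencies["person_id"].isin(keep)].reset_index(drop=True),
        )

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(directory / TABLE_FILES[name], index=False)


@dataclass
class ExclusionLog:
    """Sequential bookkeeping of the sample-exclusion cascade."""

    initial_n: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final_n(self) -> int:
        return self.initial_n - sum(count for _, count in self.steps)

    def summary(self) -> str:
        lines = [f"initial n = {self.initial_n}"]
        for label, count in self.steps:
            lines.append(f"  - {label}: removed {count}")
        lines.append(f"final n = {self.final_n}")
        return "\n".join(lines)


# ---------------------------------------------------------------- reading


def _read_table(path: str | Path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} table not found at {path}")
    frame = pd.read_csv(path, dtype={"person_id": str, "food_code": str})
    required = TABLE_SCHEMAS[name]
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise SchemaError(f"{name} table {path} is missing column(s): {', '.join(missing)}")
    return frame


def read_cohort(directory: str | Path | None = None, *, paths: Mapping[str, str | Path] | None = None) -> Cohort:
    """Read and validate the five cohort tables.

    Parameters
    ----------
    directory:
        Folder containing the canonically named CSVs (see ``TABLE_FILES``).
    paths:
        Alternatively, an explicit mapping ``table name -> file path``.

    Raises
    ------
    SchemaError
        If a file or required column is absent.
    ReferentialError
        If a child table references an unknown ``person_id``.
    """
    if (directory is None) == (paths is None):
        raise ConfigError("read_cohort needs exactly one of `directory` or `paths`")
    if directory is not None:
        directory = Path(directory)
        paths = {name: directory / fname for name, fname in TABLE_FILES.items()}

    frames = {name: _read_table(path, name) for name, path in paths.items()}
    persons = frames["persons"]

    if persons["person_id"].duplicated().any():
        dupes = persons.loc[persons["person_id"].duplicated(), "person_id"].tolist()
        raise SchemaError(f"duplicate person_id in persons table: {dupes[:5]}")

    known = set(persons["person_id"])
    for name in ("intake", "nutrients", "expenditure", "frequencies"):
        child = frames[name]
        unknown = set(child["person_id"]) - known
        if unknown:
            sample = sorted(unknown)[:5]
            raise ReferentialError(f"{name} table references unknown person_id(s): {sample}")

    for name in ("intake",):
        bad = frames[name][(frames[name]["servings"] < 0) | (frames[name]["grams"] < 0)]
        if len(bad):
            raise SchemaError(f"intake table has negative servings/grams for {bad['person_id'].tolist()[:5]}")

    return Cohort(**frames)


def cohort_round_trip(cohort: Cohort) -> Cohort:
    """Write the cohort to CSV in memory and read it back (fidelity check)."""
    buffers = {}
    for name, frame in cohort.tables().items():
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        buffers[name] = buf
    frames = {}
    for name, buf in buffers.items():
        frame = pd.read_csv(buf, dtype={"person_id": str, "food_code": str})
        frames[name] = frame
    return Cohort(**frames)


# ------------------------------------------------------------- exclusions

#: Cascade order mirrors the study-population flowchart: each person is
#: removed at the FIRST criterion they meet, so step counts are disjoint.
EXCLUSION_ORDER = [
    "pregnant_or_breastfeeding",
    "incomplete_recall",
    "missing_25ohd",
    "missing_sdi_components",
    "missing_education",
]


def _criterion_mask(cohort: Cohort, criterion: str) -> pd.Series:
    persons = cohort.persons
    pid = persons["person_id"]
    if criterion == "pregnant_or_breastfeeding":
        flag = persons["pregnant_or_breastfeeding"]
        return flag.fillna(False).astype(bool)
    if criterion == "incomplete_recall":
        nut = cohort.nutrients
        has_day = pid.isin(set(nut.loc[nut["energy_kcal"] > 0, "person_id"]))
        return ~has_day
    if criterion == "missing_25ohd":
        return persons["serum_25ohd"].isna()
    if criterion == "missing_sdi_components":
        income_missing = persons["income_category"].isna()
        exp = cohort.expenditure.set_index("person_id")
        exp_missing_any = exp[EXPENDITURE_COLUMNS[1:]].isna().any(axis=1)
        exp_missing = pid.map(exp_missing_any).fillna(True).astype(bool)
        freq = cohort.frequencies.set_index("person_id")
        freq_missing_any = freq[FREQUENCY_COLUMNS[1:]].isna().any(axis=1)
        freq_missing = pid.map(freq_missing_any).fillna(True).astype(bool)
        return income_missing | exp_missing | freq_missing
    if criterion == "missing_education":
        return persons["education"].isna()
    raise ConfigError(f"unknown exclusion criterion: {criterion!r}")


def apply_exclusions(cohort: Cohort, criteria: Sequence[str] | None = None) -> tuple[Cohort, ExclusionLog]:
    """Apply the ordered exclusion cascade and account for every removal.

    Each person is removed at the first criterion they meet; the log's
    per-criterion counts are therefore disjoint and sum to
    ``initial_n - final_n``.
    """
    criteria = list(criteria) if criteria is not None else list(EXCLUSION_ORDER)
    log = ExclusionLog(initial_n=cohort.n)
    current = cohort
    for criterion in criteria:
        mask = _criterion_mask(current, criterion)
        n_removed = int(mask.sum())
        log.steps.append((criterion, n_removed))
        if n_removed:
            keep_ids = current.persons.loc[~mask.to_numpy(), "person_id"]
            current = current.subset(keep_ids)
    return current, log


def replay_exclusion_counts(initial_n: int, removals: Sequence[int]) -> int:
    """Arithmetic identity of a printed cascade: initial n minus each step."""
    removals = list(removals)
    if any(r < 0 for r in removals):
        raise ConfigError("removal counts must be non-negative")
    final = initial_n - int(np.sum(removals))
    if final < 0:
        raise ConfigError("cascade removes more persons than the initial sample")
    return final
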