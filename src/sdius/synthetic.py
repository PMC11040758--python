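"""Seeded generator of survey-style cohorts for exercising the index.

The generator emulates the *statistical structure* a national dietary
survey hands the index: correlated energy/nutrient intakes (lognormal,
conditioned on energy so residual energy adjustment has signal to
remove), food items drawn from the 43 environmental food groups plus
unmatchable mixed dishes, right-skewed food budget shares, zero-inflated
ready-made-food frequencies, survey weights with strata and paired PSUs,
and a single latent diet-quality factor that loads positively on the
nutritional indicators and negatively on footprints, budget share and
frequencies.  A planted diet-quality shift for older adults gives the
group-contrast machinery a known truth to recover.  It makes no attempt
to match any real survey cycle's marginal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError
from .resources import load_crosswalk, load_food_group_map, load_income_bands

# ------------------------------------------------------------- parameters

#: Nutrient generation model: density per 1000 kcal and the loading of
#: the latent diet-quality factor (positive = more with better diets).
NUTRIENT_MODEL: Mapping[str, tuple[float, float]] = {
    "protein_g": (38.0, 0.10),
    "fiber_g": (8.0, 0.30),
    "vitamin_a_ug": (300.0, 0.30),
    "vitamin_c_mg": (35.0, 0.35),
    "vitamin_e_mg": (3.5, 0.25),
    "calcium_mg": (450.0, 0.20),
    "iron_mg": (6.5, 0.20),
    "magnesium_mg": (140.0, 0.25),
    "potassium_mg": (1250.0, 0.25),
    "sat_fat_g": (13.0, -0.20),
    "added_sugar_g": (30.0, -0.30),
    "sodium_mg": (1700.0, -0.15),
    "thiamin_mg": (0.75, 0.20),
    "vitamin_b6_mg": (0.90, 0.25),
    "folate_ug": (250.0, 0.25),
    "zinc_mg": (5.5, 0.20),
    "copper_mg": (0.60, 0.20),
    "mufa_g": (13.0, 0.05),
}

#: Direction in which the latent factor tilts food-group choice.
PLANT_GROUPS = {
    "maize_products", "oatmeal", "other_pulses", "peas", "nuts", "groundnuts",
    "soymilk", "tofu", "tomatoes", "onions_leeks", "root_vegetables", "brassicas",
    "other_vegetables", "citrus_fruit", "bananas", "apples", "berries_grapes", "other_fruit",
}
ANIMAL_GROUPS = {
    "beef_beef_herd", "beef_dairy_herd", "lamb_mutton", "pig_meat", "poultry_meat",
    "eggs", "milk", "cheese", "fish_farmed", "crustaceans_farmed",
}

RACE_LEVELS = ["nh_white", "nh_black", "hispanic", "other"]
EDUCATION_LEVELS = ["less_than_hs", "hs_grad", "some_college", "college_plus"]


@dataclass
class SimulationParams:
    """Knobs of the generative model (defaults are the study conditions)."""

    n: int = 1000
    seed: int = 0
    prop_female: float = 0.52
    age_min: int = 20
    age_max: int = 85
    race_probs: tuple[float, ...] = (0.63, 0.12, 0.17, 0.08)
    education_probs: tuple[float, ...] = (0.15, 0.25, 0.30, 0.30)
    n_strata: int = 15
    weight_log_sd: float = 0.4
    energy_median_kcal: float = 2050.0
    energy_log_sd: float = 0.28
    nutrient_log_sd: float = 0.25
    quality_sd: float = 1.0
    older_quality_shift: float = 0.8  # latent shift for ages >= 60
    older_age: int = 60
    mean_items: float = 11.0
    match_rate: float = 0.4
    group_tilt: float = 0.35
    serving_shape: float = 2.0
    serving_scale: float = 0.5
    income_band_probs: tuple[float, ...] = (
        0.02, 0.03, 0.05, 0.05, 0.06, 0.09, 0.09, 0.09, 0.08, 0.08, 0.14, 0.22,
    )
    budget_share_median: float = 20.0
    budget_share_log_sd: float = 0.65
    budget_share_quality_load: float = -0.15
    zero_inflation: tuple[float, float, float] = (0.45, 0.50, 0.50)
    freq_nonzero_means: tuple[float, float, float] = (3.0, 4.0, 5.4)
    freq_quality_load: float = -0.25
    alcohol_zero_prob: float = 0.70

    def validate(self) -> None:
        for name, probs in (
            ("race_probs", self.race_probs),
            ("education_probs", self.education_probs),
            ("income_band_probs", self.income_band_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if not (0.0 <= self.match_rate <= 1.0):
            raise ConfigError("match_rate must lie in [0, 1]")
        if any(not (0.0 <= p <= 1.0) for p in self.zero_inflation):
            raise ConfigError("zero-inflation probabilities must lie in [0, 1]")
        if self.n < 1:
            raise ConfigError("n must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    quality: pd.DataFrame  # person_id, latent diet-quality factor
    planted_effects: dict = field(default_factory=dict)


# -------------------------------------------------------------- generator


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: SimulationParams | None = None, **overrides) -> tuple[Cohort, GroundTruth]:
    """Generate the five cohort tables plus the ground-truth ledger.

    The same ``(params, seed)`` always yields byte-identical tables.
    """
    params = replace(params or SimulationParams(), **overrides)
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    pid = np.array([f"P{i:06d}" for i in range(1, n + 1)])

    # --- demographics and survey design
    sex = np.where(rng.random(n) < params.prop_female, "female", "male")
    age = rng.integers(params.age_min, params.age_max + 1, size=n)
    race = rng.choice(RACE_LEVELS, size=n, p=params.race_probs)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=params.education_probs)
    household = rng.integers(1, 7, size=n)
    stratum = rng.integers(1, params.n_strata + 1, size=n)
    psu = rng.integers(1, 3, size=n)
    weight = np.exp(rng.normal(0.0, params.weight_log_sd, size=n)) * 1000.0

    # --- latent diet quality with the planted age shift
    quality = rng.normal(0.0, params.quality_sd, size=n)
    older = age >= params.older_age
    quality = quality + params.older_quality_shift * older

    # --- energy and nutrients (lognormal, conditioned on energy)
    log_energy = rng.normal(np.log(params.energy_median_kcal), params.energy_log_sd, size=n)
    log_energy += np.where(sex == "male", 0.12, -0.12)
    energy = np.clip(np.exp(log_energy), 500.0, 6000.0)

    nutrients = pd.DataFrame({"person_id": pid, "energy_kcal": energy})
    for nutrient, (density, load) in NUTRIENT_MODEL.items():
        noise = rng.normal(0.0, params.nutrient_log_sd, size=n)
        nutrients[nutrient] = density * (energy / 1000.0) * np.exp(noise + load * quality)
    alcohol = np.where(
        rng.random(n) < params.alcohol_zero_prob,
        0.0,
        np.exp(rng.normal(np.log(10.0), 0.7, size=n)),
    )
    nutrients["alcohol_g"] = alcohol

    serum = np.clip(rng.normal(60.0 + 7.0 * quality, 16.0, size=n), 8.0, 250.0)

    # --- intake items over the 43 groups plus unmatchable mixed dishes
    crosswalk = load_crosswalk()
    group_map = load_food_group_map().set_index("group")
    groups = crosswalk["group"].unique()
    tilt_sign = np.array([1.0 if g in PLANT_GROUPS else -1.0 if g in ANIMAL_GROUPS else 0.0 for g in groups])
    codes_by_group = {g: crosswalk.loc[crosswalk["group"] == g, "food_code"].to_numpy() for g in groups}

    n_items = 1 + rng.poisson(params.mean_items - 1.0, size=n)
    person_idx = np.repeat(np.arange(n), n_items)
    total_rows = len(person_idx)
    matched = rng.random(total_rows) < params.match_rate

    logits = params.group_tilt * quality[person_idx][:, None] * tilt_sign[None, :]
    gumbel = rng.gumbel(size=(total_rows, len(groups)))
    choice = np.argmax(logits + gumbel, axis=1)
    chosen_groups = groups[choice]

    pick = rng.integers(0, 2, size=total_rows)
    codes = np.where(
        matched,
        [codes_by_group[g][j] for g, j in zip(chosen_groups, pick)],
        [f"99{1 + (c % 40):06d}" for c in rng.integers(0, 40, size=total_rows)],
    )
    descriptions = np.where(matched, chosen_groups, "mixed dish (not matchable)")
    servings = rng.gamma(params.serving_shape, params.serving_scale, size=total_rows)
    gram_factors = np.array([group_map.loc[g, "grams_per_serving"] for g in chosen_groups])
    grams = servings * np.where(matched, gram_factors, 180.0) * rng.uniform(0.85, 1.15, size=total_rows)

    intake = pd.DataFrame(
        {
            "person_id": pid[person_idx],
            "food_code": codes,
            "description": descriptions,
            "servings": servings,
            "grams": grams,
        }
    )

    # --- income, expenditures (right-skewed budget share)
    bands = load_income_bands()
    band_labels = bands["label"].to_numpy()
    income_cat = rng.choice(band_labels, size=n, p=params.income_band_probs)
    proxy = {
        row.label: (float(row.proxy) if not pd.isna(row.proxy) else (float(row.lower) + float(row.upper)) / 2.0)
        for row in bands.itertuples(index=False)
    }
    income_dollars = np.array([proxy[c] for c in income_cat])
    share = np.exp(
        rng.normal(np.log(params.budget_share_median), params.budget_share_log_sd, size=n)
        + params.budget_share_quality_load * quality
    )
    monthly_total = share / 100.0 * income_dollars / 12.0
    split = rng.dirichlet((5.0, 1.0, 3.0, 1.5), size=n)
    expenditure = pd.DataFrame(
        {
            "person_id": pid,
            "supermarket_month": monthly_total * split[:, 0],
            "other_store_month": monthly_total * split[:, 1],
            "eating_out_month": monthly_total * split[:, 2],
            "carryout_month": monthly_total * split[:, 3],
        }
    )

    # --- zero-inflated ready-made-food frequencies
    caps = (21, 90, 90)
    freq_cols = {}
    for j, (col, p0, mean_nz, cap) in enumerate(
        zip(
            ["fastfood_meals_7d", "ready_to_eat_30d", "frozen_30d"],
            params.zero_inflation,
            params.freq_nonzero_means,
            caps,
        )
    ):
        if p0 <= 0.0 or p0 >= 1.0:
            p_zero = np.full(n, float(p0))
        else:
            p_zero = _sigmoid(np.log(p0 / (1 - p0)) - params.freq_quality_load * quality)
        is_zero = rng.random(n) < p_zero
        counts = 1 + rng.poisson(np.maximum(mean_nz * np.exp(params.freq_quality_load * quality) - 1.0, 0.05))
        freq_cols[col] = np.where(is_zero, 0, np.minimum(counts, cap))
    frequencies = pd.DataFrame({"person_id": pid, **freq_cols})

    persons = pd.DataFrame(
        {
            "person_id": pid,
            "age_years": age,
            "sex": sex,
            "race_ethnicity": race,
            "education": education,
            "household_size": household,
            "pregnant_or_breastfeeding": False,
            "income_category": income_cat,
            "serum_25ohd": serum,
            "weight": weight,
            "stratum": stratum,
            "psu": psu,
        }
    )

    cohort = Cohort(
        persons=persons,
        intake=intake,
        nutrients=nutrients,
        expenditure=expenditure,
        frequencies=frequencies,
    )
    truth = GroundTruth(
        quality=pd.DataFrame({"person_id": pid, "quality": quality}),
        planted_effects={"older_quality_shift": params.older_quality_shift, "older_age": params.older_age},
    )
    return cohort, truth


# -------------------------------------------------------- planted dropout


def plant_missingness(cohort: Cohort, counts: Mapping[str, int], seed: int = 0) -> Cohort:
    """Make exactly the requested number of persons excludable per criterion.

    Persons are chosen disjointly so the exclusion cascade's sequential
    counts equal the planted counts exactly.  Criterion labels follow
    ``cohort.EXCLUSION_ORDER``.
    """
    from .cohort import EXCLUSION_ORDER

    unknown = set(counts) - set(EXCLUSION_ORDER)
    if unknown:
        raise ConfigError(f"unknown exclusion criteria: {sorted(unknown)}")
    total = sum(counts.values())
    if total > cohort.n:
        raise ConfigError(f"cannot plant {total} missing persons in a cohort of {cohort.n}")

    rng = np.random.default_rng(seed)
    persons = cohort.persons.copy()
    nutrients = cohort.nutrients.copy()
    expenditure = cohort.expenditure.copy()
    frequencies = cohort.frequencies.copy()
    chosen = rng.choice(persons.index.to_numpy(), size=total, replace=False)
    cursor = 0
    component_cycle = 0
    for criterion in EXCLUSION_ORDER:
        k = counts.get(criterion, 0)
        idx = chosen[cursor : cursor + k]
        cursor += k
        if k == 0:
            continue
        ids = persons.loc[idx, "person_id"]
        if criterion == "pregnant_or_breastfeeding":
            persons.loc[idx, "pregnant_or_breastfeeding"] = True
        elif criterion == "incomplete_recall":
            nutrients = nutrients[~nutrients["person_id"].isin(set(ids))].reset_index(drop=True)
        elif criterion == "missing_25ohd":
            persons.loc[idx, "serum_25ohd"] = np.nan
        elif criterion == "missing_sdi_components":
            # rotate which component goes missing, for variety
            for i in idx:
                pid_i = persons.loc[i, "person_id"]
                which = component_cycle % 3
                component_cycle += 1
                if which == 0:
                    persons.loc[i, "income_category"] = np.nan
                elif which == 1:
                    expenditure.loc[expenditure["person_id"] == pid_i, "eating_out_month"] = np.nan
                else:
                    frequencies.loc[frequencies["person_id"] == pid_i, "frozen_30d"] = np.nan
        elif criterion == "missing_education":
            persons.loc[idx, "education"] = np.nan
    return Cohort(
        persons=persons,
        intake=cohort.intake,
        nutrients=nutrients,
        expenditure=expenditure,
        frequencies=frequencies,
    )
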