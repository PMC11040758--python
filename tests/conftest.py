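import pandas as pd
import pytest

from sdius.pipeline import RunConfig, run_pipeline
from sdius.synthetic import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized synthetic cohort shared by read-only tests."""
    cohort, truth = generate_cohort(SimulationParams(n=400, seed=11))
    return cohort


@pytest.fixture(scope="session")
def truth():
    _, truth = generate_cohort(SimulationParams(n=400, seed=11))
    return truth


@pytest.fixture(scope="session")
def fixed_result(cohort):
    return run_pipeline(cohort, RunConfig(scoring_mode="fixed"))


@pytest.fixture(scope="session")
def derive_result(cohort):
    return run_pipeline(cohort, RunConfig(scoring_mode="derive"))


@pytest.fixture()
def tiny_cohort_dir(tmp_path):
    """Three handwritten persons with linked child rows, written as CSVs."""
    persons = pd.DataFrame(
        {
            "person_id": ["A", "B", "C"],
            "age_years": [25, 44, 67],
            "sex": ["female", "male", "female"],
            "race_ethnicity": ["nh_white", "hispanic", "nh_black"],
            "education": ["college_plus", "hs_grad", "some_college"],
            "household_size": [2, 4, 1],
            "pregnant_or_breastfeeding": [False, False, False],
            "income_category": ["25000-34999", "75000-99999", "100000+"],
            "serum_25ohd": [55.0, 62.5, 48.0],
            "weight": [1000.0, 1500.0, 800.0],
            "stratum": [1, 1, 2],
            "psu": [1, 2, 1],
        }
    )
    intake = pd.DataFrame(
        {
            "person_id": ["A", "A", "B", "C"],
            "food_code": ["11000101", "99000001", "11003201", "11002001"],
            "description": ["bread", "mixed dish", "beef", "tomato"],
            "servings": [1.0, 2.0, 1.5, 0.5],
            "grams": [50.0, 300.0, 127.5, 60.0],
        }
    )
    nutrients = pd.DataFrame(
        {
            "person_id": ["A", "B", "C"],
            "energy_kcal": [1800.0, 2600.0, 1600.0],
            "protein_g": [70.0, 95.0, 55.0],
            "fiber_g": [18.0, 14.0, 22.0],
            "vitamin_a_ug": [600.0, 450.0, 700.0],
            "vitamin_c_mg": [70.0, 40.0, 95.0],
            "vitamin_e_mg": [8.0, 6.0, 10.0],
            "calcium_mg": [900.0, 1100.0, 800.0],
            "iron_mg": [12.0, 16.0, 10.0],
            "magnesium_mg": [280.0, 330.0, 300.0],
            "potassium_mg": [2600.0, 2900.0, 3100.0],
            "sat_fat_g": [20.0, 35.0, 15.0],
            "added_sugar_g": [40.0, 80.0, 25.0],
            "sodium_mg": [3000.0, 4200.0, 2400.0],
            "thiamin_mg": [1.3, 1.6, 1.1],
            "vitamin_b6_mg": [1.5, 1.9, 1.4],
            "folate_ug": [380.0, 420.0, 350.0],
            "zinc_mg": [9.0, 12.0, 8.0],
            "copper_mg": [1.1, 1.3, 0.9],
        }
    )
    expenditure = pd.DataFrame(
        {
            "person_id": ["A", "B", "C"],
            "supermarket_month": [300.0, 450.0, 250.0],
            "other_store_month": [40.0, 60.0, 20.0],
            "eating_out_month": [120.0, 200.0, 90.0],
            "carryout_month": [40.0, 90.0, 15.0],
        }
    )
    frequencies = pd.DataFrame(
        {
            "person_id": ["A", "B", "C"],
            "fastfood_meals_7d": [2, 5, 0],
            "ready_to_eat_30d": [1, 8, 0],
            "frozen_30d": [3, 10, 0],
        }
    )
    for name, frame in {
        "persons.csv": persons,
        "intake_items.csv": intake,
        "nutrients.csv": nutrients,
        "expenditure.csv": expenditure,
        "frequencies.csv": frequencies,
    }.items():
        frame.to_csv(tmp_path / name, index=False)
    return tmp_path
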