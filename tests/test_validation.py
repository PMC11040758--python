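"""Survey-weighted estimation, comparison scores and agreement metrics."""

import numpy as np
import pandas as pd
import pytest

from sdius.errors import DegenerateDesignError, DomainError
from sdius.resources import load_crosswalk, load_eat_lancet_criteria
from sdius.validation import (
    AMED_COMPONENTS,
    agreement_report,
    amed_score,
    cross_classification,
    dga_food_groups,
    eat_lancet_score,
    group_contrast,
    quantile_classes,
    weighted_kappa,
    weighted_mean_se,
    weighted_pearson,
)


# ------------------------------------------------------ design estimation


def test_weighted_mean_se_reduces_to_textbook_formula():
    rng = np.random.default_rng(0)
    y = rng.normal(10, 2, 60)
    est = weighted_mean_se(y, np.ones(60), np.ones(60), np.arange(60))
    assert est.estimate == pytest.approx(y.mean())
    assert est.se == pytest.approx(y.std(ddof=1) / np.sqrt(60))
    assert est.df == 59


def test_weighted_mean_degenerate_cases():
    y = np.array([3.0, 8.0, 1.0])
    w = np.array([0.0, 5.0, 0.0])
    est = weighted_mean_se(y, w, np.ones(3), np.arange(3))
    assert est.estimate == 8.0
    const = weighted_mean_se(np.full(10, 4.2), np.ones(10), np.ones(10), np.arange(10))
    assert const.se == 0.0


def test_single_psu_stratum_strategies():
    y = np.arange(6.0)
    w = np.ones(6)
    stratum = np.array([1, 1, 2, 2, 3, 3])
    psu = np.array([1, 2, 1, 2, 1, 1])  # stratum 3 has one PSU
    with pytest.raises(DegenerateDesignError):
        weighted_mean_se(y, w, stratum, psu, single_psu="error")
    est = weighted_mean_se(y, w, stratum, psu, single_psu="collapse")
    assert np.isfinite(est.se)


def test_weighted_pearson_oracle_and_affine_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = 0.6 * x + rng.normal(size=200)
    assert weighted_pearson(x, 2 * x + 1) == pytest.approx(1.0)
    assert weighted_pearson(x, -x) == pytest.approx(-1.0)
    assert weighted_pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])
    assert weighted_pearson(3 * x - 2, y) == pytest.approx(weighted_pearson(x, y))
    with pytest.raises(DomainError):
        weighted_pearson(x, np.zeros(200))


def test_group_contrast_identical_groups_and_planted_shift():
    rng = np.random.default_rng(2)
    y = rng.normal(10, 1, 400)
    g = np.arange(400) % 2 == 0
    stratum = np.repeat(np.arange(20), 20)
    psu = np.tile(np.repeat([1, 2], 10), 20)
    ea, eb, diff, se, p = group_contrast(y, g, np.ones(400), stratum, psu)
    assert diff == pytest.approx(ea.estimate - eb.estimate)
    y2 = y + 1.0 * g
    *_, diff2, se2, p2 = group_contrast(y2, g, np.ones(400), stratum, psu)
    assert diff2 == pytest.approx(diff + 1.0)
    assert p2 < 0.001


def test_permuted_labels_reject_at_nominal_rate():
    rng = np.random.default_rng(3)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        y = rng.normal(size=120)
        g = rng.permutation(np.arange(120) % 2 == 0)
        stratum = np.repeat(np.arange(10), 12)
        psu = np.tile(np.repeat([1, 2], 6), 10)
        *_, p = group_contrast(y, g, np.ones(120), stratum, psu)
        rejections += p < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.04)


# ------------------------------------------------------ comparison scores


def _components(**over):
    base = {c: 1.0 for c in AMED_COMPONENTS}
    base.update(over)
    return base


def test_amed_extremes():
    medians = {c: 1.0 for c in AMED_COMPONENTS}
    best = _components(red_processed_meat=0.0, alcohol=10.0)
    assert amed_score(best, medians) == 9
    worst = _components(
        vegetables=0.0, legumes=0.0, fruits=0.0, whole_grains=0.0, nuts=0.0,
        fish=0.0, mufa_sfa_ratio=0.0, red_processed_meat=2.0, alcohol=0.0,
    )
    assert amed_score(worst, medians) == 0


def test_amed_random_profiles_match_enumeration_oracle():
    rng = np.random.default_rng(4)
    medians = {c: 1.0 for c in AMED_COMPONENTS}
    for _ in range(300):
        comp = {c: float(rng.uniform(0, 2)) for c in AMED_COMPONENTS}
        expected = (
            sum(comp[c] >= 1.0 for c in AMED_COMPONENTS[:-2])
            + (comp["red_processed_meat"] < 1.0)
            + (5.0 <= comp["alcohol"] <= 25.0)
        )
        assert amed_score(comp, medians) == expected


def test_amed_missing_component_raises():
    medians = {c: 1.0 for c in AMED_COMPONENTS}
    with pytest.raises(DomainError, match="fish"):
        amed_score({c: 1.0 for c in AMED_COMPONENTS if c != "fish"}, medians)


def test_eat_lancet_extremes_and_oracle():
    criteria = load_eat_lancet_criteria()
    all_met = {}
    none_met = {}
    for row in criteria.itertuples(index=False):
        if row.direction == "ge":
            all_met[row.component] = row.threshold + 1
            none_met[row.component] = max(row.threshold - 1, 0)
        else:
            all_met[row.component] = max(row.threshold - 1, 0)
            none_met[row.component] = row.threshold + 1
    assert eat_lancet_score(all_met, criteria) == 14
    assert eat_lancet_score(none_met, criteria) == 0

    rng = np.random.default_rng(5)
    for _ in range(300):
        comp = {r.component: float(rng.uniform(0, 2 * max(r.threshold, 1))) for r in criteria.itertuples(index=False)}
        expected = sum(
            (comp[r.component] >= r.threshold) if r.direction == "ge" else (comp[r.component] <= r.threshold)
            for r in criteria.itertuples(index=False)
        )
        assert eat_lancet_score(comp, criteria) == expected


def test_dga_roll_up_identity_and_additivity():
    crosswalk = load_crosswalk()
    brassica_code = crosswalk.loc[crosswalk["group"] == "brassicas", "food_code"].iloc[0]
    one_item = pd.DataFrame(
        {"person_id": ["P1"], "food_code": [brassica_code], "servings": [1.0]}
    )
    wide = dga_food_groups(one_item, crosswalk)
    assert wide["dark_green_vegetables"].iloc[0] == 1.0
    assert wide["total_vegetables"].iloc[0] == 1.0

    doubled = pd.concat([one_item, one_item], ignore_index=True)
    wide2 = dga_food_groups(doubled, crosswalk)
    assert wide2["total_vegetables"].iloc[0] == 2.0


# ------------------------------------------------------------- agreement


def test_quantile_classes_exact_split_and_tie_rule():
    scores = np.arange(100, dtype=float)
    classes = quantile_classes(scores, np.ones(100), 5)
    assert np.bincount(classes)[1:].tolist() == [20, 20, 20, 20, 20]
    # ties at a boundary fall in the lower class, deterministically
    tied = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    cls = quantile_classes(tied, np.ones(6), 5)
    assert cls[0] == cls[1]


def test_cross_classification_identity_and_reversal():
    a = np.repeat(np.arange(1, 6), 20)
    report = cross_classification(a, a, 5)
    assert report["pct_same_class"] == 100.0
    assert report["pct_gross_misclassified"] == 0.0
    assert report["performance"] == "good"

    reversed_ = 6 - a
    rep2 = cross_classification(a, reversed_, 5)
    assert rep2["pct_gross_misclassified"] == pytest.approx(40.0)
    assert rep2["pct_same_class"] == pytest.approx(20.0)  # the middle class maps to itself
    assert rep2["performance"] == "poor"


def test_cross_classification_independent_assignments():
    rng = np.random.default_rng(6)
    a = rng.integers(1, 6, 20_000)
    b = rng.integers(1, 6, 20_000)
    rep = cross_classification(a, b, 5)
    assert rep["pct_same_class"] == pytest.approx(20.0, abs=1.5)


def test_kappa_identities():
    rng = np.random.default_rng(7)
    a = rng.integers(1, 6, 500)
    kap, band = weighted_kappa(a, a)
    assert kap == pytest.approx(1.0)
    assert band == "good"
    b = rng.integers(1, 6, 500)
    k_ab, _ = weighted_kappa(a, b)
    k_ba, _ = weighted_kappa(b, a)
    assert k_ab == pytest.approx(k_ba)


def test_kappa_near_zero_under_independence():
    rng = np.random.default_rng(8)
    a = rng.integers(1, 6, 50_000)
    b = rng.integers(1, 6, 50_000)
    for scheme in ("linear", "quadratic"):
        kap, band = weighted_kappa(a, b, weight_scheme=scheme)
        assert abs(kap) < 0.02
        assert band == "poor"


def test_kappa_small_matrix_closed_form_oracle():
    # hand-computable 2x2 confusion: 40 agree on class 1, 40 on class 2,
    # 10 + 10 disagreements; linear weights on 2 classes = plain kappa:
    # po = 0.8, pe = 0.5, kappa = (0.8 - 0.5) / 0.5 = 0.6
    a = np.array([1] * 50 + [2] * 50)
    b = np.array([1] * 40 + [2] * 10 + [1] * 10 + [2] * 40)
    kap, band = weighted_kappa(a, b, weight_scheme="linear")
    assert kap == pytest.approx(0.6)
    assert band == "acceptable"


def test_kappa_degenerate_single_class():
    with pytest.raises(DegenerateDesignError):
        weighted_kappa(np.ones(10, dtype=int), np.ones(10, dtype=int))


def test_agreement_report_bundle():
    a = np.repeat(np.arange(1, 6), 10)
    rep = agreement_report(a, a, 5)
    assert rep.kappa == pytest.approx(1.0)
    assert rep.pct_same_class == 100.0
    assert rep.pct_same_class <= rep.pct_same_or_adjacent
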