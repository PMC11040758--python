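"""Survey-weighted statistics and the index validation battery.

Design-based estimation follows the ultimate-cluster Taylor
linearization: per-person weights, strata and first-stage PSUs give
variances from between-PSU variation within strata, with
``df = (#PSUs - #strata)``.  On top of that sit the validity checks a
composite diet index needs: weighted Pearson correlations, subgroup
contrasts, comparison diet scores (aMed, EAT-Lancet), DGA food-group
roll-ups, weighted quantile classes, cross-classification and weighted
kappa agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateDesignError, DomainError
from .resources import load_eat_lancet_criteria, load_food_group_map

# ------------------------------------------------- design-based estimation


@dataclass
class WeightedEstimate:
    estimate: float
    se: float
    df: int


def _prepare_design(stratum, psu, single_psu: str):
    stratum = np.asarray(stratum)
    psu = np.asarray(psu)
    # object dtype: collapsed strata get string labels below
    frame = pd.DataFrame({"stratum": pd.Series(stratum, dtype=object), "psu": pd.Series(psu, dtype=object)})
    psu_counts = frame.groupby("stratum")["psu"].nunique()
    singles = psu_counts[psu_counts < 2].index
    if len(singles):
        if single_psu == "error":
            raise DegenerateDesignError(f"strata with a single PSU: {list(singles)[:5]}")
        if single_psu != "collapse":
            raise DomainError(f"unknown single-PSU strategy {single_psu!r}")
        # Pool all singleton strata into one synthetic stratum; if that pool
        # is itself a single PSU, merge it into the largest proper stratum.
        mask = frame["stratum"].isin(singles)
        frame.loc[mask, "stratum"] = "__collapsed__"
        frame.loc[mask, "psu"] = [f"{s}:{p}" for s, p in zip(stratum[mask], psu[mask])]
        if frame.loc[frame["stratum"] == "__collapsed__", "psu"].nunique() < 2:
            proper = psu_counts[psu_counts >= 2]
            if proper.empty:
                raise DegenerateDesignError("no stratum has two PSUs; variance not estimable")
            frame.loc[mask, "stratum"] = proper.index[0]
    return frame["stratum"].to_numpy(), frame["psu"].to_numpy()


def _linearized_variance(u: np.ndarray, stratum, psu) -> tuple[float, int]:
    """Variance of a total sum(u) under with-replacement PSU sampling."""
    frame = pd.DataFrame({"u": u, "stratum": stratum, "psu": psu})
    psu_totals = frame.groupby(["stratum", "psu"], sort=False)["u"].sum()
    var = 0.0
    n_psu = 0
    n_strata = 0
    for _, tot in psu_totals.groupby(level="stratum", sort=False):
        n_h = len(tot)
        n_psu += n_h
        n_strata += 1
        if n_h >= 2:
            var += n_h / (n_h - 1) * float(((tot - tot.mean()) ** 2).sum())
    return var, n_psu - n_strata


def weighted_mean_se(values, weights, stratum, psu, single_psu: str = "collapse") -> WeightedEstimate:
    """Survey-weighted mean with a Taylor-linearized standard error.

    With equal weights and a saturated design (one stratum, each unit
    its own PSU) this reduces to the textbook mean and ``s/sqrt(n)``.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise DomainError("survey weights must be >= 0")
    stratum, psu = _prepare_design(stratum, psu, single_psu)
    total_w = w.sum()
    ybar = float(np.sum(w * y) / total_w)
    u = w * (y - ybar) / total_w
    var, df = _linearized_variance(u, stratum, psu)
    return WeightedEstimate(estimate=ybar, se=float(np.sqrt(var)), df=df)


def weighted_pearson(x, y, weights=None) -> float:
    """Weighted product-moment correlation (plain Pearson when unweighted)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx == 0 or vy == 0:
        raise DomainError("correlation undefined: zero variance input")
    return float(cov / np.sqrt(vx * vy))


def group_contrast(values, group, weights, stratum, psu, single_psu: str = "collapse"):
    """Design-based comparison of two subgroup means.

    ``group`` is a boolean/binary label; returns the two weighted
    estimates, their difference, the linearized SE of the difference and
    a two-sided p-value from the t distribution with design df.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group).astype(bool)
    w = np.asarray(weights, dtype=float)
    if g.all() or (~g).all():
        raise DomainError("both groups must be non-empty")
    stratum, psu = _prepare_design(stratum, psu, single_psu)

    est = {}
    for label, mask in (("a", g), ("b", ~g)):
        wm = w * mask
        est[label] = float(np.sum(wm * y) / np.sum(wm))
    w1 = float(np.sum(w[g]))
    w0 = float(np.sum(w[~g]))
    u = w * (g * (y - est["a"]) / w1 - (~g) * (y - est["b"]) / w0)
    var, df = _linearized_variance(u, stratum, psu)
    diff = est["a"] - est["b"]
    se = float(np.sqrt(var))
    if se == 0:
        p = 0.0 if diff != 0 else 1.0
        t = np.inf if diff != 0 else 0.0
    else:
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), df=max(df, 1)))
    ea = WeightedEstimate(est["a"], float("nan"), df)
    eb = WeightedEstimate(est["b"], float("nan"), df)
    return ea, eb, float(diff), se, p


# -------------------------------------------------- comparison diet scores

AMED_BENEFICIAL = ["vegetables", "legumes", "fruits", "whole_grains", "nuts", "fish", "mufa_sfa_ratio"]
AMED_COMPONENTS = AMED_BENEFICIAL + ["red_processed_meat", "alcohol"]


def amed_score(
    components: Mapping[str, float],
    medians: Mapping[str, float],
    alcohol_range: tuple[float, float] = (5.0, 25.0),
) -> int:
    """Alternative Mediterranean diet score (0-9).

    One point per beneficial component (vegetables, legumes, fruits,
    whole grains, nuts, fish, MUFA:SFA ratio) at or above its reference
    median; one point for red/processed meat strictly below its median;
    one point for alcohol inside the moderate range (g/day, inclusive).
    """
    missing = [c for c in AMED_COMPONENTS if c not in components]
    if missing:
        raise DomainError(f"aMed components missing: {missing}")
    score = 0
    for comp in AMED_BENEFICIAL:
        if components[comp] >= medians[comp]:
            score += 1
    if components["red_processed_meat"] < medians["red_processed_meat"]:
        score += 1
    lo, hi = alcohol_range
    if lo <= components["alcohol"] <= hi:
        score += 1
    return score


def eat_lancet_score(components: Mapping[str, float], criteria: pd.DataFrame | None = None) -> int:
    """EAT-Lancet diet score (0-14): one point per criterion met.

    ``criteria`` rows carry a component name, a direction (``ge``/``le``)
    and a threshold in grams/day (or a dimensionless ratio for the
    added-fats criterion); amounts are compared inclusively.
    """
    if criteria is None:
        criteria = load_eat_lancet_criteria()
    score = 0
    for row in criteria.itertuples(index=False):
        if row.component not in components:
            raise DomainError(f"EAT-Lancet component missing: {row.component!r}")
        value = float(components[row.component])
        threshold = float(row.threshold)
        if row.direction == "ge":
            score += int(value >= threshold)
        elif row.direction == "le":
            score += int(value <= threshold)
        else:
            raise DataError(f"unknown criterion direction {row.direction!r}")
    return score


def dga_food_groups(
    intake: pd.DataFrame,
    crosswalk: pd.DataFrame,
    group_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-person daily servings rolled up into DGA food groups.

    Unmatched food codes (absent from the crosswalk) are dropped from
    the roll-up, mirroring the footprint accounting.  Adds roll-up
    totals for vegetables, grains and protein foods.
    """
    if group_map is None:
        group_map = load_food_group_map()
    mapping = crosswalk.set_index("food_code")["group"]
    work = intake[["person_id", "food_code", "servings"]].copy()
    work["group"] = work["food_code"].astype(str).map(mapping)
    work = work.dropna(subset=["group"])
    work = work.merge(group_map[["group", "dga_group"]], on="group", how="left")
    if work["dga_group"].isna().any():
        unknown = work.loc[work["dga_group"].isna(), "group"].unique()[:5]
        raise DataError(f"food groups not in the DGA map: {list(unknown)}")
    wide = (
        work.pivot_table(index="person_id", columns="dga_group", values="servings", aggfunc="sum", fill_value=0.0)
        .reset_index()
    )
    for col in load_food_group_map()["dga_group"].unique():
        if col not in wide.columns:
            wide[col] = 0.0
    veg = ["dark_green_vegetables", "red_orange_vegetables", "legumes", "starchy_vegetables", "other_vegetables"]
    wide["total_vegetables"] = wide[veg].sum(axis=1)
    wide["total_grains"] = wide[["whole_grains", "refined_grains"]].sum(axis=1)
    protein = ["meats", "poultry", "eggs", "seafood", "nuts_seeds", "soy_products"]
    wide["total_protein_foods"] = wide[protein].sum(axis=1)
    return wide


def diet_components(
    intake: pd.DataFrame,
    nutrients: pd.DataFrame,
    crosswalk: pd.DataFrame,
    group_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-person component amounts for the aMed and EAT-Lancet scores.

    Food-based components come from matched intake items via the food
    group map (grams = servings x grams-per-serving); the fat-quality
    ratio, alcohol and added sugar come from the nutrient totals.
    """
    if group_map is None:
        group_map = load_food_group_map()
    mapping = crosswalk.set_index("food_code")["group"]
    work = intake[["person_id", "food_code", "servings"]].copy()
    work["group"] = work["food_code"].astype(str).map(mapping)
    work = work.dropna(subset=["group"])
    work = work.merge(group_map, on="group", how="left")
    work["grams"] = work["servings"] * work["grams_per_serving"]

    frames = {}
    for target in ("amed_component", "eat_lancet_component"):
        sub = work.dropna(subset=[target])
        frames[target] = sub.pivot_table(
            index="person_id", columns=target, values="grams", aggfunc="sum", fill_value=0.0
        )

    out = nutrients[["person_id"]].copy().set_index("person_id")
    for target, frame in frames.items():
        out = out.join(frame, how="left")
    out = out.fillna(0.0)

    nut = nutrients.set_index("person_id")
    sat = nut["sat_fat_g"].astype(float)
    mufa = nut.get("mufa_g", pd.Series(0.0, index=nut.index)).astype(float)
    ratio = np.where(sat > 0, mufa / sat, np.inf)
    out["mufa_sfa_ratio"] = pd.Series(ratio, index=nut.index)
    out["added_fats"] = out["mufa_sfa_ratio"]
    out["alcohol"] = nut.get("alcohol_g", pd.Series(0.0, index=nut.index)).astype(float)
    out["added_sugar"] = nut["added_sugar_g"].astype(float)

    for comp in AMED_COMPONENTS:
        if comp not in out.columns:
            out[comp] = 0.0
    for comp in load_eat_lancet_criteria()["component"]:
        if comp not in out.columns:
            out[comp] = 0.0
    return out.reset_index()


def cohort_amed_scores(
    components: pd.DataFrame,
    persons: pd.DataFrame,
    alcohol_range: tuple[float, float] = (5.0, 25.0),
    medians: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.Series:
    """aMed per person against sex-specific weighted cohort medians.

    ``medians`` may override the cohort-derived references: a mapping
    ``sex -> component -> median``.
    """
    merged = components.merge(persons[["person_id", "sex", "weight"]], on="person_id", validate="1:1")
    median_components = [c for c in AMED_COMPONENTS if c != "alcohol"]
    if medians is None:
        medians = {}
        for sex, sub in merged.groupby("sex"):
            w = sub["weight"].to_numpy(dtype=float)
            medians[sex] = {
                comp: _weighted_median(sub[comp].to_numpy(dtype=float), w) for comp in median_components
            }
    scores = [
        amed_score(row, medians[row["sex"]], alcohol_range=alcohol_range)
        for row in merged.to_dict("records")
    ]
    return pd.Series(scores, index=components.index, name="amed")


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x, kind="stable")
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, 0.5 * cw[-1], side="left"))
    return float(x[order][min(idx, len(x) - 1)])


# --------------------------------------------------- agreement machinery


@dataclass
class AgreementReport:
    pct_same_class: float
    pct_same_or_adjacent: float
    pct_gross_misclassified: float
    kappa: float
    kappa_band: str
    performance: str


def quantile_classes(scores, weights, k: int = 5) -> np.ndarray:
    """Weighted k-tile class labels (1..k) with the deterministic <=-rule.

    Ties at a boundary always fall in the lower class; each class holds
    roughly 1/k of the weight mass.
    """
    x = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(np.unique(x)) < k:
        raise DegenerateDesignError(f"need >= {k} distinct scores for {k} classes")
    from .scoring import _weighted_quantile

    qs = [(i + 1) / k for i in range(k - 1)]
    cuts = _weighted_quantile(x, w, qs)
    return np.asarray(1 + np.sum(x[:, None] > cuts[None, :], axis=1), dtype=int)


def cross_classification(classes_a, classes_b, k: int, weights=None) -> dict:
    """Agreement percentages between two k-class assignments.

    Reports percent in the same class, same-or-adjacent class, and
    grossly misclassified (opposite extremes, classes 1<->k), with the
    50%/10% performance rule applied to same-class / gross percentages.
    """
    a = np.asarray(classes_a, dtype=int)
    b = np.asarray(classes_b, dtype=int)
    if a.shape != b.shape:
        raise DomainError("class assignments must be the same length")
    w = np.ones_like(a, dtype=float) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    same = float(np.sum(w * (a == b)) / total * 100)
    adjacent = float(np.sum(w * (np.abs(a - b) <= 1)) / total * 100)
    gross = float(np.sum(w * (((a == 1) & (b == k)) | ((a == k) & (b == 1)))) / total * 100)
    if same > 50 and gross < 10:
        performance = "good"
    elif same < 50 and gross > 10:
        performance = "poor"
    else:
        performance = "indeterminate"
    return {
        "pct_same_class": same,
        "pct_same_or_adjacent": adjacent,
        "pct_gross_misclassified": gross,
        "performance": performance,
    }


def kappa_band(kappa: float) -> str:
    """Interpretation bands: >=0.61 good, 0.41-0.60 acceptable, 0.21-0.40 fair."""
    if kappa >= 0.61:
        return "good"
    if kappa >= 0.41:
        return "acceptable"
    if kappa >= 0.21:
        return "fair"
    return "poor"


def weighted_kappa(classes_a, classes_b, weight_scheme: str = "linear", weights=None) -> tuple[float, str]:
    """Chance-corrected ordinal agreement with linear or quadratic weights.

    Survey weights, when given, act as fractional counts in the
    confusion matrix.  Returns ``(kappa, band)``.
    """
    a = np.asarray(classes_a, dtype=int)
    b = np.asarray(classes_b, dtype=int)
    if a.shape != b.shape:
        raise DomainError("class assignments must be the same length")
    labels = np.union1d(a, b)
    if len(labels) < 2:
        raise DegenerateDesignError("kappa undefined: a single observed class")
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    w = np.ones_like(a, dtype=float) if weights is None else np.asarray(weights, dtype=float)

    confusion = np.zeros((k, k))
    np.add.at(confusion, (np.vectorize(index.get)(a), np.vectorize(index.get)(b)), w)
    confusion /= confusion.sum()

    dist = np.abs(np.arange(k)[:, None] - np.arange(k)[None, :]) / (k - 1)
    if weight_scheme == "linear":
        agree = 1.0 - dist
    elif weight_scheme == "quadratic":
        agree = 1.0 - dist**2
    else:
        raise DomainError(f"unknown kappa weight scheme {weight_scheme!r}")

    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    po = float(np.sum(agree * confusion))
    pe = float(np.sum(agree * np.outer(row, col)))
    if pe == 1.0:
        raise DegenerateDesignError("kappa undefined: expected agreement is 1")
    kap = (po - pe) / (1.0 - pe)
    return float(kap), kappa_band(float(kap))


def agreement_report(
    classes_a,
    classes_b,
    k: int,
    weights=None,
    kappa_scheme: str = "linear",
) -> AgreementReport:
    """Full cross-classification + kappa agreement between two assignments."""
    cc = cross_classification(classes_a, classes_b, k, weights=weights)
    kap, band = weighted_kappa(classes_a, classes_b, weight_scheme=kappa_scheme, weights=weights)
    return AgreementReport(
        pct_same_class=cc["pct_same_class"],
        pct_same_or_adjacent=cc["pct_same_or_adjacent"],
        pct_gross_misclassified=cc["pct_gross_misclassified"],
        kappa=kap,
        kappa_band=band,
        performance=cc["performance"],
    )
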