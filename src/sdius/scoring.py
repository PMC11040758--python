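"""Point assignment, sub-index scores and the total SDI-US.

Each of the 12 indicators is banded into 1-5 points.  Nine indicators
use quintile bands (left-open/right-closed: a value equal to a threshold
falls in the lower band); the direction decides whether small values are
good (environmental, economic) or large values are (nutritional).  The
three sociocultural frequency indicators follow the *zero rule*: an
exact zero earns 5 points, nonzero values are banded by quartiles of the
nonzero distribution into 4..1.

Sub-index scores are the plain mean of member points; the total index is
the sum of the four sub-indices, so it ranges from 4 (all worst) to 20
(all best).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDesignError, DomainError
from .resources import load_cutpoints

SUB_INDICES = ["nutritional", "environmental", "economic", "sociocultural"]


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    direction: str  # "higher" (higher is better) or "lower"
    zero_rule: bool
    sub_index: str


#: The 12 indicators in canonical order (2 nutritional, 6 environmental,
#: 1 economic, 3 sociocultural).
INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("nrf93", "higher", False, "nutritional"),
    IndicatorSpec("mar", "higher", False, "nutritional"),
    IndicatorSpec("freshwater_l", "lower", False, "environmental"),
    IndicatorSpec("stress_water_l", "lower", False, "environmental"),
    IndicatorSpec("acid_g", "lower", False, "environmental"),
    IndicatorSpec("eutroph_g", "lower", False, "environmental"),
    IndicatorSpec("ghge_kg", "lower", False, "environmental"),
    IndicatorSpec("land_m2", "lower", False, "environmental"),
    IndicatorSpec("budget_share_pct", "lower", False, "economic"),
    IndicatorSpec("freq_fastfood", "lower", True, "sociocultural"),
    IndicatorSpec("freq_rte", "lower", True, "sociocultural"),
    IndicatorSpec("freq_frozen", "lower", True, "sociocultural"),
)

INDICATOR_NAMES = [spec.name for spec in INDICATORS]


def indicator_specs(environmental_variant: str = "six") -> tuple[IndicatorSpec, ...]:
    """The active indicator set.

    The ``"five"`` environmental variant drops freshwater withdrawals
    (a sensitivity configuration guarding against double counting of
    water), changing only the environmental sub-index divisor.
    """
    if environmental_variant == "six":
        return INDICATORS
    if environmental_variant == "five":
        return tuple(s for s in INDICATORS if s.name != "freshwater_l")
    raise DomainError(f"unknown environmental variant {environmental_variant!r}")


class CutpointTable(dict):
    """Mapping indicator name -> strictly increasing threshold tuple.

    Quintile indicators carry 4 thresholds; zero-rule indicators carry 3
    (quartile cuts of the nonzero distribution).
    """

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CutpointTable":
        table = cls()
        for row in frame.itertuples(index=False):
            cuts = [row.t1, row.t2, row.t3, row.t4]
            cuts = tuple(float(c) for c in cuts if not pd.isna(c))
            table[row.indicator] = cuts
        table.validate()
        return table

    def validate(self) -> None:
        # Non-decreasing is required; ties are tolerated because rank-based
        # banding of heavily tied counts legitimately produces equal
        # thresholds (the <=-rule then skips the empty band deterministically).
        for name, cuts in self.items():
            if any(b < a for a, b in zip(cuts, cuts[1:])):
                raise DataError(f"cut-points for {name!r} are not non-decreasing: {cuts}")
            if len(set(cuts)) < 2:
                raise DataError(f"cut-points for {name!r} are fully degenerate: {cuts}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        spec_by_name = {s.name: s for s in INDICATORS}
        for name, cuts in self.items():
            spec = spec_by_name[name]
            padded = list(cuts) + [np.nan] * (4 - len(cuts))
            rows.append({"indicator": name, "direction": spec.direction, "zero_rule": spec.zero_rule,
                         "t1": padded[0], "t2": padded[1], "t3": padded[2], "t4": padded[3]})
        return pd.DataFrame(rows)


def fixed_cutpoints() -> CutpointTable:
    """The versioned US rubric thresholds shipped with the package."""
    return CutpointTable.from_frame(load_cutpoints())


def assign_points(value: float, spec: IndicatorSpec, cuts: Mapping[str, Sequence[float]]) -> int:
    """Band a single indicator value into 1-5 points.

    Band boundaries are right-closed: a value exactly equal to a
    threshold falls in the lower (closer to the threshold's left) band.
    Zero-rule indicators award 5 for an exact zero and band nonzero
    values by the three quartile cuts into 4..1.
    """
    if not np.isfinite(value):
        raise DomainError(f"indicator {spec.name!r} value is not finite: {value}")
    t = cuts[spec.name]
    if spec.zero_rule:
        if len(t) != 3:
            raise DataError(f"zero-rule indicator {spec.name!r} needs 3 cuts, has {len(t)}")
        if value == 0:
            return 5
        return int(4 - sum(value > x for x in t))
    if len(t) != 4:
        raise DataError(f"indicator {spec.name!r} needs 4 cuts, has {len(t)}")
    above = sum(value > x for x in t)
    return int(1 + above) if spec.direction == "higher" else int(5 - above)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, qs: Sequence[float]) -> np.ndarray:
    """Inverse weighted empirical CDF: smallest x with F(x) >= q."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    total = cw[-1]
    out = np.empty(len(qs))
    for i, q in enumerate(qs):
        idx = int(np.searchsorted(cw, q * total, side="left"))
        out[i] = v[min(idx, len(v) - 1)]
    return out


def derive_cutpoints(
    values: Mapping[str, np.ndarray] | pd.DataFrame,
    weights: np.ndarray | pd.Series,
    specs: Sequence[IndicatorSpec] = INDICATORS,
) -> CutpointTable:
    """Data-derived rubric: weighted quintile thresholds per indicator
    (weighted quartiles of the nonzero subset for zero-rule indicators)."""
    weights = np.asarray(weights, dtype=float)
    table = CutpointTable()
    for spec in specs:
        x = np.asarray(values[spec.name], dtype=float)
        if spec.zero_rule:
            nonzero = x != 0
            xnz, wnz = x[nonzero], weights[nonzero]
            if len(np.unique(xnz)) < 4:
                raise DegenerateDesignError(
                    f"{spec.name!r}: need >= 4 distinct nonzero values for zero-rule quartiles"
                )
            cuts = _weighted_quantile(xnz, wnz, (0.25, 0.50, 0.75))
        else:
            if len(np.unique(x)) < 5:
                raise DegenerateDesignError(f"{spec.name!r}: need >= 5 distinct values for quintiles")
            cuts = _weighted_quantile(x, weights, (0.2, 0.4, 0.6, 0.8))
        if len(np.unique(cuts)) < 2:
            raise DegenerateDesignError(f"{spec.name!r}: quantile thresholds fully tied at {cuts[0]}")
        table[spec.name] = tuple(float(c) for c in cuts)
    return table


def subindex_score(points: Sequence[int], k: int) -> float:
    """Mean of the member-indicator points of one sub-index."""
    points = list(points)
    if len(points) != k:
        raise DomainError(f"expected {k} member points, got {len(points)}")
    if any(not (1 <= p <= 5) for p in points):
        raise DomainError(f"points must lie in 1..5, got {points}")
    return float(sum(points)) / k


def total_sdi(sub_scores: Mapping[str, float]) -> float:
    """Total index: exact sum of the four sub-index scores (range 4-20)."""
    missing = [s for s in SUB_INDICES if s not in sub_scores]
    if missing:
        raise DomainError(f"missing sub-index scores: {missing}")
    for name in SUB_INDICES:
        if not (1.0 <= sub_scores[name] <= 5.0):
            raise DomainError(f"sub-index {name!r}={sub_scores[name]} outside [1, 5]")
    return float(sum(sub_scores[name] for name in SUB_INDICES))


def modified_sdi_without(card: Mapping[str, float], dropped: str) -> float:
    """Leave-one-out index: total minus one sub-index (range 3-15)."""
    if dropped not in SUB_INDICES:
        raise DomainError(f"unknown sub-index {dropped!r}")
    return float(card["sdi_total"] - card[f"sub_{dropped}"])


def score_cohort(
    indicators: pd.DataFrame,
    cuts: CutpointTable | None = None,
    *,
    mode: str = "fixed",
    weights: pd.Series | np.ndarray | None = None,
    environmental_variant: str = "six",
) -> pd.DataFrame:
    """Score every person: 12 point columns, 4 sub-index columns, total.

    ``mode="fixed"`` applies the shipped US rubric; ``mode="derive"``
    recomputes weighted quantile cut-points from this cohort (requires
    ``weights``).
    """
    specs = indicator_specs(environmental_variant)
    if mode == "fixed":
        if cuts is None:
            cuts = fixed_cutpoints()
    elif mode == "derive":
        if weights is None:
            raise DomainError("derive mode requires survey weights")
        cuts = derive_cutpoints(indicators, weights, specs)
    else:
        raise DomainError(f"unknown scoring mode {mode!r}")

    out = pd.DataFrame({"person_id": indicators["person_id"]})
    for spec in specs:
        col = indicators[spec.name].to_numpy(dtype=float)
        out[f"pts_{spec.name}"] = [assign_points(v, spec, cuts) for v in col]

    for sub in SUB_INDICES:
        members = [s.name for s in specs if s.sub_index == sub]
        pts = out[[f"pts_{m}" for m in members]].to_numpy()
        out[f"sub_{sub}"] = pts.mean(axis=1)
    out["sdi_total"] = sum(out[f"sub_{s}"] for s in SUB_INDICES)
    return out
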