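"""Composite vulnerability scoring and risk-zone classification.

Each district's per-factor natural-breaks class (low/medium/high) is
converted to a Likert score. Risk-direction factors score low/medium/high
as 1/2/3; protective factors (exclusive breastfeeding, healthy homes,
under-five service coverage) are reverse-scored 3/2/1 so that a high total
always means high vulnerability. Factor scores are summed per district and
the total is classified into low/medium/high risk zones, either by the
fixed thresholds (low < 12, medium 12-14, high > 14) or by re-applying
natural breaks to the totals (the "overlay" variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .classification import BreakSet, classify_with_breaks, jenks_breaks
from .errors import InvalidArgumentError

__all__ = [
    "FactorScoreConfig",
    "DEFAULT_FACTORS",
    "score_factors",
    "total_scores",
    "classify_risk",
    "build_vulnerability_map",
    "level_counts",
]

# The seven significant predictors and their risk directions.
DEFAULT_FACTORS: tuple[tuple[str, str], ...] = (
    ("population_density", "risk"),
    ("rainfall", "risk"),
    ("exclusive_breastfeeding", "protective"),
    ("malnutrition", "risk"),
    ("healthy_home", "protective"),
    ("under_five_services", "protective"),
    ("health_facilities", "risk"),
)

_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class FactorScoreConfig:
    """Scoring rules: factor directions, class scores and risk thresholds.

    ``threshold_mode`` is "fixed" (low <= low_max, high >= high_min) or
    "natural_breaks" (Jenks with k=3 on the totals).
    """

    factors: tuple[tuple[str, str], ...] = DEFAULT_FACTORS
    scoring: Mapping[str, int] = field(
        default_factory=lambda: {"low": 1, "medium": 2, "high": 3}
    )
    threshold_mode: str = "fixed"
    low_max: int = 11
    high_min: int = 15
    reverse_protective: bool = True

    def __post_init__(self):
        if not self.factors:
            raise InvalidArgumentError("factor list must not be empty")
        for name, direction in self.factors:
            if direction not in ("risk", "protective"):
                raise InvalidArgumentError(f"{name}: bad direction {direction!r}")
        vals = list(self.scoring.values())
        if len(set(vals)) != len(vals) or any(v <= 0 for v in vals):
            raise InvalidArgumentError("scores must be distinct positive integers")
        if self.threshold_mode not in ("fixed", "natural_breaks"):
            raise InvalidArgumentError(f"bad threshold_mode {self.threshold_mode!r}")
        if self.low_max >= self.high_min:
            raise InvalidArgumentError("low_max must be < high_min")


def score_factors(
    class_table: pd.DataFrame, config: FactorScoreConfig | None = None
) -> pd.DataFrame:
    """Per-district Likert scores, one column per factor.

    ``class_table`` is long format (district_id, factor, class) as written
    by the classification stage. Protective factors reverse-score via
    s -> (min+max) - s, which for 1/2/3 is 4 - s.
    """
    config = config or FactorScoreConfig()
    missing_cols = {"district_id", "factor", "class"} - set(class_table.columns)
    if missing_cols:
        raise InvalidArgumentError(f"class table missing columns: {sorted(missing_cols)}")
    scoring = dict(config.scoring)
    flip_sum = min(scoring.values()) + max(scoring.values())

    wide = class_table.pivot(index="district_id", columns="factor", values="class")
    scores = {}
    for name, direction in config.factors:
        if name not in wide.columns:
            raise InvalidArgumentError(f"no classes for factor {name!r}")
        col = wide[name]
        bad = col[col.isna() | ~col.isin(scoring)]
        if len(bad):
            raise InvalidArgumentError(
                f"district {bad.index[0]} has missing/unknown class for factor {name!r}"
            )
        s = col.map(scoring).astype(int)
        if direction == "protective" and config.reverse_protective:
            s = flip_sum - s
        scores[name] = s
    return pd.DataFrame(scores, index=wide.index)


def total_scores(factor_scores: pd.DataFrame) -> pd.Series:
    """Integer sum of factor scores per district."""
    if factor_scores.isna().any().any():
        raise InvalidArgumentError("score table has missing entries")
    return factor_scores.sum(axis=1).astype(int).rename("total")


def classify_risk(
    totals: pd.Series, config: FactorScoreConfig | None = None
) -> pd.Series:
    """Risk level per district from its total score.

    Fixed mode: high iff total > 14 (>= high_min), medium for 12-14, low
    below 12 (with the default thresholds). Natural-breaks mode re-runs
    Jenks with k=3 on the totals and labels ascending classes
    low/medium/high; with fewer than 3 distinct totals it falls back to
    fixed thresholds with a warning.
    """
    config = config or FactorScoreConfig()
    t = pd.Series(totals).astype(int)
    if (t <= 0).any():
        raise InvalidArgumentError("totals must be positive integers")
    mode = config.threshold_mode
    if mode == "natural_breaks" and t.nunique() < 3:
        warnings.warn(
            "fewer than 3 distinct totals; falling back to fixed thresholds",
            stacklevel=2,
        )
        mode = "fixed"
    if mode == "fixed":
        levels = np.where(
            t >= config.high_min, "high", np.where(t > config.low_max, "medium", "low")
        )
        return pd.Series(levels, index=t.index, name="level")
    breaks = jenks_breaks(t.to_numpy(), k=3, labels=_LEVELS)
    return pd.Series(
        classify_with_breaks(t.to_numpy(), breaks), index=t.index, name="level"
    )


def build_vulnerability_map(
    polygons: Mapping[str, Polygon],
    levels: pd.Series,
    totals: pd.Series | None = None,
) -> tuple[dict, dict[str, int]]:
    """GeoJSON FeatureCollection of districts annotated with risk levels.

    Returns (feature_collection, level_counts). District ids in ``levels``
    must match the polygon ids exactly.
    """
    poly_ids = set(polygons)
    level_ids = set(levels.index)
    if poly_ids != level_ids:
        diff = sorted(poly_ids.symmetric_difference(level_ids))
        raise InvalidArgumentError(f"district id mismatch: {diff}")

    from shapely.geometry import mapping  # local import keeps module load light

    features = []
    for district_id, poly in polygons.items():
        props = {"district_id": district_id, "level": str(levels[district_id])}
        if totals is not None:
            props["total"] = int(totals[district_id])
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(poly)}
        )
    collection = {"type": "FeatureCollection", "features": features}
    counts = {lev: int((levels == lev).sum()) for lev in _LEVELS}
    return collection, counts


def level_counts(levels: pd.Series) -> dict[str, int]:
    """Number of districts per risk level (always reports all three levels)."""
    return {lev: int((levels == lev).sum()) for lev in _LEVELS}
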