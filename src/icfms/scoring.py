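"""Multidimensional disability scoring and five-level grading.

Subjects are scored on four functional dimensions of the WHO International
Classification of Functioning, Disability and Health (ICF): activity
limitation (0-50 points), body function/structure impairment (0-60),
participation restriction (0-30) and health condition (0-100).  The total
score (0-240) is banded into five ordered disability grades,

    1 = severe, 2 = overweight (partial-severe), 3 = moderate,
    4 = mild, 5 = healthy,

so higher grades mean better function.  Death is a separate absorbing state
(code 0) carried alongside the grades in downstream transition analysis.

The band edges and per-dimension score caps are configurable through
:class:`GradingScheme`; the defaults reproduce the published banding
([0,50] -> 1, (50,100] -> 2, (100,150] -> 3, (150,200] -> 4, (200,240] -> 5).
Only the first band is closed on the right at its lower edge, because
"50 points or less" is the one explicitly closed boundary in the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Dimension names, in canonical column order.
DIMENSIONS: tuple[str, ...] = ("activity", "body", "participation", "health")

DEFAULT_MAXIMA: tuple[float, ...] = (50.0, 60.0, 30.0, 100.0)
DEFAULT_EDGES: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)

#: Grade code -> short label (Table-1 style naming).
GRADE_LABELS: dict[int, str] = {
    1: "severe",
    2: "overweight",
    3: "moderate",
    4: "mild",
    5: "health",
}
GRADES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Absorbing death state code used in the ``state`` column.
DEATH_STATE: int = 0
STATE_LABELS: dict[int, str] = {DEATH_STATE: "death", **GRADE_LABELS}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up (0.05 -> 0.1) to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GradingScheme:
    """Score caps per dimension and band edges on the total-score axis."""

    dimension_maxima: tuple[float, ...] = DEFAULT_MAXIMA
    band_edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        if len(self.dimension_maxima) != len(DIMENSIONS):
            raise ValidationError(
                f"expected {len(DIMENSIONS)} dimension maxima, got "
                f"{len(self.dimension_maxima)}"
            )
        if any(m <= 0 for m in self.dimension_maxima):
            raise ValidationError("dimension maxima must be positive")
        edges = self.band_edges
        if len(edges) != 4:
            raise ValidationError("need exactly 4 band edges for 5 grades")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("band edges must be strictly increasing")
        if edges[-1] >= self.max_total:
            raise ValidationError(
                "highest band edge must be below the maximum total score"
            )

    @property
    def max_total(self) -> float:
        return float(sum(self.dimension_maxima))

    def band(self, grade: int) -> tuple[float, float]:
        """(lower, upper) total-score bounds of ``grade``'s band.

        The interval is ``[lower, upper]`` for grade 1 and ``(lower, upper]``
        otherwise.
        """
        if grade not in GRADE_LABELS:
            raise ValidationError(f"unknown grade {grade!r}")
        bounds = (0.0, *self.band_edges, self.max_total)
        return bounds[grade - 1], bounds[grade]

    @classmethod
    def from_dict(cls, cfg: dict) -> "GradingScheme":
        """Build from a config block ``{'edges': [...], 'maxima': [...]}``."""
        return cls(
            dimension_maxima=tuple(cfg.get("maxima", DEFAULT_MAXIMA)),
            band_edges=tuple(cfg.get("edges", DEFAULT_EDGES)),
        )


@dataclass(frozen=True)
class DimensionScores:
    """Four ICF dimension scores of one subject at one wave."""

    activity: float
    body: float
    participation: float
    health: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.activity, self.body, self.participation, self.health)


@dataclass(frozen=True)
class DisabilityGrade:
    """An ordered disability grade; 1 (severe) < ... < 5 (healthy)."""

    code: int
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.code not in GRADE_LABELS:
            raise ValidationError(f"grade code must be in 1..5, got {self.code}")
        object.__setattr__(self, "label", GRADE_LABELS[self.code])


def total_score(
    scores: DimensionScores | Sequence[float],
    scheme: GradingScheme | None = None,
) -> float:
    """Sum the four dimension scores after range-checking each one."""
    scheme = scheme or GradingScheme()
    values = scores.as_tuple() if isinstance(scores, DimensionScores) else tuple(scores)
    if len(values) != len(DIMENSIONS):
        raise ValidationError(f"expected {len(DIMENSIONS)} scores, got {len(values)}")
    for name, value, cap in zip(DIMENSIONS, values, scheme.dimension_maxima):
        if not np.isfinite(value) or value < 0 or value > cap:
            raise ValidationError(
                f"dimension {name!r} score {value!r} outside [0, {cap}]"
            )
    return float(sum(values))


def grade(total: float, scheme: GradingScheme | None = None) -> DisabilityGrade:
    """Map a total score to its disability grade (piecewise-constant)."""
    scheme = scheme or GradingScheme()
    if not np.isfinite(total) or total < 0 or total > scheme.max_total:
        raise ValidationError(
            f"total score {total!r} outside [0, {scheme.max_total}]"
        )
    code = int(np.searchsorted(scheme.band_edges, total, side="left")) + 1
    return DisabilityGrade(code)


def grade_totals(totals: np.ndarray, scheme: GradingScheme | None = None) -> np.ndarray:
    """Vectorized grade codes for an array of total scores."""
    scheme = scheme or GradingScheme()
    totals = np.asarray(totals, dtype=float)
    bad = ~np.isfinite(totals) | (totals < 0) | (totals > scheme.max_total)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} total score(s) outside [0, {scheme.max_total}]"
        )
    return np.searchsorted(scheme.band_edges, totals, side="left").astype(int) + 1


def grade_cohort(
    panel: pd.DataFrame, scheme: GradingScheme | None = None
) -> pd.DataFrame:
    """Attach ``grade`` and ``state`` columns to a panel of observations.

    Surviving records (``dead == 0``) must carry all four dimension scores
    and receive their grade in both columns; dead records receive the death
    state (0) and a missing grade.  Input row order is preserved.
    """
    scheme = scheme or GradingScheme()
    if panel.empty:
        raise ValidationError("panel is empty")
    missing = [c for c in DIMENSIONS if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel lacks score columns: {missing}")
    out = panel.copy()
    dead = out["dead"].fillna(0).astype(int) == 1
    scores = out.loc[:, list(DIMENSIONS)].to_numpy(dtype=float)
    has_scores = np.isfinite(scores).all(axis=1)
    invalid = ~dead.to_numpy() & ~has_scores
    if invalid.any():
        ids = out.loc[invalid, "subject_id"].tolist()[:5]
        raise ValidationError(
            f"{int(invalid.sum())} surviving record(s) with incomplete scores "
            f"(first subject ids: {ids})"
        )
    caps = np.asarray(scheme.dimension_maxima)
    with np.errstate(invalid="ignore"):
        out_of_range = has_scores & ((scores < 0) | (scores > caps)).any(axis=1)
    if out_of_range.any():
        ids = out.loc[out_of_range, "subject_id"].tolist()[:5]
        raise ValidationError(
            f"out-of-range dimension scores (first subject ids: {ids})"
        )
    grade_col = np.full(len(out), np.nan)
    alive_scored = has_scores
    if alive_scored.any():
        totals = scores[alive_scored].sum(axis=1)
        grade_col[alive_scored] = grade_totals(totals, scheme)
    state = np.where(dead.to_numpy(), DEATH_STATE, grade_col)
    out["grade"] = grade_col
    out["state"] = state
    return out


_DESCRIBE_VARS = ("grade", "dead", "age_group", "male", "urban", "widowed")

_CATEGORY_LABELS = {
    "grade": lambda v: f"{GRADE_LABELS[int(v)].capitalize()} = {int(v)}",
    "dead": lambda v: "Death = 1" if int(v) == 1 else "Survival = 0",
}


def describe_cohort(panel: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style descriptive statistics of a graded panel.

    For every core variable present, returns one row per category with its
    count and the percent (count / non-missing total for that variable,
    rounded half-up to one decimal).
    """
    if panel.empty:
        raise ValidationError("panel is empty")
    rows = []
    for var in _DESCRIBE_VARS:
        if var not in panel.columns:
            continue
        col = panel[var].dropna()
        if col.empty:
            continue
        counts = col.value_counts().sort_index()
        total = int(counts.sum())
        label_fn = _CATEGORY_LABELS.get(var, lambda v: str(v))
        for cat, cnt in counts.items():
            rows.append(
                {
                    "variable": var,
                    "category": label_fn(cat),
                    "count": int(cnt),
                    "percent": round_half_up(100.0 * cnt / total, 1),
                }
            )
    if not rows:
        raise ValidationError("no describable variables present")
    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])
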