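"""Moving-average population forecasting and disabled-population scale.

A short annual series of elderly population counts (unit: 10,000 persons)
per age group is extended with an iterated simple moving average: each
forecast is the mean of the trailing ``window`` values, where
already-forecast values re-enter the window.  The projected population is
then split into the five disability grades using per-age-group grade
prevalence vectors (by default the observed baseline grade distribution),
so that the grade-level counts sum back to the projected group population
exactly.

Prevalence can optionally be evolved over the horizon by repeatedly
applying a 3-year transition matrix, renormalizing over survivors.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import GRADE_LABELS, GRADES
from .transitions import TransitionMatrix


def moving_average_forecast(
    series: Sequence[float] | pd.Series, horizon: int, window: int
) -> pd.Series:
    """Extend a series by ``horizon`` iterated simple-moving-average steps.

    Returns the full extended series; if the input is a pandas Series with
    an integer (year) index, forecast years continue the index.
    """
    if isinstance(series, pd.Series):
        values = series.to_numpy(dtype=float)
        years = list(series.index)
    else:
        values = np.asarray(series, dtype=float)
        years = list(range(len(values)))
    if window < 2:
        raise ValidationError("window must be at least 2")
    if len(values) < window:
        raise ValidationError(
            f"window ({window}) exceeds available history ({len(values)})"
        )
    if horizon < 1:
        raise ValidationError("horizon must be at least 1")
    out = list(values)
    for _ in range(horizon):
        out.append(float(np.mean(out[-window:])))
    step = years[-1] - years[-2] if len(years) > 1 else 1
    years = years + [years[-1] + step * (h + 1) for h in range(horizon)]
    return pd.Series(out, index=years, name=getattr(series, "name", None))


def forecast_population(
    population: pd.DataFrame, horizon: int, window: int = 4
) -> pd.DataFrame:
    """Apply the moving-average forecast per age group.

    ``population`` has columns ``year, age_group, count_10k``; the result
    appends forecast rows flagged by ``forecast = 1``.
    """
    required = {"year", "age_group", "count_10k"}
    if not required.issubset(population.columns):
        raise ValidationError(f"population table needs columns {sorted(required)}")
    frames = []
    for group, df in population.groupby("age_group", sort=False):
        df = df.sort_values("year")
        if df["year"].diff().dropna().ne(1).any():
            raise ValidationError(f"years not contiguous for group {group!r}")
        if (df["count_10k"] <= 0).any():
            raise ValidationError(f"non-positive count for group {group!r}")
        s = moving_average_forecast(
            pd.Series(df["count_10k"].to_numpy(), index=df["year"].to_numpy()),
            horizon,
            window,
        )
        out = pd.DataFrame(
            {"year": s.index, "age_group": group, "count_10k": s.to_numpy()}
        )
        out["forecast"] = (out["year"] > df["year"].max()).astype(int)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def _check_prevalence(prevalence: Mapping[str, Sequence[float]]) -> dict:
    out = {}
    for group, p in prevalence.items():
        v = np.asarray(p, dtype=float)
        if v.shape != (5,) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"prevalence for {group!r} must be a normalized 5-vector"
            )
        out[group] = v
    return out


def disabled_scale(
    population: pd.DataFrame,
    prevalence: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Split projected population into grade-level counts.

    ``count(year, group, grade) = population(year, group) * prevalence``;
    grade counts therefore sum exactly to the group population.
    """
    prev = _check_prevalence(prevalence)
    rows = []
    for _, rec in population.iterrows():
        group = rec["age_group"]
        if group not in prev:
            raise ValidationError(f"no prevalence vector for group {group!r}")
        for g in GRADES:
            rows.append(
                {
                    "year": int(rec["year"]),
                    "age_group": group,
                    "grade": g,
                    "grade_label": GRADE_LABELS[g],
                    "count_10k": float(rec["count_10k"]) * prev[group][g - 1],
                }
            )
    return pd.DataFrame(rows)


def evolve_prevalence(
    prevalence: Sequence[float], matrix: TransitionMatrix, steps: int = 1
) -> np.ndarray:
    """Push a grade distribution through the chain, renormalizing over
    survivors after each 3-year step (period prevalence among the living)."""
    v = np.asarray(prevalence, dtype=float)
    if v.shape != (5,) or abs(v.sum() - 1.0) > 1e-9:
        raise ValidationError("prevalence must be a normalized 5-vector")
    for _ in range(steps):
        v = v @ matrix.Q
        total = v.sum()
        if total <= 0:
            raise ValidationError("no survivors left to renormalize over")
        v = v / total
    return v
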