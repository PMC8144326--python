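"""Synthetic two-wave cohort generator with known ground truth.

Emulates a CLHLS-style longitudinal panel: each subject is observed at a
baseline wave (graded 1-5 from four ICF dimension scores) and again three
years later, where the state is drawn from an age-group-specific 5x6
transition matrix whose sixth column is absorbing death.  Covariates
(male / urban / widowed) shift the death probability on the log-odds scale,
with the transient entries of the row renormalized; optional grade effects
tilt the conditional surviving-grade distribution proportional-odds style.

The generator also produces annual population series (geometric growth) for
the projection stage, and small clustered binary / ordinal outcome samples
used to exercise the random-intercept validity models.

Defaults encode the study conditions: baseline grade prevalence
(4.7 / 5.3 / 9.0 / 13.9 / 67.1 percent), per-age-group sample sizes
(2,890 / 4,377 / 4,079 / 2,909) and transition matrices anchored on the
reported age-specific cells (see docs/methods.md for the completion rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import DIMENSIONS, GRADES, GradingScheme

AGE_GROUPS: tuple[str, ...] = ("65-74", "75-84", "85-94", "95+")

DEFAULT_N_SUBJECTS: dict[str, int] = {
    "65-74": 2890,
    "75-84": 4377,
    "85-94": 4079,
    "95+": 2909,
}

#: Baseline grade prevalence (severe .. healthy), identical across age groups.
DEFAULT_PREVALENCE: tuple[float, ...] = (0.047, 0.053, 0.090, 0.139, 0.671)

# Rows: initial grade 1..5; columns: destination grade 1..5, death.  Percent.
_RAW_MATRICES: dict[str, list[list[float]]] = {
    "65-74": [
        [12.0, 8.0, 7.4, 6.0, 53.3, 13.3],
        [6.0, 10.0, 14.0, 19.9, 31.3, 18.8],
        [4.9, 13.1, 16.4, 8.2, 37.7, 19.7],
        [1.0, 1.5, 1.5, 13.1, 68.3, 14.6],
        [0.3, 0.5, 1.5, 4.3, 84.9, 8.5],
    ],
    "75-84": [
        [18.0, 12.0, 8.0, 6.9, 18.8, 36.3],
        [8.0, 16.0, 10.0, 8.0, 25.0, 33.0],
        [4.0, 6.0, 18.0, 14.0, 28.0, 30.0],
        [1.5, 2.5, 8.0, 20.0, 41.0, 27.0],
        [0.2, 0.3, 1.0, 2.1, 74.8, 21.6],
    ],
    "85-94": [
        [20.0, 8.0, 6.0, 5.1, 8.5, 52.4],
        [8.0, 14.0, 10.0, 8.0, 12.0, 48.0],
        [4.0, 6.0, 16.0, 16.0, 14.0, 44.0],
        [2.0, 4.0, 12.0, 22.0, 22.0, 38.0],
        [1.0, 2.0, 8.0, 23.9, 53.6, 11.5],
    ],
    "95+": [
        [22.0, 8.0, 5.0, 3.2, 2.2, 59.6],
        [8.0, 16.0, 9.0, 7.0, 5.0, 55.0],
        [5.0, 7.0, 16.0, 12.0, 8.0, 52.0],
        [3.0, 5.0, 14.0, 18.0, 12.0, 48.0],
        [2.0, 4.0, 12.0, 15.2, 32.8, 34.0],
    ],
}


def default_matrices() -> dict[str, np.ndarray]:
    """Age-group-specific 5x6 generating matrices (rows sum to 1 exactly)."""
    out = {}
    for group, rows in _RAW_MATRICES.items():
        m = np.asarray(rows, dtype=float)
        out[group] = m / m.sum(axis=1, keepdims=True)
    return out


#: Log-odds covariate effects on 3-year death (urban not significant).
DEFAULT_DEATH_EFFECTS: dict[str, float] = {"male": 1.0, "urban": 0.0, "widowed": 0.65}
#: Log-odds effects on the surviving grade (off by default; the baseline
#: generating mechanism is the transition matrix itself).
DEFAULT_GRADE_EFFECTS: dict[str, float] = {"male": 0.0, "urban": 0.0, "widowed": 0.0}
DEFAULT_COVARIATE_PREVALENCE: dict[str, float] = {
    "male": 0.45,
    "urban": 0.40,
    "widowed": 0.50,
}

COVARIATES: tuple[str, ...] = ("male", "urban", "widowed")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


@dataclass
class CohortSpec:
    """Ground-truth configuration of the synthetic two-wave cohort."""

    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_SUBJECTS)
    )
    prevalence: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {g: DEFAULT_PREVALENCE for g in AGE_GROUPS}
    )
    matrices: Mapping[str, np.ndarray] = field(default_factory=default_matrices)
    death_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEATH_EFFECTS)
    )
    grade_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_EFFECTS)
    )
    covariate_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    waves: tuple[int, int] = (2011, 2014)
    scheme: GradingScheme = field(default_factory=GradingScheme)
    seed: int = 20110000

    def validate(self) -> None:
        for group in self.n_subjects:
            if self.n_subjects[group] <= 0:
                raise ValidationError(f"n_subjects for {group!r} must be positive")
            prev = np.asarray(self.prevalence[group], dtype=float)
            if prev.shape != (5,) or abs(prev.sum() - 1.0) > 1e-9 or (prev < 0).any():
                raise ValidationError(
                    f"prevalence for {group!r} must be a probability 5-vector"
                )
            m = np.asarray(self.matrices[group], dtype=float)
            if m.shape != (5, 6) or (m < 0).any():
                raise ValidationError(f"matrix for {group!r} must be 5x6, nonnegative")
            if np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValidationError(f"matrix rows for {group!r} must sum to 1")

    def to_dict(self) -> dict:
        """JSON-serializable ground truth (for `--truth` manifests)."""
        return {
            "n_subjects": dict(self.n_subjects),
            "prevalence": {g: list(map(float, p)) for g, p in self.prevalence.items()},
            "matrices": {
                g: np.asarray(m, dtype=float).tolist()
                for g, m in self.matrices.items()
            },
            "death_effects": dict(self.death_effects),
            "grade_effects": dict(self.grade_effects),
            "covariate_prevalence": dict(self.covariate_prevalence),
            "waves": list(self.waves),
            "seed": self.seed,
        }


def spec_from_config(cfg: Mapping | None = None, seed: int | None = None) -> CohortSpec:
    """Build a :class:`CohortSpec` from a (possibly partial) config mapping.

    Recognized keys: ``n_subjects``, ``prevalence``, ``matrices``,
    ``death_effects``, ``grade_effects``, ``covariate_prevalence``,
    ``waves``, ``seed``.  Anything omitted keeps its default.
    """
    cfg = dict(cfg or {})
    spec = CohortSpec()
    if "n_subjects" in cfg:
        spec.n_subjects = {str(k): int(v) for k, v in cfg["n_subjects"].items()}
    if "prevalence" in cfg:
        prev = cfg["prevalence"]
        if isinstance(prev, Mapping):
            spec.prevalence = {str(k): tuple(map(float, v)) for k, v in prev.items()}
        else:  # one vector for every age group
            spec.prevalence = {g: tuple(map(float, prev)) for g in spec.n_subjects}
    else:
        spec.prevalence = {g: DEFAULT_PREVALENCE for g in spec.n_subjects}
    if "matrices" in cfg:
        spec.matrices = {
            str(k): np.asarray(v, dtype=float) for k, v in cfg["matrices"].items()
        }
    else:
        base = default_matrices()
        unknown = [g for g in spec.n_subjects if g not in base]
        if unknown:
            raise ValidationError(
                f"no default matrix for age group(s) {unknown}; supply `matrices`"
            )
        spec.matrices = {g: base[g] for g in spec.n_subjects}
    for key in ("death_effects", "grade_effects", "covariate_prevalence"):
        if key in cfg:
            setattr(spec, key, {str(k): float(v) for k, v in cfg[key].items()})
    if "waves" in cfg:
        spec.waves = tuple(int(w) for w in cfg["waves"])
    if seed is not None:
        spec.seed = int(seed)
    elif "seed" in cfg:
        spec.seed = int(cfg["seed"])
    return spec


def _split_totals(
    totals: np.ndarray, caps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split each total across the four dimensions by a uniform composition.

    A flat Dirichlet proposal is capped at the dimension maxima and the
    excess redistributed proportionally to the remaining capacity, which
    preserves the total exactly.
    """
    n = len(totals)
    w = rng.gamma(1.0, size=(n, len(caps)))
    alloc = w / w.sum(axis=1, keepdims=True) * totals[:, None]
    for _ in range(8):
        excess = np.maximum(alloc - caps, 0.0).sum(axis=1)
        if excess.max() <= 1e-10:
            break
        alloc = np.minimum(alloc, caps)
        room = caps - alloc
        room_tot = room.sum(axis=1)
        share = np.divide(excess, room_tot, out=np.zeros(n), where=room_tot > 0)
        alloc = alloc + room * share[:, None]
    return alloc


def _draw_categorical(
    probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Row-wise categorical draw from an (n, k) probability array."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(probs))
    return (u[:, None] > cum).sum(axis=1)


def _shift_death(
    row_probs: np.ndarray, eta: np.ndarray, group: str, grades: np.ndarray
) -> np.ndarray:
    """Shift the death column by per-subject log-odds, renormalizing rows."""
    p0 = row_probs[:, 5]
    out = row_probs.copy()
    shifted = eta != 0
    degenerate = shifted & ((p0 <= 0.0) | (p0 >= 1.0))
    if degenerate.any():
        g = int(grades[np.flatnonzero(degenerate)[0]])
        raise ValidationError(
            f"covariate shift on a degenerate death probability in cell "
            f"(age_group={group!r}, grade={g})"
        )
    p1 = np.where(shifted, _expit(_logit(np.clip(p0, 1e-12, 1 - 1e-12)) + eta), p0)
    scale = np.divide(1 - p1, 1 - p0, out=np.zeros_like(p0), where=(1 - p0) > 0)
    out[:, :5] *= scale[:, None]
    out[:, 5] = p1
    return out


def _tilt_grades(cond: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Proportional-odds tilt of a conditional grade distribution.

    Positive ``eta`` means better function: cumulative mass below each grade
    shrinks by ``eta`` on the log-odds scale.
    """
    cum = np.cumsum(cond[:, :4], axis=1)
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    tilted = _expit(_logit(cum) - eta[:, None])
    full = np.concatenate([tilted, np.ones((len(cond), 1))], axis=1)
    return np.diff(full, prepend=0.0, axis=1)


def generate_panel(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate a two-wave panel from a :class:`CohortSpec`.

    Returns a DataFrame in the standard panel layout (two rows per subject).
    Fully reproducible from ``spec.seed``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    caps = np.asarray(spec.scheme.dimension_maxima, dtype=float)
    frames = []
    offset = 0
    for group in spec.n_subjects:
        n = int(spec.n_subjects[group])
        prev = np.asarray(spec.prevalence[group], dtype=float)
        matrix = np.asarray(spec.matrices[group], dtype=float)

        cov = {
            c: (rng.random(n) < spec.covariate_prevalence.get(c, 0.0)).astype(int)
            for c in COVARIATES
        }
        g1 = _draw_categorical(np.tile(prev, (n, 1)), rng) + 1

        eta_death = sum(
            spec.death_effects.get(c, 0.0) * cov[c] for c in COVARIATES
        )
        eta_death = np.asarray(eta_death, dtype=float)
        rows = matrix[g1 - 1]
        rows = _shift_death(rows, eta_death, group, g1)

        eta_grade = np.asarray(
            sum(spec.grade_effects.get(c, 0.0) * cov[c] for c in COVARIATES),
            dtype=float,
        )
        if np.any(eta_grade != 0):
            p_death = rows[:, 5]
            alive_mass = 1 - p_death
            ok = alive_mass > 0
            cond = np.zeros((n, 5))
            cond[ok] = rows[ok, :5] / alive_mass[ok, None]
            cond[ok] = _tilt_grades(cond[ok], eta_grade[ok])
            rows = np.concatenate([cond * alive_mass[:, None], p_death[:, None]], 1)

        dest = _draw_categorical(rows, rng)  # 0..4 grades-1, 5 death
        dead2 = dest == 5
        g2 = np.where(dead2, 0, dest + 1)

        # realized scores: total uniform within the grade's band, then split
        bands = np.asarray([spec.scheme.band(g) for g in GRADES])

        def scores_for(grades: np.ndarray) -> np.ndarray:
            out = np.full((len(grades), 4), np.nan)
            alive = grades > 0
            if alive.any():
                lo, hi = bands[grades[alive] - 1].T
                totals = rng.uniform(lo, hi)
                out[alive] = _split_totals(totals, caps, rng)
            return out

        s1 = scores_for(g1)
        s2 = scores_for(g2)

        ids = [f"S{offset + i:06d}" for i in range(n)]
        offset += n
        for wave, dead, scores in (
            (spec.waves[0], np.zeros(n, dtype=int), s1),
            (spec.waves[1], dead2.astype(int), s2),
        ):
            frame = pd.DataFrame(
                {
                    "subject_id": ids,
                    "wave": wave,
                    "age_group": group,
                    **{c: cov[c] for c in COVARIATES},
                    "dead": dead,
                }
            )
            for j, dim in enumerate(DIMENSIONS):
                frame[dim] = scores[:, j]
            frames.append(frame)
    panel = pd.concat(frames, ignore_index=True)
    cols = ["subject_id", "wave", "age_group", *COVARIATES, "dead", *DIMENSIONS]
    return panel.loc[:, cols].sort_values(
        ["subject_id", "wave"], kind="stable", ignore_index=True
    )


# -- annual population series -------------------------------------------------

#: Resident 65+ population by age group, unit 10,000 persons (base year 2016).
DEFAULT_POPULATION_BASE: dict[str, float] = {
    "65-74": 360.0,
    "75-84": 200.0,
    "85-94": 70.0,
    "95+": 10.0,
}
DEFAULT_POPULATION_GROWTH: float = 0.04


def generate_population_series(
    base: Mapping[str, float] | None = None,
    growth: float | Mapping[str, float] = DEFAULT_POPULATION_GROWTH,
    start_year: int = 2016,
    n_years: int = 4,
) -> pd.DataFrame:
    """Deterministic geometric-growth population table (year x age group).

    ``count_10k[t] = base * (1 + rate)**(t - start_year)``.
    """
    base = dict(base or DEFAULT_POPULATION_BASE)
    if n_years < 1:
        raise ValidationError("need at least one year")
    rows = []
    for group, b in base.items():
        if b <= 0:
            raise ValidationError(f"base count for {group!r} must be positive")
        rate = growth[group] if isinstance(growth, Mapping) else float(growth)
        for t in range(n_years):
            rows.append(
                {
                    "year": start_year + t,
                    "age_group": group,
                    "count_10k": float(b) * (1.0 + rate) ** t,
                }
            )
    return pd.DataFrame(rows)


# -- clustered outcome samples for the validity models ------------------------


def generate_clustered_binary(
    n_clusters: int,
    cluster_size: int,
    beta: Mapping[str, float],
    intercept: float = -1.0,
    sigma_u: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary outcomes from a random-intercept logit model.

    ``P(y=1 | x, u) = expit(intercept + x @ beta + u)``, ``u ~ N(0, sigma_u^2)``
    per cluster; predictors are iid standard normal.
    """
    rng = np.random.default_rng(seed)
    n = n_clusters * cluster_size
    cluster = np.repeat(np.arange(n_clusters), cluster_size)
    X = {k: rng.standard_normal(n) for k in beta}
    u = rng.normal(0.0, sigma_u, n_clusters)[cluster]
    eta = intercept + sum(b * X[k] for k, b in beta.items()) + u
    y = (rng.random(n) < _expit(eta)).astype(int)
    return pd.DataFrame({"cluster": cluster, **X, "y": y})


def generate_clustered_ordinal(
    n_clusters: int,
    cluster_size: int,
    beta: Mapping[str, float],
    thresholds: Sequence[float] = (-2.0, -0.7, 0.7, 2.0),
    sigma_u: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-level ordinal outcomes from a random-intercept proportional-odds
    model: latent ``x @ beta + u + logistic noise`` cut at ``thresholds``."""
    thresholds = np.asarray(thresholds, dtype=float)
    if not np.all(np.diff(thresholds) > 0):
        raise ValidationError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    n = n_clusters * cluster_size
    cluster = np.repeat(np.arange(n_clusters), cluster_size)
    X = {k: rng.standard_normal(n) for k in beta}
    u = rng.normal(0.0, sigma_u, n_clusters)[cluster]
    latent = sum(b * X[k] for k, b in beta.items()) + u + rng.logistic(size=n)
    y = 1 + (latent[:, None] > thresholds[None, :]).sum(axis=1)
    return pd.DataFrame({"cluster": cluster, **X, "y": y})
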