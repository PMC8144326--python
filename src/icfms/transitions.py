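"""Non-parametric estimation of 3-year disability-state transition matrices.

Two-wave graded panels are reduced to 5x6 transition counts (initial grade
1-5 at baseline against grade 1-5 or death three years later) and converted
to row-stochastic probability matrices by the multinomial maximum-likelihood
estimator p[i][j] = n[i][j] / row_total(i).  Death is absorbing and always
occupies the last column.  Counts can be stratified by baseline age group.

No smoothing is applied by default — the estimates are the raw observed
frequencies; optional add-k smoothing is available behind a flag.  Rows with
zero observations yield NaN probabilities plus a warning rather than an
imputed value, and the life-table stage refuses such rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EstimationError, ValidationError
from .scoring import DEATH_STATE, GRADE_LABELS, GRADES, round_half_up

#: Column index of the absorbing death state in every 5x6 matrix.
DEATH_COL: int = 5

STATE_COLUMNS: tuple[str, ...] = tuple(GRADE_LABELS[g] for g in GRADES) + ("death",)

OVERALL: str = "overall"


@dataclass
class TransitionCounts:
    """Observed wave-1 -> wave-2 transition counts for one stratum."""

    stratum: str
    n: np.ndarray  # (5, 6) non-negative integers
    lost: int = 0  # subjects without a usable wave-2 outcome
    dead_at_baseline: int = 0  # excluded: already absorbed at wave 1

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        if self.n.shape != (5, 6) or (self.n < 0).any():
            raise ValidationError("counts must be a non-negative 5x6 array")

    @property
    def row_totals(self) -> np.ndarray:
        return self.n.sum(axis=1)


@dataclass
class TransitionMatrix:
    """Row-stochastic 5x6 transition probabilities over one interval."""

    stratum: str
    p: np.ndarray  # (5, 6)
    interval_years: float = 3.0
    row_counts: np.ndarray = field(default_factory=lambda: np.zeros(5, dtype=int))

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.row_counts = np.asarray(self.row_counts, dtype=int)
        if self.p.shape != (5, 6):
            raise ValidationError("transition matrix must be 5x6")
        finite = ~np.isnan(self.p).any(axis=1)
        if ((self.p[finite] < 0) | (self.p[finite] > 1)).any():
            raise ValidationError("probabilities must lie in [0, 1]")
        if finite.any():
            sums = self.p[finite].sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-12:
                raise ValidationError("each defined row must sum to 1 (tol 1e-12)")
        if self.interval_years <= 0:
            raise ValidationError("interval_years must be positive")

    @property
    def Q(self) -> np.ndarray:
        """Transient 5x5 block (death column dropped)."""
        return self.p[:, :DEATH_COL]

    @property
    def death(self) -> np.ndarray:
        return self.p[:, DEATH_COL]


def _pair_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Match wave-1/wave-2 rows by subject, validating panel structure."""
    if "state" not in panel.columns:
        raise ValidationError("panel must be graded first (missing `state` column)")
    dup = panel.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        ids = panel.loc[dup, "subject_id"].unique()[:5].tolist()
        raise ValidationError(f"duplicate subject-wave rows (e.g. {ids})")
    counts = panel.groupby("subject_id")["wave"].nunique()
    if (counts > 2).any():
        raise ValidationError("a subject appears in more than two waves")
    panel = panel.sort_values(["subject_id", "wave"], kind="stable")
    first = panel.groupby("subject_id", sort=False).nth(0)
    second = panel.groupby("subject_id", sort=False).nth(1)
    pairs = first.set_index("subject_id").join(
        second.set_index("subject_id"), rsuffix="_2", how="left"
    )
    return pairs.reset_index()


def count_transitions(
    panel: pd.DataFrame, stratify_by_age: bool = False
) -> dict[str, TransitionCounts]:
    """Tally wave-1 -> wave-2 transitions, overall or per baseline age group.

    Each matched pair contributes exactly one count.  Subjects without a
    wave-2 record are reported in the ``lost`` tally; subjects already dead
    at wave 1 are excluded and tallied separately (with a warning).
    """
    pairs = _pair_panel(panel)
    dead_w1 = pairs["state"] == DEATH_STATE
    if dead_w1.any():
        warnings.warn(
            f"{int(dead_w1.sum())} subject(s) dead at baseline excluded",
            stacklevel=2,
        )
    strata: Iterable[tuple[str, pd.DataFrame]]
    if stratify_by_age:
        strata = [(str(g), df) for g, df in pairs.groupby("age_group", sort=True)]
    else:
        strata = [(OVERALL, pairs)]
    out: dict[str, TransitionCounts] = {}
    for name, df in strata:
        dead1 = df["state"] == DEATH_STATE
        usable = ~dead1 & df["state_2"].notna()
        lost = int((~dead1 & df["state_2"].isna()).sum())
        n = np.zeros((5, 6), dtype=int)
        if usable.any():
            i = df.loc[usable, "state"].astype(int).to_numpy() - 1
            s2 = df.loc[usable, "state_2"].astype(int).to_numpy()
            j = np.where(s2 == DEATH_STATE, DEATH_COL, s2 - 1)
            np.add.at(n, (i, j), 1)
        out[name] = TransitionCounts(
            stratum=name, n=n, lost=lost, dead_at_baseline=int(dead1.sum())
        )
    return out


def estimate_matrix(
    counts: TransitionCounts,
    interval_years: float = 3.0,
    smoothing_k: float = 0.0,
) -> TransitionMatrix:
    """Multinomial MLE ``p[i][j] = n[i][j] / row_total(i)``.

    ``smoothing_k`` adds k pseudo-counts to every cell (default off).  Rows
    with zero observations become NaN with a warning.
    """
    n = counts.n.astype(float) + float(smoothing_k)
    totals = n.sum(axis=1)
    p = np.full((5, 6), np.nan)
    nonzero = totals > 0
    p[nonzero] = n[nonzero] / totals[nonzero, None]
    if (~nonzero).any():
        empty = [GRADE_LABELS[i + 1] for i in np.flatnonzero(~nonzero)]
        warnings.warn(
            f"stratum {counts.stratum!r}: no observations for initial "
            f"state(s) {empty}; rows set to NaN",
            stacklevel=2,
        )
    return TransitionMatrix(
        stratum=counts.stratum,
        p=p,
        interval_years=interval_years,
        row_counts=counts.row_totals,
    )


def estimate_from_panel(
    panel: pd.DataFrame,
    stratify_by_age: bool = False,
    interval_years: float = 3.0,
    smoothing_k: float = 0.0,
) -> dict[str, TransitionMatrix]:
    """Convenience composition of counting and estimation."""
    return {
        name: estimate_matrix(c, interval_years, smoothing_k)
        for name, c in count_transitions(panel, stratify_by_age).items()
    }


def bootstrap_matrix_ci(
    panel: pd.DataFrame,
    B: int = 200,
    level: float = 0.95,
    stratify_by_age: bool = False,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Subject-level bootstrap percentile intervals per matrix cell.

    Returns ``{stratum: (lower, upper)}`` with 5x6 bounds at the requested
    coverage level.
    """
    if B < 100:
        raise ValidationError("need at least B=100 bootstrap replicates")
    pairs = _pair_panel(panel)
    rng = np.random.default_rng(seed)
    if stratify_by_age:
        groups = {str(g): df for g, df in pairs.groupby("age_group", sort=True)}
    else:
        groups = {OVERALL: pairs}
    alpha = (1.0 - level) / 2.0
    out = {}
    for name, df in groups.items():
        if len(df) < 2:
            raise EstimationError(f"stratum {name!r} has fewer than 2 subjects")
        dead1 = df["state"] == DEATH_STATE
        usable = df[~dead1 & df["state_2"].notna()]
        i_all = usable["state"].astype(int).to_numpy() - 1
        s2 = usable["state_2"].astype(int).to_numpy()
        j_all = np.where(s2 == DEATH_STATE, DEATH_COL, s2 - 1)
        m = len(usable)
        reps = np.full((B, 5, 6), np.nan)
        for b in range(B):
            idx = rng.integers(0, m, size=m)
            n = np.zeros((5, 6))
            np.add.at(n, (i_all[idx], j_all[idx]), 1.0)
            totals = n.sum(axis=1)
            nz = totals > 0
            n[nz] /= totals[nz, None]
            n[~nz] = np.nan
            reps[b] = n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lower = np.nanpercentile(reps, 100 * alpha, axis=0)
            upper = np.nanpercentile(reps, 100 * (1 - alpha), axis=0)
        out[name] = (lower, upper)
    return out


def format_transition_report(matrices: Mapping[str, TransitionMatrix]) -> str:
    """Human-readable transition tables: percentages to one decimal, rows
    labelled by initial state, with the pre-rounding row sums noted."""
    lines = []
    header = "initial \\ 3y later | " + " | ".join(f"{c:>10}" for c in STATE_COLUMNS)
    for name, tm in matrices.items():
        lines.append(f"== stratum: {name} (interval {tm.interval_years:g} y) ==")
        lines.append(header)
        for i, g in enumerate(GRADES):
            row = tm.p[i]
            if np.isnan(row).any():
                cells = " | ".join(f"{'--':>10}" for _ in row)
                note = "no observations"
            else:
                cells = " | ".join(
                    f"{round_half_up(100 * v, 1):>9.1f}%" for v in row
                )
                note = f"row sum {row.sum():.12g}, n={int(tm.row_counts[i])}"
            lines.append(f"{GRADE_LABELS[g]:>18} | {cells}   [{note}]")
        lines.append("")
    return "\n".join(lines)


# -- JSON persistence ---------------------------------------------------------


def matrices_to_json(
    matrices: Mapping[str, TransitionMatrix], path: str | Path
) -> None:
    payload = {
        name: {
            "stratum": tm.stratum,
            "labels": list(STATE_COLUMNS),
            "interval_years": tm.interval_years,
            "row_counts": tm.row_counts.tolist(),
            "p": tm.p.tolist(),
        }
        for name, tm in matrices.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def matrices_from_json(path: str | Path) -> dict[str, TransitionMatrix]:
    payload = json.loads(Path(path).read_text())
    return {
        name: TransitionMatrix(
            stratum=d["stratum"],
            p=np.asarray(d["p"], dtype=float),
            interval_years=d["interval_years"],
            row_counts=np.asarray(d["row_counts"], dtype=int),
        )
        for name, d in payload.items()
    }
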