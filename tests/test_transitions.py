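"""Transition counting and multinomial estimation of the 3-year matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icfms.exceptions import EstimationError, ValidationError
from icfms.transitions import (
    DEATH_COL,
    TransitionCounts,
    TransitionMatrix,
    bootstrap_matrix_ci,
    count_transitions,
    estimate_matrix,
    format_transition_report,
    matrices_from_json,
    matrices_to_json,
)


def test_all_healthy_stay_healthy(pair_panel_factory):
    panel = pair_panel_factory([(i, 5, 5) for i in range(4)])
    counts = count_transitions(panel)["overall"]
    expected = np.zeros((5, 6), dtype=int)
    expected[4, 4] = 4
    assert (counts.n == expected).all()


def test_mixed_destinations_count_once_each(pair_panel_factory):
    panel = pair_panel_factory([(1, 5, 4), (2, 5, 0), (3, 3, 3)])
    counts = count_transitions(panel)["overall"]
    assert counts.n[4, 3] == 1  # healthy -> mild
    assert counts.n[4, DEATH_COL] == 1  # healthy -> death
    assert counts.n[2, 2] == 1  # moderate -> moderate
    assert counts.n.sum() == 3


def test_lost_to_followup_tallied(pair_panel_factory):
    panel = pair_panel_factory([(1, 5, 5), (2, 4, None)])
    counts = count_transitions(panel)["overall"]
    assert counts.lost == 1
    assert counts.n.sum() == 1


def test_dead_at_baseline_excluded_with_warning(pair_panel_factory):
    panel = pair_panel_factory([(1, 0, 0), (2, 5, 5)])
    with pytest.warns(UserWarning, match="dead at baseline"):
        counts = count_transitions(panel)["overall"]
    assert counts.dead_at_baseline == 1
    assert counts.n.sum() == 1


def test_duplicate_subject_wave_rows_error(pair_panel_factory):
    panel = pair_panel_factory([(1, 5, 5)])
    dup = pd.concat([panel, panel.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValidationError, match="duplicate"):
        count_transitions(dup)


def test_estimator_is_row_ratio():
    n = np.zeros((5, 6), dtype=int)
    n[0] = [2, 0, 0, 0, 1, 1]
    n[4] = [0, 0, 0, 0, 0, 10]
    n[1:4, 0] = 1  # keep remaining rows non-empty
    tm = estimate_matrix(TransitionCounts("overall", n))
    assert np.allclose(tm.p[0], [0.5, 0, 0, 0, 0.25, 0.25])
    assert np.allclose(tm.p[4], [0, 0, 0, 0, 0, 1])


def test_zero_count_row_gives_nan_and_warning():
    n = np.zeros((5, 6), dtype=int)
    n[[0, 1, 2, 3], 5] = 1  # severe..mild observed, healthy never
    with pytest.warns(UserWarning, match="health"):
        tm = estimate_matrix(TransitionCounts("overall", n))
    assert np.isnan(tm.p[4]).all()
    assert not np.isnan(tm.p[:4]).any()


def test_smoothing_fills_empty_cells():
    n = np.zeros((5, 6), dtype=int)
    n[:, 5] = 4
    tm = estimate_matrix(TransitionCounts("overall", n), smoothing_k=1.0)
    assert np.allclose(tm.p.sum(axis=1), 1.0)
    assert (tm.p > 0).all()


@given(
    counts=st.lists(
        st.lists(st.integers(0, 50), min_size=6, max_size=6),
        min_size=5,
        max_size=5,
    )
)
def test_estimated_rows_are_stochastic(counts):
    n = np.asarray(counts)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = estimate_matrix(TransitionCounts("overall", n))
    defined = ~np.isnan(tm.p).any(axis=1)
    if defined.any():
        assert np.abs(tm.p[defined].sum(axis=1) - 1.0).max() <= 1e-12


def test_estimate_invariant_to_row_order(pair_panel_factory, rng):
    records = [(i, int(rng.integers(1, 6)), int(rng.integers(0, 6))) for i in range(60)]
    panel = pair_panel_factory(records)
    shuffled = panel.sample(frac=1.0, random_state=1).reset_index(drop=True)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = estimate_matrix(count_transitions(panel)["overall"])
        b = estimate_matrix(count_transitions(shuffled)["overall"])
    np.testing.assert_array_equal(a.p, b.p)


def test_hand_computed_probabilities_on_small_panel(pair_panel_factory):
    records = [
        (1, 5, 5), (2, 5, 5), (3, 5, 4), (4, 5, 0),
        (5, 3, 3), (6, 3, 5), (7, 1, 0), (8, 1, 1),
    ]
    panel = pair_panel_factory(records)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = estimate_matrix(count_transitions(panel)["overall"])
    assert tm.p[4, 4] == 0.5  # 2 of 4 healthy stayed
    assert tm.p[4, 3] == 0.25
    assert tm.p[4, DEATH_COL] == 0.25
    assert tm.p[2, 2] == 0.5 and tm.p[2, 4] == 0.5
    assert tm.p[0, 0] == 0.5 and tm.p[0, DEATH_COL] == 0.5


def test_age_stratification_splits_counts(pair_panel_factory):
    panel = pair_panel_factory([(1, 5, 5), (2, 5, 0)])
    panel.loc[panel["subject_id"] == "2", "age_group"] = "95+"
    by_age = count_transitions(panel, stratify_by_age=True)
    assert set(by_age) == {"65-74", "95+"}
    assert by_age["65-74"].n[4, 4] == 1
    assert by_age["95+"].n[4, DEATH_COL] == 1


def test_bootstrap_intervals_contain_point_estimate(pair_panel_factory, rng):
    records = [(i, int(rng.integers(1, 6)), int(rng.integers(0, 6))) for i in range(200)]
    panel = pair_panel_factory(records)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = estimate_matrix(count_transitions(panel)["overall"])
        lo, hi = bootstrap_matrix_ci(panel, B=150, seed=0)["overall"]
    mask = ~np.isnan(tm.p) & ~np.isnan(lo) & ~np.isnan(hi)
    assert (lo[mask] <= tm.p[mask] + 1e-12).all()
    assert (hi[mask] >= tm.p[mask] - 1e-12).all()


def test_bootstrap_rejects_tiny_stratum(pair_panel_factory):
    panel = pair_panel_factory([(1, 5, 5)])
    with pytest.raises(EstimationError):
        bootstrap_matrix_ci(panel, B=100)
    with pytest.raises(ValidationError):
        bootstrap_matrix_ci(panel, B=10)


def test_report_shows_one_decimal_percentages(pair_panel_factory):
    panel = pair_panel_factory([(i, 5, 5) for i in range(3)] + [(9, 5, 0)])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = estimate_matrix(count_transitions(panel)["overall"])
    report = format_transition_report({"overall": tm})
    assert "75.0%" in report and "25.0%" in report
    assert "health" in report


def test_matrices_json_roundtrip(tmp_path, pair_panel_factory, rng):
    records = [(i, int(rng.integers(1, 6)), int(rng.integers(0, 6))) for i in range(80)]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = estimate_matrix(count_transitions(pair_panel_factory(records))["overall"])
    path = tmp_path / "m.json"
    matrices_to_json({"overall": tm}, path)
    back = matrices_from_json(path)["overall"]
    np.testing.assert_array_equal(back.p, tm.p)
    np.testing.assert_array_equal(back.row_counts, tm.row_counts)
    assert back.interval_years == tm.interval_years


def test_matrix_validation_rejects_bad_rows():
    p = np.full((5, 6), 1 / 6)
    p[0, 0] += 1e-6
    with pytest.raises(ValidationError):
        TransitionMatrix("overall", p)
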