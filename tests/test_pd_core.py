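"""Closed-form PD estimation, conditioning rules, and cell summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trials
from moralpd.pd_core import (
    cell_summaries,
    condition_for_regression,
    conventional_measure,
    estimate_pd,
    group_level_estimate,
    tree_probabilities,
)


def _agg(p_cong, p_incong):
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(len(p_cong))],
            "p_unacc_cong": p_cong,
            "p_unacc_incong": p_incong,
        }
    )


class TestEstimatePD:
    def test_sample_level_proportions(self):
        # complements of 14% / 55% acceptance: U = 0.41, D = 0.45/0.59
        est = estimate_pd(_agg([0.86], [0.45]))
        assert est.loc[0, "U"] == pytest.approx(0.41)
        assert est.loc[0, "D"] == pytest.approx(0.45 / 0.59)
        assert not est.loc[0, "u_clamped"]

    def test_zero_difference_gives_u_zero(self):
        est = estimate_pd(_agg([0.6], [0.6]))
        assert est.loc[0, "U"] == 0.0
        assert est.loc[0, "D"] == pytest.approx(0.6)

    def test_negative_u_clamped_to_zero(self):
        est = estimate_pd(_agg([0.4], [0.5]))
        assert est.loc[0, "U_raw"] == pytest.approx(-0.1)
        assert est.loc[0, "U"] == 0.0
        assert est.loc[0, "u_clamped"]
        assert est.loc[0, "D"] == pytest.approx(0.5)

    def test_u_of_one_leaves_d_undefined(self):
        est = estimate_pd(_agg([1.0], [0.0]))
        assert est.loc[0, "U"] == 1.0
        assert est.loc[0, "d_undefined"]
        assert np.isnan(est.loc[0, "D"])

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            estimate_pd(_agg([1.2], [0.5]))

    @given(
        d=st.floats(0.0, 1.0),
        u=st.floats(0.0, 0.99),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_algebraic_inverse_roundtrip(self, d, u):
        p_cong, p_incong = tree_probabilities(d, u)
        est = estimate_pd(_agg([p_cong], [p_incong]))
        assert est.loc[0, "U"] == pytest.approx(u, abs=1e-12)
        assert est.loc[0, "D"] == pytest.approx(d, abs=1e-12)

    def test_u_raw_is_exact_difference(self, rng):
        p_c = rng.random(100)
        p_i = rng.random(100)
        est = estimate_pd(_agg(p_c, p_i))
        assert (est["U_raw"].to_numpy() == p_c - p_i).all()


class TestConditionForRegression:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.42, 0.40), (0.44, 0.45), (0.425, 0.45), (0.0, 0.0), (1.0, 1.0)],
    )
    def test_documented_roundings(self, value, expected):
        assert condition_for_regression(value, 20) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_grid_times_weight_is_integer(self, value):
        grid = condition_for_regression(value, 20)
        assert 0.0 <= grid <= 1.0
        assert grid * 20 == pytest.approx(round(grid * 20), abs=1e-9)

    def test_bad_weight_rejected(self):
        with pytest.raises(ValueError):
            condition_for_regression(0.5, 0)

    def test_unclamped_values_rejected(self):
        with pytest.raises(ValueError):
            condition_for_regression(-0.1, 20)


class TestConventionalMeasure:
    def test_counting(self):
        trials = make_trials(
            [("a", "incongruent", "accept_harm")] * 4
            + [("a", "incongruent", "reject_harm")] * 6
        )
        score = conventional_measure(trials)
        assert score.loc[0, "conventional"] == pytest.approx(0.4)
        assert score.loc[0, "weight"] == 10

    def test_all_rejected_scores_zero(self):
        trials = make_trials([("a", "incongruent", "reject_harm")] * 10)
        score = conventional_measure(trials)
        assert score.loc[0, "conventional"] == 0.0

    def test_missing_incongruent_trials_flagged(self):
        trials = make_trials([("a", "incongruent", "reject_harm")] * 7)
        assert conventional_measure(trials).loc[0, "incomplete"]


class TestCellSummaries:
    def _participants(self, ids):
        return pd.DataFrame(
            {
                "participant_id": ids,
                "instrumentality": "means",
                "personal_force": "personal",
                "sex": "female",
            }
        )

    def test_hand_arithmetic(self):
        est = estimate_pd(_agg([0.6, 0.8], [0.6, 0.8]))  # U = 0, D = 0.6 / 0.8
        cells = cell_summaries(est, self._participants(["p0", "p1"]))
        assert cells.loc[0, "d_mean"] == pytest.approx(0.7)
        assert cells.loc[0, "d_sd"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_identical_participants_zero_sd(self):
        est = estimate_pd(_agg([0.7, 0.7, 0.7], [0.3, 0.3, 0.3]))
        cells = cell_summaries(est, self._participants(["p0", "p1", "p2"]))
        assert cells.loc[0, "d_sd"] == pytest.approx(0.0, abs=1e-12)
        assert cells.loc[0, "u_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_undefined_d_reduces_effective_n(self):
        est = estimate_pd(_agg([1.0, 0.8, 0.7], [0.0, 0.4, 0.4]))
        cells = cell_summaries(est, self._participants(["p0", "p1", "p2"]))
        assert cells.loc[0, "n"] == 3
        assert cells.loc[0, "n_d_defined"] == 2

    def test_single_participant_cell_rejected(self):
        est = estimate_pd(_agg([0.8], [0.4]))
        with pytest.raises(ValueError):
            cell_summaries(est, self._participants(["p0"]))


def test_group_level_estimate_matches_pooled_equations():
    agg = _agg([0.9, 0.7], [0.5, 0.3])
    out = group_level_estimate(agg)
    assert out["U"] == pytest.approx(0.4)
    assert out["D"] == pytest.approx(0.4 / 0.6)
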