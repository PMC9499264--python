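import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhizorank.scoring import (TreatmentRanker, build_score_matrix,
                               rank_scores, round_half_up, totals_and_means)


def brute_force_max_tie_scores(values):
    """Independent oracle: each value scores the maximum of the
    ascending sort positions occupied by its ties."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    position = {}
    for pos, idx in enumerate(order, start=1):
        position.setdefault(values[idx], []).append(pos)
    return [max(position[v]) for v in values]


class TestRankScores:
    def test_distinct_ascending(self):
        assert rank_scores([1, 2, 3]).tolist() == [1, 2, 3]

    def test_published_spad_column(self):
        """12 distinct chlorophyll means rank to the published scores."""
        spad = [25.8, 27.2, 27.7, 24.1, 23.6, 24.2,
                22.2, 26.2, 29.0, 33.3, 29.5, 27.8]
        assert rank_scores(spad, 12).tolist() == \
            [5, 7, 8, 3, 2, 4, 1, 6, 10, 12, 11, 9]

    def test_published_root_dw_max_tie(self):
        """Tied values all take the maximum of their tied positions."""
        root_dw = [0.3, 0.3, 0.2, 0.2, 0.2, 0.2, 0.3, 0.3]
        assert rank_scores(root_dw, 8).tolist() == [8, 8, 4, 4, 4, 4, 8, 8]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="expected 4"):
            rank_scores([1, 2, 3], 4)

    def test_too_short(self):
        with pytest.raises(ValueError):
            rank_scores([1.0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="matrix level"):
            rank_scores([1.0, np.nan, 2.0])

    @given(st.lists(st.integers(min_value=0, max_value=6),
                    min_size=2, max_size=12))
    def test_matches_brute_force_oracle(self, values):
        """Heavily tied vectors agree with the enumeration oracle."""
        assert rank_scores(values).tolist() == \
            brute_force_max_tie_scores(values)

    @given(st.lists(st.floats(min_value=-100, max_value=100,
                              allow_nan=False), min_size=2, max_size=10),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, values, rnd):
        perm = list(range(len(values)))
        rnd.shuffle(perm)
        base = rank_scores(values)
        shuffled = rank_scores([values[i] for i in perm])
        assert shuffled.tolist() == [int(base[i]) for i in perm]

    def test_no_ties_is_permutation(self, rng):
        values = rng.permutation(20).astype(float)
        assert sorted(rank_scores(values)) == list(range(1, 21))

    def test_monotonicity(self, rng):
        """Raising one treatment's value never lowers its score."""
        values = rng.integers(0, 5, size=8).astype(float)
        base = rank_scores(values)
        for i in range(len(values)):
            bumped = values.copy()
            bumped[i] += 1.5
            assert rank_scores(bumped)[i] >= base[i]


class TestTotalsAndMeans:
    def test_full_row(self):
        """61 points over 13 parameters → mean 4.7."""
        scores = pd.DataFrame(
            {f"p{i}": [v] for i, v in
             enumerate([10, 7, 8, 4, 8, 1, 3, 7, 5, 2, 4, 1, 1])},
            index=["Control"]).astype("Int64")
        out = totals_and_means(scores)
        assert out.loc["Control", "total"] == 61
        assert out.loc["Control", "mean"] == 4.7

    def test_partial_row_nt_excluded(self):
        """79 points over 9 available parameters → mean 8.8 (half-up)."""
        row = [6, 9, 11, 12, 10, 12, 7, 2, 10] + [None] * 4
        scores = pd.DataFrame({f"p{i}": [v] for i, v in enumerate(row)},
                              index=["Char_MC-B"]).astype("Int64")
        out = totals_and_means(scores)
        assert out.loc["Char_MC-B", "total"] == 79
        assert out.loc["Char_MC-B", "n_params"] == 9
        assert out.loc["Char_MC-B", "mean"] == 8.8

    def test_single_parameter(self):
        scores = pd.DataFrame({"p": [5, 2]}, index=["a", "b"]).astype("Int64")
        out = totals_and_means(scores)
        assert out.loc["a", "mean"] == 5.0
        assert out.loc["a", "is_highest"] and out.loc["b", "is_lowest"]

    def test_half_up_on_exact_boundary(self):
        # 49/4 = 12.25 → 12.3 under half-up (banker's would give 12.2)
        scores = pd.DataFrame({"p1": [20, 1], "p2": [20, 1], "p3": [5, 1],
                               "p4": [4, 1]}).astype("Int64")
        out = totals_and_means(scores)
        assert out.loc[0, "mean"] == 12.3


def test_round_half_up():
    assert round_half_up(8.25, 1) == 8.3
    assert round_half_up(4.65, 1) == 4.7
    assert round_half_up(4.64, 1) == 4.6


class TestTreatmentRanker:
    def test_matrix_scoring_and_sklearn_api(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 1.0]},
                              index=["t1", "t2", "t3"])
        ranker = TreatmentRanker().fit(values)
        assert ranker.scores_["a"].tolist() == [1, 2, 3]
        assert ranker.scores_["b"].tolist() == [3, 3, 1]
        assert ranker.max_scores_.tolist() == [3, 3]
        params = ranker.get_params()
        assert set(params) == {"directions", "precision", "mean_decimals"}
        clone_scores = TreatmentRanker(**params).fit_transform(values)
        pd.testing.assert_frame_equal(clone_scores, ranker.scores_)

    def test_nt_column_subset_ranking(self):
        """A parameter missing for some treatments ranks only the rest,
        with max score = number of ranked treatments."""
        values = pd.DataFrame({
            "x": [3.0, 1.0, 2.0, 4.0],
            "y": [np.nan, 1.0, 2.0, np.nan]})
        scores = build_score_matrix(values)
        assert scores["x"].tolist() == [3, 1, 2, 4]
        assert scores["y"][1] == 1 and scores["y"][2] == 2
        assert scores["y"].isna().tolist() == [True, False, False, True]

    def test_direction_flag(self):
        values = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scores = build_score_matrix(values, directions={"x": -1})
        assert scores["x"].tolist() == [3, 2, 1]

    def test_precision_mode(self):
        """Printed-precision ranking ties values that full precision
        separates."""
        values = pd.DataFrame({"x": [0.14, 0.149, 0.30]})
        assert build_score_matrix(values)["x"].tolist() == [1, 2, 3]
        assert build_score_matrix(values, precision=1)["x"].tolist() == [2, 2, 3]

    def test_too_few_available(self):
        values = pd.DataFrame({"x": [1.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="at least 2"):
            build_score_matrix(values)

    def test_score_bounds_invariant(self, rng):
        values = pd.DataFrame(rng.integers(0, 4, size=(9, 5)).astype(float))
        scores = build_score_matrix(values)
        assert (scores.min() >= 1).all()
        assert (scores.max() <= 9).all()
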