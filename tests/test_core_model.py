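"""Linear-additive value model: normalization, anchors, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcda_panel import (
    committee_value_estimate,
    normalize_weights,
    rater_value_estimate,
    summarize_matrix,
    uniform_weight_value,
)
from mcda_panel.errors import AlignmentError, IncompletePanelError, ScaleViolationError
from mcda_panel.rounding import round_half_up

from .conftest import make_matrix

CRITERIA_14 = [f"C{i}" for i in range(1, 15)]


class TestNormalizeWeights:
    def test_uniform_weights_give_equal_fractions(self):
        for const in (1, 3, 5):
            norm = normalize_weights({c: const for c in CRITERIA_14})
            assert all(np.isclose(v, 1 / 14) for v in norm.values())

    def test_two_criterion_toy(self):
        assert normalize_weights({"a": 4, "b": 1}) == {"a": 0.8, "b": 0.2}

    @given(st.lists(st.integers(1, 5), min_size=14, max_size=14))
    @settings(max_examples=50, deadline=None)
    def test_matches_manual_summation(self, raw):
        weights = dict(zip(CRITERIA_14, raw))
        norm = normalize_weights(weights)
        # independent oracle: explicit loop accumulation
        total = 0
        for w in raw:
            total += w
        for cid, w in weights.items():
            assert norm[cid] == pytest.approx(w / total, abs=1e-12)
        assert sum(norm.values()) == pytest.approx(1.0, abs=1e-9)
        order = sorted(weights, key=weights.get)
        assert sorted(order, key=norm.get) == order  # order-preserving

    def test_errors(self):
        with pytest.raises(IncompletePanelError):
            normalize_weights({})
        with pytest.raises(ScaleViolationError):
            normalize_weights({"a": 0, "b": 2})


class TestRaterValueEstimate:
    def test_anchors_independent_of_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            weights = dict(zip(CRITERIA_14, rng.integers(1, 6, 14)))
            v_max, _ = rater_value_estimate(weights, {c: 3 for c in CRITERIA_14})
            v_min, _ = rater_value_estimate(weights, {c: 0 for c in CRITERIA_14})
            assert v_max == 1.0
            assert v_min == 0.0

    def test_two_criterion_toy(self):
        # manual: (4/5)*(3/3) + (1/5)*(0/3) = 0.8
        v, contrib = rater_value_estimate({"a": 4, "b": 1}, {"a": 3, "b": 0})
        assert v == pytest.approx(0.8, abs=1e-12)
        assert contrib["a"] == pytest.approx(0.8)
        assert contrib["b"] == 0.0

    def test_criterion_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            rater_value_estimate({"a": 1, "b": 1}, {"a": 1, "c": 1})

    @given(
        st.lists(st.integers(1, 5), min_size=14, max_size=14),
        st.lists(st.integers(0, 3), min_size=14, max_size=14),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_bounds(self, w, s):
        weights = dict(zip(CRITERIA_14, w))
        scores = dict(zip(CRITERIA_14, s))
        v, contrib = rater_value_estimate(weights, scores)
        assert 0.0 <= v <= 1.0
        assert all(c >= 0 for c in contrib.values())
        assert sum(contrib.values()) == pytest.approx(v, abs=1e-9)

    @given(
        st.lists(st.integers(1, 5), min_size=14, max_size=14),
        st.lists(st.integers(0, 3), min_size=14, max_size=14),
        st.integers(0, 13),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_single_score(self, w, s, idx):
        weights = dict(zip(CRITERIA_14, w))
        scores = dict(zip(CRITERIA_14, s))
        v0, _ = rater_value_estimate(weights, scores)
        bumped = dict(scores)
        cid = CRITERIA_14[idx]
        if bumped[cid] < 3:
            bumped[cid] += 1
            v1, _ = rater_value_estimate(weights, bumped)
            assert v1 > v0


class TestCommitteeValueEstimate:
    def test_single_rater_degenerate(self, criteria):
        rng = np.random.default_rng(1)
        w = make_matrix(rng.integers(1, 6, (1, 14)), "weight", crits=list(criteria.core_ids))
        s = make_matrix(rng.integers(0, 4, (1, 14)), "score", crits=list(criteria.core_ids))
        res = committee_value_estimate(w, s, criteria)
        assert res.committee_mean == pytest.approx(list(res.per_rater_value.values())[0])
        assert res.committee_sd == 0.0

    def test_consensus_committee_has_zero_sd(self, criteria):
        w = make_matrix(np.tile([3, 4, 5, 2, 1, 3, 4, 5, 2, 1, 3, 4, 5, 2], (9, 1)),
                        "weight", crits=list(criteria.core_ids))
        s = make_matrix(np.tile([1, 2, 3, 0, 1, 2, 3, 0, 1, 2, 3, 0, 1, 2], (9, 1)),
                        "score", crits=list(criteria.core_ids))
        res = committee_value_estimate(w, s, criteria)
        assert res.committee_sd == 0.0

    def test_uniform_weights_closed_form(self, criteria):
        # with equal weights for every rater, V = grand mean score / 3
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 4, (9, 14))
        w = make_matrix(np.full((9, 14), 3), "weight", crits=list(criteria.core_ids))
        s = make_matrix(scores, "score", crits=list(criteria.core_ids))
        res = committee_value_estimate(w, s, criteria)
        assert res.committee_mean == pytest.approx(scores.mean() / 3, abs=1e-12)
        assert res.committee_mean == pytest.approx(
            uniform_weight_value(scores.mean()), abs=1e-12
        )

    def test_cluster_shares_sum_to_one(self, criteria):
        rng = np.random.default_rng(3)
        w = make_matrix(rng.integers(1, 6, (9, 14)), "weight", crits=list(criteria.core_ids))
        s = make_matrix(rng.integers(1, 4, (9, 14)), "score", crits=list(criteria.core_ids))
        res = committee_value_estimate(w, s, criteria)
        assert sum(res.cluster_shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(res.cluster_shares) == set(criteria.clusters)

    def test_rater_mismatch_raises(self, criteria):
        w = make_matrix(np.full((9, 14), 3), "weight", crits=list(criteria.core_ids))
        s = make_matrix(np.full((8, 14), 2), "score", crits=list(criteria.core_ids))
        with pytest.raises(AlignmentError):
            committee_value_estimate(w, s, criteria)


class TestSummarizeMatrix:
    def test_consensus_weight(self):
        m = make_matrix(np.full((9, 1), 4), "weight")
        (summary,) = summarize_matrix(m)
        assert summary.mean == 4.0
        assert summary.sd == 0.0

    def test_single_rater_sd_zero(self):
        m = make_matrix([[2, 5, 1]], "weight")
        assert all(s.sd == 0.0 for s in summarize_matrix(m))

    def test_feasible_vector_for_printed_summary(self):
        # 5 fives and 4 fours: mean 4.56 -> 4.6, sample SD 0.527 -> 0.5
        m = make_matrix(np.array([[5], [5], [5], [5], [5], [4], [4], [4], [4]]), "weight")
        (summary,) = summarize_matrix(m)
        assert round_half_up(summary.mean, 1) == 4.6
        assert round_half_up(summary.sd, 1) == 0.5

    def test_population_convention_optional(self):
        m = make_matrix(np.array([[1], [2], [3]]), "score")
        (sample,) = summarize_matrix(m, sd_ddof=1)
        (pop,) = summarize_matrix(m, sd_ddof=0)
        assert sample.sd == pytest.approx(1.0)
        assert pop.sd == pytest.approx(np.sqrt(2 / 3))


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(4.55, 1) == 4.6
    assert round_half_up(0.435, 2) == 0.44
    assert round_half_up(2.5) == 3.0
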