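"""Test-retest reliability: pairing, ICC(3,1), agreement proportions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcda_panel import (
    PairedObservations,
    agreement_proportions,
    cluster_agreement,
    icc_3_1,
    pair_sessions,
    value_estimate_reliability,
)
from mcda_panel.errors import AlignmentError, ScaleViolationError, UndefinedICCError

from .conftest import icc_oracle, make_matrix


def pairs_from(test, retest, role=None):
    test = np.asarray(test, float)
    return PairedObservations(
        tuple(f"u{i}" for i in range(len(test))), test, np.asarray(retest, float), role=role
    )


class TestPairSessions:
    def test_complete_9x14_panel_yields_126_pairs(self, criteria):
        rng = np.random.default_rng(0)
        t = make_matrix(rng.integers(1, 6, (9, 14)), "weight", crits=list(criteria.core_ids))
        r = make_matrix(rng.integers(1, 6, (9, 14)), "weight", session="retest",
                        crits=list(criteria.core_ids))
        assert pair_sessions(t, r).n == 126

    def test_single_cell(self):
        t = make_matrix([[3]], "weight")
        r = make_matrix([[4]], "weight", session="retest")
        assert pair_sessions(t, r).n == 1

    def test_missing_rater_complete_case_with_warning(self, criteria):
        rng = np.random.default_rng(1)
        t = make_matrix(rng.integers(1, 6, (9, 14)), "weight", crits=list(criteria.core_ids))
        r = make_matrix(rng.integers(1, 6, (8, 14)), "weight", session="retest",
                        crits=list(criteria.core_ids))
        with pytest.warns(UserWarning, match="R9"):
            pairs = pair_sessions(t, r)
        assert pairs.n == 112

    def test_role_mismatch_raises(self):
        t = make_matrix([[3]], "weight")
        r = make_matrix([[1]], "score", session="retest")
        with pytest.raises(AlignmentError):
            pair_sessions(t, r)


class TestICC:
    def test_identical_sessions_give_unity(self):
        res = icc_3_1(pairs_from([1, 2, 3, 4], [1, 2, 3, 4]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.error_ms == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_absorbed_by_fixed_session_effect(self):
        res = icc_3_1(pairs_from([1, 2, 3, 4], [2, 3, 4, 5]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_on_worked_example(self):
        test, retest = [1, 2, 3, 4], [1, 3, 2, 4]
        res = icc_3_1(pairs_from(test, retest))
        assert res.icc == pytest.approx(icc_oracle(test, retest), abs=1e-12)
        assert res.icc == pytest.approx(0.8, abs=1e-12)  # hand-computed (BMS-EMS)/(BMS+EMS)

    @given(
        st.integers(2, 60),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_on_random_panels(self, n, seed):
        rng = np.random.default_rng(seed)
        test = rng.integers(1, 6, n)
        retest = rng.integers(1, 6, n)
        if np.all(test == test[0]) and np.all(retest == retest[0]):
            return  # zero-variance case covered separately
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # negative ICCs expected
            res = icc_3_1(pairs_from(test, retest))
        assert res.icc == pytest.approx(icc_oracle(test, retest), abs=1e-12)

    def test_matches_pingouin_icc3(self):
        # independent library cross-check on one random panel
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        test = rng.integers(1, 6, 30)
        retest = rng.integers(1, 6, 30)
        res = icc_3_1(pairs_from(test, retest))
        df = pd.DataFrame({
            "unit": list(range(30)) * 2,
            "session": ["t"] * 30 + ["r"] * 30,
            "y": np.concatenate([test, retest]),
        })
        table = pg.intraclass_corr(df, targets="unit", raters="session", ratings="y")
        icc3 = float(table.loc[table["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert res.icc == pytest.approx(icc3, abs=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        test = rng.integers(1, 6, 20).astype(float)
        retest = rng.integers(1, 6, 20).astype(float)
        if np.all(test == test[0]) and np.all(retest == retest[0]):
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # negative ICCs expected
            base = icc_3_1(pairs_from(test, retest)).icc
            trans = icc_3_1(pairs_from(a * test + b, a * retest + b)).icc
        assert trans == pytest.approx(base, abs=1e-9)

    def test_zero_variance_is_explicit_error(self):
        with pytest.raises(UndefinedICCError):
            icc_3_1(pairs_from([3, 3, 3], [3, 3, 3]))
        with pytest.raises(UndefinedICCError):
            # pure session shift, no unit variance
            icc_3_1(pairs_from([3, 3, 3], [4, 4, 4]))

    def test_negative_icc_reported_unclamped(self):
        test, retest = [1, 5, 1, 5], [5, 1, 5, 1]
        with pytest.warns(UserWarning, match="negative"):
            res = icc_3_1(pairs_from(test, retest))
        assert res.icc < 0
        assert res.icc == pytest.approx(icc_oracle(test, retest), abs=1e-12)


class TestAgreementProportions:
    def test_identical_sessions(self):
        ap = agreement_proportions(pairs_from([1, 2, 3], [1, 2, 3]))
        assert ap.percentages() == {"same": 100.0, "diff1": 0.0, "diff2": 0.0, "diff_gt2": 0.0}

    def test_partition_is_exact_before_rounding(self):
        rng = np.random.default_rng(3)
        test = rng.integers(1, 6, 126)
        retest = rng.integers(1, 6, 126)
        ap = agreement_proportions(pairs_from(test, retest))
        assert sum(ap.fraction(c) for c in ("same", "diff1", "diff2", "diff_gt2")) == 1

    def test_non_integer_values_rejected(self):
        with pytest.raises(ScaleViolationError):
            agreement_proportions(pairs_from([1.5, 2], [1, 2]))

    def test_gt2_category_tracked(self):
        ap = agreement_proportions(pairs_from([1, 1], [5, 1]))
        assert ap.count_diff_gt2 == 1


class TestClusterAgreement:
    def test_two_criterion_cluster_percentage(self, criteria):
        # disease_impact has 2 criteria -> 18 pairs for 9 raters; make 14 identical
        rng = np.random.default_rng(4)
        vals = rng.integers(1, 5, (9, 14))
        t = make_matrix(vals, "weight", crits=list(criteria.core_ids))
        retest_vals = vals.copy()
        di_cols = [list(criteria.core_ids).index(c) for c in criteria.clusters["disease_impact"]]
        flat = [(r, c) for c in di_cols for r in range(9)][:4]
        for r, c in flat:
            retest_vals[r, c] = vals[r, c] + 1
        r = make_matrix(retest_vals, "weight", session="retest", crits=list(criteria.core_ids))
        pct = cluster_agreement(pair_sessions(t, r), criteria)
        assert pct["disease_impact"] == pytest.approx(100 * 14 / 18)

    def test_all_identical_cluster_is_100(self, criteria):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 6, (9, 14))
        t = make_matrix(vals, "weight", crits=list(criteria.core_ids))
        r = make_matrix(vals, "weight", session="retest", crits=list(criteria.core_ids))
        pct = cluster_agreement(pair_sessions(t, r), criteria)
        assert all(p == 100.0 for p in pct.values())

    def test_three_criterion_cluster_division(self, criteria):
        # economics has 3 criteria -> 27 pairs; 24 identical -> 88.9%
        vals = np.full((9, 14), 3)
        t = make_matrix(vals, "weight", crits=list(criteria.core_ids))
        retest_vals = vals.copy()
        eco_cols = [list(criteria.core_ids).index(c) for c in criteria.clusters["economics"]]
        for r_i in range(3):
            retest_vals[r_i, eco_cols[0]] = 4
        r = make_matrix(retest_vals, "weight", session="retest", crits=list(criteria.core_ids))
        pct = cluster_agreement(pair_sessions(t, r), criteria)
        assert pct["economics"] == pytest.approx(100 * 24 / 27)

    def test_unmapped_criterion_is_configuration_error(self, criteria):
        from mcda_panel.errors import ConfigurationError

        t = make_matrix([[3]], "weight", crits=["mystery"])
        r = make_matrix([[3]], "weight", session="retest", crits=["mystery"])
        with pytest.raises(ConfigurationError):
            cluster_agreement(pair_sessions(t, r), criteria)


class TestValueEstimateReliability:
    def _committee(self, seed, criteria):
        rng = np.random.default_rng(seed)
        w = make_matrix(rng.integers(1, 6, (9, 14)), "weight", crits=list(criteria.core_ids))
        s = make_matrix(rng.integers(0, 4, (9, 14)), "score", crits=list(criteria.core_ids))
        return w, s

    def test_identical_sessions_unity(self, criteria):
        w, s = self._committee(6, criteria)
        w2 = make_matrix(w.values.to_numpy(), "weight", session="retest", crits=list(criteria.core_ids))
        s2 = make_matrix(s.values.to_numpy(), "score", session="retest", crits=list(criteria.core_ids))
        res = value_estimate_reliability(w, s, w2, s2)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.n_units == 9

    def test_perturbation_degrades_icc_toward_but_not_past_one(self, criteria):
        # Monte-Carlo property: less perturbation -> higher ICC
        from mcda_panel import RetestModel, perturb_retest

        iccs = {}
        for p_same in (0.65, 0.9, 1.0):
            model = RetestModel(p_same, (1 - p_same) * 0.9, (1 - p_same) * 0.1)
            vals = []
            for seed in range(15):
                w, s = self._committee(100 + seed, criteria)
                rw = perturb_retest(w, model, 2 * seed)
                rs = perturb_retest(s, model, 2 * seed + 1)
                vals.append(value_estimate_reliability(w, s, rw, rs).icc)
            iccs[p_same] = float(np.mean(vals))
        assert iccs[0.65] < iccs[0.9] <= iccs[1.0] == pytest.approx(1.0, abs=1e-12)
        assert iccs[0.65] > 0
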