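"""Signed-rank engine, q-values, DMS calling, age drift and position overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylpair.diffmeth import (
    QValueConfig,
    age_association,
    call_dms,
    differential_table,
    fold_changes,
    overlap_positions,
    paired_signed_rank,
    qvalues,
    signed_rank_matrix,
)


def brute_force_signed_rank_p(diffs):
    """Independent oracle: two-tailed exact p over all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        w_all.append(sum(r for s, r in zip(signs, ranks) if s))
    w_all = np.array(w_all)
    lower = np.mean(w_all <= w_obs + 1e-12)
    upper = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2 * min(lower, upper))


class TestPairedSignedRank:
    def test_all_positive_five_pairs_exact(self):
        res = paired_signed_rank(np.zeros(5), np.array([1.0, 2, 3, 4, 5]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.0625)

    def test_symmetric_differences_give_p_one(self):
        res = paired_signed_rank(np.zeros(4), np.array([2.0, -2, 3, -3]))
        assert res.p_value == pytest.approx(1.0)

    def test_undersized_after_zero_removal_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            paired_signed_rank(np.array([1.0, 2, 5]), np.array([2.0, 1, 5]))

    def test_all_zero_differences_flagged(self):
        res = paired_signed_rank(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.all_zero and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        diffs = rng.normal(0, 1, size=n)
        res = paired_signed_rank(np.zeros(n), diffs)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(diffs), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_independent_library(self, seed):
        rng = np.random.default_rng(100 + seed)
        before = rng.normal(size=8)
        after = before + rng.normal(size=8)
        res = paired_signed_rank(before, after)
        ref = stats.wilcoxon(after, before, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_approx_path_matches_independent_library(self, seed):
        rng = np.random.default_rng(200 + seed)
        before = rng.normal(size=23)
        after = before + rng.normal(0.2, 1, size=23)
        res = paired_signed_rank(before, after)
        assert res.method == "approx"
        ref = stats.wilcoxon(after, before, method="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_matrix_engine_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        before = rng.normal(size=(40, 23))
        after = before + rng.normal(0.1, 0.5, size=(40, 23))
        w, p = signed_rank_matrix(before, after)
        for i in range(40):
            res = paired_signed_rank(before[i], after[i], exact_max_n=0)
            assert p[i] == pytest.approx(res.p_value, rel=1e-12)
            assert w[i] == pytest.approx(res.statistic)

    def test_matrix_engine_handles_ties_and_zeros(self):
        before = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        after = np.array([[1.0, 3.0, 4.0, 5.0, 4.0, 7.0]])  # one zero, tied |d|
        _, p = signed_rank_matrix(before, after)
        ref = stats.wilcoxon(after[0], before[0], method="approx", correction=True)
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-10)


class TestQValues:
    def test_fixed_one_reduces_to_step_up(self):
        config = QValueConfig(pi0_mode="fixed_one")
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), config)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        q = qvalues(np.ones(20), QValueConfig(pi0_mode="fixed_one"))
        np.testing.assert_allclose(q, 1.0)

    def test_fixed_one_equals_independent_step_up_oracle(self):
        rng = np.random.default_rng(11)
        p = np.concatenate([rng.uniform(0, 1, 900), rng.uniform(0, 0.01, 100)])
        q = qvalues(p, QValueConfig(pi0_mode="fixed_one"))
        from statsmodels.stats.multitest import multipletests

        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_p_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 50)
        q = qvalues(p, QValueConfig(pi0_mode="smoother"))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        shuffled = rng.permutation(50)
        q_shuffled = qvalues(p[shuffled], QValueConfig(pi0_mode="smoother"))
        np.testing.assert_allclose(q_shuffled, q[shuffled], atol=1e-12)

    def test_smoother_pi0_bounded_and_sane(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 5000)  # pure null
        q = qvalues(p, QValueConfig(pi0_mode="smoother"))
        assert q.min() > 0.0 and q.max() <= 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            qvalues(np.array([0.5, 1.5]))

    def test_small_family_falls_back_to_fixed_one(self):
        with pytest.warns(UserWarning, match="falling back"):
            q = qvalues(np.array([0.2, 0.4, 0.9]), QValueConfig(pi0_mode="smoother"))
        assert q.max() <= 1.0


class TestCallsAndFoldChanges:
    @pytest.fixture()
    def results(self):
        return pd.DataFrame(
            {
                "probe_id": ["a", "b", "c"],
                "mean_before": [0.40, 0.50, 0.296],
                "mean_after": [0.46, 0.53, 0.406],
                "difference": [0.06, 0.03, 0.11],
                "q_value": [0.04, 0.04, 0.2],
            }
        )

    def test_nested_call_sets(self, results):
        calls = call_dms(results)
        assert set(calls["set_q"]["probe_id"]) == {"a", "b"}
        assert set(calls["set_q_delta"]["probe_id"]) == {"a"}
        assert calls["tallies"]["n_q_delta_increase"] == 1

    def test_fold_change_percent(self, results):
        fc = fold_changes(results)
        assert fc.iloc[0] == pytest.approx(15.0)
        # a site moving from 29.6% to 40.6% methylation is a +37.2% fold change
        assert fc.iloc[2] == pytest.approx(37.2, abs=0.05)

    def test_zero_baseline_is_flagged_undefined(self):
        frame = pd.DataFrame({"mean_before": [0.0], "mean_after": [0.1]})
        assert np.isnan(fold_changes(frame).iloc[0])

    def test_gene_deduplication(self, results):
        annotation = pd.DataFrame(
            {"probe_id": ["a", "b", "c"], "genes": [["G1", "G1"], ["G2"], []]}
        )
        calls = call_dms(results, annotation)
        assert calls["genes"] == ["G1"]
        assert calls["tallies"]["n_unique_genes"] == 1


class TestAgeAssociation:
    def test_perfect_linear_fit(self):
        ages = np.array([30.0, 33, 36, 39, 42, 45])
        m = (0.02 * ages)[None, :]
        res = age_association(m, ages, ["p0"])
        assert res.loc[0, "slope"] == pytest.approx(0.02)
        assert res.loc[0, "p_value"] < 1e-10
        assert bool(res.loc[0, "significant"])

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(30, 45, 24)
        m = rng.normal(size=(2000, 24))
        res = age_association(m, ages, [f"p{i}" for i in range(2000)])
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_undersized_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            age_association(np.ones((1, 2)), np.array([30.0, 40.0]), ["p0"])

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant age"):
            age_association(np.ones((1, 6)), np.full(6, 35.0), ["p0"])


class TestOverlap:
    def test_disjoint_and_identical(self):
        a = pd.DataFrame({"chromosome": ["1", "2"], "position": [10, 20]})
        b = pd.DataFrame({"chromosome": ["3"], "position": [10]})
        assert overlap_positions(a, b) == 0
        assert overlap_positions(a, a) == 2

    def test_matching_requires_both_coordinates(self):
        a = pd.DataFrame({"chromosome": ["1"], "position": [10]})
        b = pd.DataFrame({"chromosome": ["1", "2"], "position": [11, 10]})
        assert overlap_positions(a, b) == 0
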