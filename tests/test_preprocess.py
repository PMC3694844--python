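"""Preprocessing chain: beta/M transforms, detection, normalization, batch."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylpair.array_model import ValueMatrix
from methylpair.preprocess import (
    PreprocessConfig,
    adjust_batches,
    background_correct_m,
    beta_to_m,
    compute_beta,
    control_m_values,
    detection_pvalues,
    filter_detected,
    filter_probes,
    m_to_beta,
    quantile_normalize,
)

DATA = Path(__file__).parent / "data"


def vmatrix(values, kind="m_value"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ValueMatrix(
        [f"p{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        kind,
    )


class TestComputeBeta:
    @pytest.mark.parametrize(
        "meth,unmeth,expected",
        [(400.0, 500.0, 0.4), (0.0, 0.0, 0.0), (900.0, 0.0, 0.9)],
    )
    def test_offset_formula(self, meth, unmeth, expected):
        beta = compute_beta(
            vmatrix([[meth]], "meth_intensity"), vmatrix([[unmeth]], "unmeth_intensity")
        )
        assert beta.values[0, 0] == pytest.approx(expected)

    def test_strictly_below_one_for_positive_offset(self):
        beta = compute_beta(
            vmatrix([[1e9]], "meth_intensity"), vmatrix([[0.0]], "unmeth_intensity")
        )
        assert 0 < beta.values[0, 0] < 1

    def test_misaligned_matrices_rejected(self):
        meth = vmatrix([[1.0]], "meth_intensity")
        unmeth = ValueMatrix(["other"], ["s0"], [[1.0]], "unmeth_intensity")
        with pytest.raises(ValueError, match="aligned"):
            compute_beta(meth, unmeth)


class TestDetection:
    def test_probe_at_background_mean_has_p_half(self):
        controls = np.array([[90.0], [100.0], [110.0]])
        p = detection_pvalues(vmatrix([[100.0]], "meth_intensity"), controls)
        assert p.values[0, 0] == pytest.approx(0.5)

    def test_three_sigma_tail(self):
        # background 100 +- 10; a probe at 130 sits 3 sd out
        rng = np.random.default_rng(0)
        controls = rng.normal(100, 10, size=(4000, 1))
        controls = (controls - controls.mean()) / controls.std(ddof=1) * 10 + 100
        p = detection_pvalues(vmatrix([[130.0]], "meth_intensity"), controls)
        assert p.values[0, 0] == pytest.approx(stats.norm.sf(3.0), rel=1e-6)

    def test_strong_probe_approaches_zero(self):
        controls = np.array([[90.0], [110.0]])
        p = detection_pvalues(vmatrix([[1e6]], "meth_intensity"), controls)
        assert p.values[0, 0] < 1e-12

    def test_zero_control_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="zero control variance"):
            detection_pvalues(vmatrix([[5.0]], "meth_intensity"), np.full((3, 1), 100.0))

    def test_mean_p_filter_boundary_is_strict(self):
        values = vmatrix([[0.1], [0.2], [0.3]], "beta")
        detp = vmatrix([[0.001], [0.02], [0.009]], "detection_p")
        kept = filter_detected(values, detp, 0.01)
        assert kept.probe_ids == ["p0", "p2"]
        boundary = filter_detected(values, vmatrix([[0.01], [0.01], [0.01]], "detection_p"), 0.01)
        assert kept.shape[1] == 1 and boundary.shape[0] == 0


class TestBetaMTransforms:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_logit_points(self, beta, m):
        assert beta_to_m(np.array(beta)) == pytest.approx(m, abs=1e-12)

    def test_published_site_mean(self):
        # 41.8% methylation before the intervention at a 5'UTR site
        assert beta_to_m(np.array(0.418)) == pytest.approx(np.log2(0.418 / 0.582), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-30, 30))
    def test_round_trip_identity_on_m_scale(self, m):
        assert m_to_beta(beta_to_m(m_to_beta(np.array(m)))) == pytest.approx(
            m_to_beta(np.array(m)), abs=1e-12
        )

    def test_boundary_betas_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            m = beta_to_m(np.array([0.0, 1.0]))
        assert np.isfinite(m).all()


class TestBackgroundCorrection:
    def test_zero_median_is_identity(self):
        m = vmatrix([[1.0, 2.0], [3.0, 4.0]])
        controls = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        out = background_correct_m(m, controls)
        np.testing.assert_allclose(out.values, m.values)

    def test_column_shift_by_control_median(self):
        m = vmatrix([[1.0], [2.0]])
        out = background_correct_m(m, np.array([[0.5], [0.5]]))
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.5])

    def test_column_medians_shift_exactly(self):
        rng = np.random.default_rng(3)
        m = vmatrix(rng.normal(size=(50, 4)))
        controls = rng.normal(0.3, 0.1, size=(9, 4))
        out = background_correct_m(m, controls)
        np.testing.assert_allclose(
            np.median(out.values, axis=0),
            np.median(m.values, axis=0) - np.median(controls, axis=0),
            atol=1e-12,
        )

    def test_control_m_values_match_beta_chain(self):
        m = control_m_values(np.array([[100.0]]), offset=100.0)
        assert m[0, 0] == pytest.approx(0.0)  # beta = 100/200


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        out = quantile_normalize(vmatrix([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        m = vmatrix([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_ties_get_mean_of_reference_span(self):
        out = quantile_normalize(vmatrix([[1.0, 3.0], [1.0, 4.0], [2.0, 5.0]]))
        # reference = mean of sorted columns = [2, 2.5, 3.5]; ties span ranks 1-2
        np.testing.assert_allclose(out.values[:, 0], [2.25, 2.25, 3.5])
        np.testing.assert_allclose(out.values[:, 1], [2.0, 2.5, 3.5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent_and_columns_share_sorted_values(self, seed):
        rng = np.random.default_rng(seed)
        m = vmatrix(rng.normal(size=(20, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)
        ref = np.sort(once.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(once.values[:, j]), ref, atol=1e-12)

    def test_single_sample_returned_unchanged_with_warning(self):
        m = vmatrix([[1.0], [2.0]])
        with pytest.warns(UserWarning, match="fewer than 2 samples"):
            out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)


class TestBatchAdjustment:
    def test_matches_reference_empirical_bayes_output(self):
        # frozen output of the reference R implementation (sva::ComBat,
        # parametric priors, timepoint as protected covariate) on a small
        # synthetic matrix; both fixture files are synthetic
        dat = pd.read_csv(DATA / "combat_input_synthetic.tsv", sep="\t", index_col=0)
        design = pd.read_csv(DATA / "combat_design_synthetic.tsv", sep="\t")
        vm = ValueMatrix(list(dat.index), list(dat.columns), dat.to_numpy(), "m_value")
        out = adjust_batches(vm, design["batch"], design["timepoint"])
        expected = pd.read_csv(
            DATA / "combat_expected_synthetic.tsv", sep="\t", index_col=0
        ).to_numpy()
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_single_batch_is_identity(self):
        m = vmatrix(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.warns(UserWarning, match="single batch"):
            out = adjust_batches(m, ["B1"] * 4)
        np.testing.assert_allclose(out.values, m.values)

    def test_pure_constant_shift_removed(self):
        rng = np.random.default_rng(1)
        n = 600
        base = rng.normal(0, 1, size=(n, 1)) + rng.normal(0, 0.2, size=(n, 12))
        shifted = base.copy()
        shifted[:, 6:] += 0.8
        m = vmatrix(shifted)
        out = adjust_batches(m, ["B1"] * 6 + ["B2"] * 6)
        gap = out.values[:, :6].mean() - out.values[:, 6:].mean()
        # the 0.8 shift is removed up to empirical-Bayes estimation noise
        # (shrinkage with 6 samples per batch leaves a small residual)
        assert abs(gap) < 0.8 * 0.03
        per_probe_gap = out.values[:, 6:].mean(axis=1) - out.values[:, :6].mean(axis=1)
        assert abs(np.median(per_probe_gap)) < 0.05

    def test_null_batches_nearly_identity(self):
        rng = np.random.default_rng(2)
        m = vmatrix(rng.normal(0, 1, size=(500, 12)))
        out = adjust_batches(m, ["B1"] * 6 + ["B2"] * 6)
        # no real batch effect: the adjustment is bounded by shrinkage noise
        # (about half of the per-batch mean estimation error gets removed)
        assert np.abs(out.values - m.values).mean() < 0.12
        assert np.corrcoef(out.values.ravel(), m.values.ravel())[0, 1] > 0.98

    def test_confounded_batch_rejected(self):
        m = vmatrix(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="confounded"):
            adjust_batches(m, ["B1", "B1", "B2", "B2"], ["before", "before", "after", "after"])


class TestBlacklistFilter:
    def test_boundaries(self):
        annotation = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c", "d"],
                "cross_reactive_bases": [49, 47, 0, 0],
                "snp_maf": [0.0, 0.0, 0.05, 0.06],
            }
        )
        keep = filter_probes(annotation, PreprocessConfig())
        # cross-reactive >= 49 excluded; 47 retained; MAF 0.05 retained (strict >)
        np.testing.assert_array_equal(keep, [False, True, True, False])
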