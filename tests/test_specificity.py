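import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from isospec import (
    ExpressionMatrix,
    QPFit,
    SampleAnnotation,
    SimulationConfig,
    ValidationError,
    bh_fdr,
    decide_specific,
    median_fold_change,
    run_specificity,
    simulate_dataset,
    t1_statistic,
    t2_statistic,
    top_specific,
    truth_frame,
)


def make_fit(beta, var, labels=None):
    beta = np.asarray(beta, dtype=float)
    labels = labels or [f"g{i}" for i in range(len(beta))]
    return QPFit(
        group_labels=list(labels),
        group_counts=np.full(len(beta), 10),
        beta=beta,
        cov_beta=np.diag(np.asarray(var, dtype=float)),
        phi=1.0,
        robust_weights=np.ones(10 * len(beta)),
        n_iter=3,
        converged=True,
        all_zero_group=np.zeros(len(beta), bool),
    )


class TestBHFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_oracle(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_manual_cumulative_min(self, p):
        """BH equals p*(n/rank) followed by a reverse cumulative minimum."""
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * n / np.arange(1, n + 1)
        manual = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        expected = np.empty(n)
        expected[order] = manual
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_fdr(bad)


class TestT1:
    def test_equal_betas_give_zero(self):
        fit = make_fit([1.0] * 5, [0.1] * 5)
        t1, p1 = t1_statistic(fit, "g0")
        assert t1 == 0.0 and p1 == 1.0

    def test_hand_computed_contrast(self):
        beta = np.array([2.0, 0, 0, 0, 0])
        var = np.array([0.04, 0.01, 0.01, 0.01, 0.01])
        fit = make_fit(beta, var)
        t1, p1 = t1_statistic(fit, "g0")
        se = np.sqrt(0.04 + 4 * 0.01 / 16)
        assert t1 == pytest.approx(2.0 / se)
        assert p1 == pytest.approx(2 * stats.norm.sf(2.0 / se))

    def test_sign_flips_for_underexpressed_target(self):
        fit = make_fit([2.0, 0.5, 0.5, 0.5], [0.05] * 4)
        t_over, _ = t1_statistic(fit, "g0")
        fit_under = make_fit([-2.0, 0.5, 0.5, 0.5], [0.05] * 4)
        t_under, _ = t1_statistic(fit_under, "g0")
        assert t_over > 0 > t_under

    def test_unknown_target(self):
        with pytest.raises(ValidationError):
            t1_statistic(make_fit([1, 2], [0.1, 0.1]), "nope")


class TestT2:
    def test_identical_remaining_betas(self):
        fit = make_fit([5.0, 1.0, 1.0, 1.0], [0.1] * 4)
        t2, df2, p2 = t2_statistic(fit, {"g0"})
        assert t2 == 0.0 and p2 == 1.0 and df2 == 2

    def test_df_arithmetic_five_groups(self):
        fit = make_fit(np.arange(5.0), [0.1] * 5)
        _, df2, _ = t2_statistic(fit, {"g0"})
        assert df2 == 3

    def test_quadratic_form_oracle(self, rng):
        beta = rng.normal(size=5)
        var = rng.uniform(0.01, 0.5, size=5)
        fit = make_fit(beta, var)
        t2, df2, p2 = t2_statistic(fit, {"g4"})
        # independent oracle: full contrast-matrix quadratic form
        C = np.array([[1, -1, 0, 0], [0, 1, -1, 0], [0, 0, 1, -1.0]])
        b = beta[:4]
        S = np.diag(var[:4])
        expected = b @ C.T @ np.linalg.solve(C @ S @ C.T, C @ b)
        assert t2 == pytest.approx(expected, rel=1e-10)
        assert p2 == pytest.approx(stats.chi2.sf(expected, 3), rel=1e-10)

    def test_too_few_remaining(self):
        fit = make_fit([1.0, 2.0, 3.0], [0.1] * 3)
        with pytest.raises(ValidationError):
            t2_statistic(fit, {"g0", "g1"})


class TestFoldChange:
    def test_plain_ratio(self):
        assert median_fold_change([10, 10, 10, 2, 2, 2], [1, 1, 1, 0, 0, 0], 0.0) == 5.0

    def test_identical_values(self):
        assert median_fold_change([3, 3, 3, 3], [1, 1, 0, 0], 0.01) == 1.0

    def test_zero_rest_uses_pseudocount(self):
        fc = median_fold_change([1, 1, 0, 0], [1, 1, 0, 0], 0.01)
        assert fc == pytest.approx(1.01 / 0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            median_fold_change([1, 2], [1, 1], 0.01)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "fdr1,fdr2,fc,t1,expected",
        [
            (0.005, 0.2, 1.5, 3.0, (True, "primary")),
            (0.005, 0.05, 6.0, 3.0, (True, "rescue")),
            (0.5, 0.9, 100.0, 3.0, (False, "none")),
            (0.005, 0.05, 4.0, 3.0, (False, "none")),  # rescue fails fc gate
            (0.005, 0.005, 6.0, 3.0, (False, "none")),  # rescue fails fdr2 gate
            (0.005, 0.2, 1.5, -3.0, (False, "none")),  # under-expressed
            (0.02, 0.2, 10.0, 3.0, (False, "none")),  # fails fdr1 gate
            (0.005, 0.15, 6.0, 3.0, (True, "primary")),  # both paths -> primary
        ],
    )
    def test_rule_paths(self, fdr1, fdr2, fc, t1, expected):
        assert decide_specific(fdr1, fdr2, fc, t1) == expected

    def test_pure_function(self):
        args = (0.001, 0.5, 2.0, 4.0)
        assert decide_specific(*args) == decide_specific(*args)


class TestRunSpecificity:
    def test_planted_markers_recovered(self, planted_dataset, planted_truth_frame):
        _, x, samples, _, _ = planted_dataset
        res = run_specificity(x, samples)
        planted = planted_truth_frame[planted_truth_frame.pattern == "specific"]
        detections = res[res.decision]
        hits = detections.merge(
            planted, left_on=["feature_id", "subtype"], right_on=["isoform_id", "subtypes"]
        )
        sensitivity = len(hits) / len(planted)
        assert sensitivity >= 0.9
        # declared subtype matches the planted subtype for nearly all planted detections
        planted_det = detections.merge(planted, left_on="feature_id", right_on="isoform_id")
        assert len(hits) / len(planted_det) >= 0.95

    def test_constant_feature_never_decided(self):
        values = np.vstack([np.full(20, 7.0), np.random.default_rng(1).gamma(2, 10, 20)])
        x = ExpressionMatrix(["const", "noise"], [f"s{i}" for i in range(20)], values)
        samples = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(20)],
                    "subtype": np.repeat(["A", "B", "C", "D"], 5),
                    "split": "discovery",
                }
            )
        )
        res = run_specificity(x, samples)
        assert not res.loc[res.feature_id == "const", "decision"].any()

    def test_statistics_invariant_to_label_order(self, planted_dataset):
        _, x, samples, _, _ = planted_dataset
        res1 = run_specificity(x, samples)
        shuffled = SampleAnnotation(
            samples.frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        res2 = run_specificity(x, shuffled)
        merged = res1.merge(res2, on=["feature_id", "subtype"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.t1_a, merged.t1_b, rtol=1e-9)
        np.testing.assert_allclose(merged.t2_a, merged.t2_b, rtol=1e-9)

    def test_sensitivity_monotone_in_effect_fold(self):
        sens = []
        for fold in (1.5, 3.0, 8.0):
            cfg = SimulationConfig(
                n_genes=400,
                samples_per_subtype=(10,) * 5,
                effect_fold=fold,
                n_coexpressed=0,
                seed=13,
            )
            x, samples, _, truth = simulate_dataset(cfg)
            tf = truth_frame(truth)
            planted = tf[tf.pattern == "specific"]
            res = run_specificity(x, samples)
            hits = res[res.decision].merge(
                planted, left_on=["feature_id", "subtype"], right_on=["isoform_id", "subtypes"]
            )
            sens.append(len(hits) / len(planted))
        assert sens[0] <= sens[1] <= sens[2]

    def test_requires_two_subtypes(self):
        x = ExpressionMatrix(["f"], [f"s{i}" for i in range(4)], [[1.0, 2.0, 3.0, 4.0]])
        samples = SampleAnnotation(
            pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(4)], "subtype": "A", "split": "discovery"}
            )
        )
        with pytest.raises(ValidationError):
            run_specificity(x, samples)

    def test_top_ranking_deterministic(self, planted_dataset):
        _, x, samples, _, _ = planted_dataset
        res = run_specificity(x, samples)
        top = top_specific(res, n=5)
        assert (top.groupby("subtype").size() <= 5).all()
        again = top_specific(res, n=5)
        pd.testing.assert_frame_equal(top, again)
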