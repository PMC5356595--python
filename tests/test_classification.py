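import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isospec import (
    ExpressionMatrix,
    PanelSelectionError,
    SampleAnnotation,
    SimulationConfig,
    TranscriptAnnotation,
    ValidationError,
    aggregate_gene_level,
    compare_isoform_gene_auc,
    fit_l1_panel,
    incremental_panel_auc,
    marker_auc,
    marker_auc_table,
    simulate_dataset,
    truth_frame,
)


def brute_force_auc(values, labels):
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    pos, neg = values[labels], values[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestMarkerAUC:
    def test_four_pair_example(self):
        assert marker_auc([3, 5, 1, 4], [1, 1, 0, 0]) == 0.75

    def test_perfect_separation(self):
        assert marker_auc([10, 11, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_pure_ties_are_half(self):
        assert marker_auc([4, 4, 4, 4], [1, 1, 0, 0]) == 0.5

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=200),
        st.data(),
    )
    def test_equals_brute_force_pair_counting(self, values, data):
        n = len(values)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda l: any(l) and not all(l)
            )
        )
        assert marker_auc(values, labels) == pytest.approx(brute_force_auc(values, labels))

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=50),
        st.data(),
    )
    def test_label_flip_antisymmetry(self, values, data):
        n = len(values)
        labels = np.array(
            data.draw(
                st.lists(st.booleans(), min_size=n, max_size=n).filter(
                    lambda l: any(l) and not all(l)
                )
            )
        )
        assert marker_auc(values, labels) + marker_auc(values, ~labels) == pytest.approx(1.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.gamma(2.0, 5.0, 100)
        labels = rng.random(100) < 0.3
        assert marker_auc(values, labels) == pytest.approx(roc_auc_score(labels, values))

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            marker_auc([1, 2], [1, 1])


def two_class_annotation(samples_per_class=12):
    n = samples_per_class
    ids = [f"s{i}" for i in range(2 * n)]
    return ids, SampleAnnotation(
        pd.DataFrame(
            {"sample_id": ids, "subtype": ["A"] * n + ["B"] * n, "split": "discovery"}
        )
    )


class TestIsoformVsGene:
    def test_single_isoform_gene_delta_zero(self, rng):
        ids, samples = two_class_annotation()
        values = rng.gamma(2.0, 10.0, size=(1, 24))
        x = ExpressionMatrix(["i1"], ids, values)
        ann = [TranscriptAnnotation("i1", "G1", True, 500)]
        iso = marker_auc_table(x, samples, level="isoform")
        gene = marker_auc_table(aggregate_gene_level(x, ann), samples, level="gene")
        delta = compare_isoform_gene_auc(iso, gene, ann)
        assert (delta.delta_discovery == 0).all()

    def test_signal_isoform_beats_diluted_gene(self, rng):
        ids, samples = two_class_annotation()
        signal = np.concatenate([rng.gamma(20, 1, 12), rng.gamma(100, 1, 12)])
        noise = rng.gamma(4.0, 100.0, size=24)  # heavy, noisy background
        x = ExpressionMatrix(["sig", "noi"], ids, np.vstack([signal, noise]))
        ann = [
            TranscriptAnnotation("sig", "G1", True, 500),
            TranscriptAnnotation("noi", "G1", True, 700),
        ]
        iso = marker_auc_table(x, samples, level="isoform")
        gene = marker_auc_table(aggregate_gene_level(x, ann), samples, level="gene")
        delta = compare_isoform_gene_auc(iso, gene, ann)
        row = delta[(delta.feature_id == "sig") & (delta.target_subtype == "B")]
        assert float(row.delta_discovery.iloc[0]) > 0
        assert delta.delta_discovery.between(-1, 1).all()

    def test_unmapped_isoform_rejected(self, rng):
        ids, samples = two_class_annotation()
        x = ExpressionMatrix(["i1"], ids, rng.gamma(2.0, 10.0, size=(1, 24)))
        iso = marker_auc_table(x, samples, level="isoform")
        with pytest.raises(ValidationError):
            compare_isoform_gene_auc(iso, iso, [])


def panel_scenario(seed=0):
    cfg = SimulationConfig(
        subtype_names=("LumA", "LumB"),
        samples_per_subtype=(100, 100),
        n_genes=250,
        n_specific=(0, 5),
        n_coexpressed=0,
        seed=seed,
    )
    return simulate_dataset(cfg)


class TestL1Panel:
    def test_separating_feature_selected_first(self, rng):
        ids, samples = two_class_annotation(20)
        noise = rng.gamma(2.0, 10.0, size=(30, 40))
        separator = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(50, 60, 20)])
        values = np.vstack([separator, noise])
        x = ExpressionMatrix(["sep"] + [f"n{i}" for i in range(30)], ids, values)
        panel = fit_l1_panel(x, samples, ("A", "B"), seed=1)
        assert panel.selected_features[0] == "sep"

    def test_infinite_penalty_reports_failure(self, rng):
        ids, samples = two_class_annotation(10)
        x = ExpressionMatrix(
            [f"f{i}" for i in range(5)], ids, rng.gamma(2.0, 10.0, size=(5, 20))
        )
        with pytest.raises(PanelSelectionError, match="no features"):
            fit_l1_panel(x, samples, ("A", "B"), penalty_grid=[1e-8], seed=1)

    def test_planted_markers_recovered(self):
        x, samples, _, truth = panel_scenario(seed=2)
        planted = set(truth_frame(truth).query("pattern == 'specific'").isoform_id)
        panel = fit_l1_panel(x, samples, ("LumA", "LumB"), seed=2)
        assert len(planted & set(panel.selected_features)) >= 4

    def test_incremental_curve_consistency(self):
        x, samples, _, _ = panel_scenario(seed=3)
        panel = fit_l1_panel(x, samples, ("LumA", "LumB"), seed=3)
        curve = incremental_panel_auc(panel, x, samples)
        assert [k for k, *_ in curve] == list(range(1, len(panel.selected_features) + 1))
        assert all(0 <= a <= 1 and 0 <= v <= 1 for _, a, v in curve)
        with pytest.raises(ValidationError):
            incremental_panel_auc(panel, x, samples, max_k=len(panel.selected_features) + 1)

    def test_coefficients_sorted_by_magnitude(self):
        x, samples, _, _ = panel_scenario(seed=4)
        panel = fit_l1_panel(x, samples, ("LumA", "LumB"), seed=4)
        mags = np.abs(panel.coefficients)
        assert (np.diff(mags) <= 1e-12).all()

    def test_single_class_rejected(self, rng):
        ids = [f"s{i}" for i in range(10)]
        samples = SampleAnnotation(
            pd.DataFrame({"sample_id": ids, "subtype": "A", "split": "discovery"})
        )
        x = ExpressionMatrix(["f1"], ids, rng.gamma(2.0, 10.0, size=(1, 10)))
        with pytest.raises(ValidationError):
            fit_l1_panel(x, samples, ("A", "B"), seed=0)
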