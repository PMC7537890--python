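"""Penultimate-layer feature extraction and the PCA comparison."""

import numpy as np
import pandas as pd
import pytest

import esvnet
from esvnet.features import FeatureConfig, SynergisticFeature
from esvnet.table import SampleTable

from conftest import make_relu_probe_model


def iid_table(n=2000, seed=0, p=23):
    rng = np.random.default_rng(seed)
    raw = pd.DataFrame(rng.standard_normal((n, p)),
                       columns=list(esvnet.FACTOR_CODES[:p]))
    raw["Y"] = rng.standard_normal(n)
    return SampleTable.from_raw(raw, percent_columns=())


class TestPenultimateActivations:
    def test_linear_reconstruction_identity(self, trained):
        model, _ = trained
        X = np.random.default_rng(0).standard_normal((1000, 23))
        h = esvnet.penultimate_activations(model, X)
        recon = h @ model.output_weights + model.output_bias
        np.testing.assert_allclose(recon, model.predict(X), atol=1e-6)

    def test_relu_non_negative(self, trained):
        model, _ = trained
        X = np.random.default_rng(1).standard_normal((200, 23))
        assert (esvnet.penultimate_activations(model, X) >= 0).all()

    def test_zeroing_one_output_weight_is_exact_perturbation(self, trained):
        model, _ = trained
        X = np.random.default_rng(2).standard_normal((100, 23))
        h = esvnet.penultimate_activations(model, X)
        j = int(np.argmax(np.abs(model.output_weights)))
        clipped = esvnet.TrainedSurrogate(
            weights=[W.copy() for W in model.weights],
            biases=[b.copy() for b in model.biases],
            activations=list(model.activations))
        w_j = clipped.weights[-1][j, 0]
        clipped.weights[-1][j, 0] = 0.0
        delta = clipped.predict(X) - model.predict(X)
        np.testing.assert_allclose(delta, -w_j * h[:, j], atol=1e-10)

    def test_nonlinear_output_rejected(self):
        model = esvnet.TrainedSurrogate(
            weights=[np.zeros((23, 2)), np.zeros((2, 1))],
            biases=[np.zeros(2), np.zeros(1)],
            activations=["relu", "linear"])
        model.activations[-1] = "relu"  # violate the contract post hoc
        with pytest.raises(ValueError):
            esvnet.penultimate_activations(model, np.zeros((1, 23)))


class TestExtractFeatures:
    def test_single_neuron_closed_form(self, fused_table):
        # h_1 = ReLU(2 x_A1), w_1 = 0.5: the contribution for A1 must equal
        # 0.5 * (sweep range of ReLU(2 x)) computed directly
        j = fused_table.codes.index("A1")
        model = make_relu_probe_model(j, scale=2.0, out_weight=0.5)
        feats = esvnet.extract_features(model, fused_table,
                                        FeatureConfig(contrib_threshold=1e-12))
        assert len(feats) == 1
        col = fused_table.column("A1")
        xs = np.linspace(col.min(), col.max(), 201)
        expected = 0.5 * np.ptp(np.maximum(2.0 * xs, 0.0))
        assert feats[0].contributions["A1"] == pytest.approx(expected, rel=1e-12)
        assert feats[0].weight == 0.5
        assert "A1" in feats[0].contained

    def test_zero_weight_neuron_excluded(self, fused_table):
        model = make_relu_probe_model(0, scale=1.0, out_weight=0.0)
        assert esvnet.extract_features(model, fused_table) == []

    def test_contribution_threshold_selects_contained(self, fused_table):
        # scale the probe so the A1 contribution lands just at published
        # magnitudes: contributions >= 3e-4 are contained, smaller are not
        j = fused_table.codes.index("A1")
        col = fused_table.column("A1")
        sweep_range = np.ptp(np.maximum(col.min()
                                        + (col.max() - col.min())
                                        * np.linspace(0, 1, 201), 0.0))
        w = 0.000964 / sweep_range
        model = make_relu_probe_model(j, scale=1.0, out_weight=w)
        feats = esvnet.extract_features(model, fused_table,
                                        FeatureConfig(contrib_threshold=3e-4))
        assert len(feats) == 1
        assert feats[0].contributions["A1"] == pytest.approx(0.000964, rel=1e-9)
        assert feats[0].contained == ("A1",)

    def test_retained_at_most_penultimate_width(self, trained, fused_table):
        model, _ = trained
        feats = esvnet.extract_features(model, fused_table)
        assert len(feats) <= 16
        weights = [f.weight for f in feats]
        assert weights == sorted(weights, reverse=True)
        for f in feats:
            assert set(f.contained) <= set(esvnet.FACTOR_CODES)
            assert all(v >= 0 for v in f.contributions.values())
            assert f.contained == tuple(
                c for c, v in f.contributions.items() if v >= 3e-4)

    def test_strong_oracle_factor_is_captured(self, oracle_fit):
        table, truth, model, _ = oracle_fit
        feats = esvnet.extract_features(model, table)
        contained_union = set().union(*(f.contained for f in feats))
        assert {"A5", "B5"} <= contained_union

    def test_contribution_grid_refinement_stability(self, oracle_fit):
        table, _, model, _ = oracle_fit
        coarse = esvnet.extract_features(model, table,
                                         FeatureConfig(sweep_points=201))
        dense = esvnet.extract_features(model, table,
                                        FeatureConfig(sweep_points=2001))
        coarse_by_neuron = {f.neuron: f for f in coarse}
        for f in dense:
            c = coarse_by_neuron[f.neuron]
            scale = max(max(f.contributions.values()), 1e-12)
            for code in f.contributions:
                drift = abs(f.contributions[code] - c.contributions[code])
                assert drift < 0.02 * scale


class TestPCACompare:
    def test_loadings_orthonormal_variance_nonincreasing(self, fused_table):
        pca = esvnet.pca_compare(fused_table, n_components=6)
        gram = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        evr = pca.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()

    def test_isotropic_null_has_flat_spectrum(self):
        table = iid_table(n=10_000, seed=3)
        pca = esvnet.pca_compare(table, n_components=23)
        evr = pca.explained_variance_ratio
        assert evr.max() / evr.min() < 1.5

    def test_duplicated_column_pair_dominates_first_component(self):
        rng = np.random.default_rng(4)
        raw = pd.DataFrame(
            0.05 * rng.standard_normal((500, 23)),
            columns=list(esvnet.FACTOR_CODES))
        shared = rng.standard_normal(500)
        raw["A1"] = shared
        raw["A2"] = shared
        raw["Y"] = rng.standard_normal(500)
        table = SampleTable.from_raw(raw, percent_columns=())
        pca = esvnet.pca_compare(table, n_components=3, loading_threshold=0.1)
        assert {"A1", "A2"} <= set(pca.contained[0])
        l1 = dict(zip(pca.codes, pca.loadings[0]))
        assert abs(l1["A1"]) == pytest.approx(abs(l1["A2"]), rel=1e-6)

    def test_loading_threshold_defines_contained(self, fused_table):
        pca = esvnet.pca_compare(fused_table, n_components=4,
                                 loading_threshold=0.3)
        for comp, contained in zip(pca.loadings, pca.contained):
            expected = {c for c, v in zip(pca.codes, comp) if abs(v) >= 0.3}
            assert set(contained) == expected

    def test_component_count_limits(self, fused_table):
        with pytest.raises(ValueError):
            esvnet.pca_compare(fused_table, n_components=24)
        with pytest.raises(ValueError):
            esvnet.pca_compare(iid_table(n=5), n_components=6)


class TestFeatureReport:
    def test_empty_feature_list_keeps_pca_side(self, fused_table):
        pca = esvnet.pca_compare(fused_table, n_components=3)
        report = esvnet.feature_report([], pca)
        assert len(report) == 3
        assert report["feature_factors"].eq("").all()
        assert report["pc_factors"].notna().all()

    def test_identical_sets_full_overlap(self, fused_table):
        pca = esvnet.pca_compare(fused_table, n_components=1,
                                 loading_threshold=0.0)
        feat = SynergisticFeature(
            neuron=0, weight=1.0,
            contributions={c: 1.0 for c in pca.contained[0]},
            contained=pca.contained[0])
        report = esvnet.feature_report([feat], pca)
        assert report.loc[0, "overlap"] == len(pca.contained[0])

    def test_mismatched_factor_sets_rejected(self, fused_table):
        pca = esvnet.pca_compare(fused_table, n_components=1)
        feat = SynergisticFeature(neuron=0, weight=1.0,
                                  contributions={"ZZ": 1.0}, contained=("ZZ",))
        with pytest.raises(ValueError):
            esvnet.feature_report([feat], pca)
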