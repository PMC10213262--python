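"""The tanh/softmax classifier: forward pass, training, CV, interpretability."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import stromatype as st
from stromatype import GenePanel, PanelEntry, TrainConfig, TrainedModel
from stromatype.model import output_layer_probabilities


def _features(values, genes, samples):
    return st.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _zero_model(genes=("g1", "g2")):
    g = len(genes)
    return TrainedModel(
        hidden_weights=np.zeros((g, 2)),
        hidden_biases=np.zeros(2),
        output_weights=np.zeros((2, 4)),
        output_biases=np.zeros(4),
        gene_order=list(genes),
    )


class TestForwardPass:
    def test_zero_parameters_give_uniform_probabilities(self):
        model = _zero_model()
        feats = _features([[1.0, -2.0], [0.5, 3.0]], ["g1", "g2"], ["s1", "s2"])
        calls = st.predict_subtypes(model, feats)
        assert np.allclose(calls.probabilities.to_numpy(), 0.25)
        assert np.allclose(calls.latent.to_numpy(), 0.0)
        # tie-break: first class in (A, IA, ID, IS) order
        assert (calls.subtype == "A").all()

    def test_output_bias_log2_closed_form(self):
        model = _zero_model()
        model.output_biases = np.array([np.log(2.0), 0.0, 0.0, 0.0])
        feats = _features([[0.7], [0.1]], ["g1", "g2"], ["s1"])
        calls = st.predict_subtypes(model, feats)
        assert np.allclose(
            calls.probabilities.loc["s1"], [0.4, 0.2, 0.2, 0.2], atol=1e-12
        )
        assert calls.subtype["s1"] == "A"

    def test_hand_computed_two_gene_forward_pass(self):
        w1 = np.array([[0.5, -1.0], [2.0, 0.25]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[1.0, -0.5, 0.0, 2.0], [0.3, 0.7, -1.0, 0.4]])
        b2 = np.array([0.05, -0.1, 0.2, 0.0])
        model = TrainedModel(w1, b1, w2, b2, gene_order=["g1", "g2"])
        x = np.array([0.3, -0.8])
        h = np.tanh(x @ w1 + b1)
        logits = h @ w2 + b2
        p = np.exp(logits) / np.exp(logits).sum()
        calls = st.predict_subtypes(
            model, _features(x.reshape(2, 1), ["g1", "g2"], ["s1"])
        )
        assert np.allclose(calls.probabilities.loc["s1"], p, atol=1e-9)
        assert np.allclose(calls.latent.loc["s1"], h, atol=1e-9)
        assert calls.max_probability["s1"] == pytest.approx(p.max(), abs=1e-9)

    def test_probabilities_sum_to_one(self, std_calls):
        sums = std_calls.probabilities.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (
            std_calls.subtype
            == std_calls.probabilities.idxmax(axis=1).str.removeprefix("P_")
        ).all()

    def test_latent_strictly_inside_tanh_range(self, std_calls):
        lat = std_calls.latent.to_numpy()
        assert (lat > -1).all() and (lat < 1).all()

    def test_gene_mismatch_errors(self, std_model, std_cohort):
        model, _ = std_model
        feats = _features([[0.0], [0.0]], ["gA", "gB"], ["s1"])
        with pytest.raises(ValueError, match="gA"):
            st.predict_subtypes(model, feats)

    def test_predict_is_pure(self, std_model, std_cohort):
        model, _ = std_model
        expr, _, _ = std_cohort
        c1 = st.classify_raw(model, expr)
        c2 = st.classify_raw(model, expr)
        pd.testing.assert_frame_equal(c1.table, c2.table)


class TestTraining:
    def test_determinism_same_seed_same_parameters(self, std_cohort, std_panel):
        expr, _, _ = std_cohort
        m1, _ = st.train_from_raw(expr, std_panel, TrainConfig(seed=11))
        m2, _ = st.train_from_raw(expr, std_panel, TrainConfig(seed=11))
        assert np.array_equal(m1.hidden_weights, m2.hidden_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)

    def test_missing_class_errors_by_name(self, std_cohort, std_panel):
        expr, _, truth = std_cohort
        labels = truth.subtypes.copy()
        labels[labels == "IS"] = "IA"
        ref = st.fit_reference(expr, std_panel)
        feats = st.map_to_reference(expr, ref)
        with pytest.raises(ValueError, match="IS"):
            st.train_model(feats, labels)

    def test_final_loss_not_above_initial(self, std_model):
        model, _ = std_model
        assert model.metadata["final_loss"] <= model.metadata["initial_loss"]

    def test_stopping_rule_bounds_iterations(self, std_model):
        model, _ = std_model
        assert model.metadata["n_iterations"] <= 1000

    def test_held_out_accuracy_with_noise(self, std_model):
        model, _ = std_model
        cfg = st.SimConfig(n_samples=400, seed=1234)
        expr, _, truth = st.simulate_cohort(cfg)
        calls = st.classify_raw(model, expr)
        assert (calls.subtype == truth.subtypes).mean() >= 0.90

    def test_model_json_round_trip(self, std_model, std_cohort, tmp_path):
        model, _ = std_model
        expr, _, _ = std_cohort
        p = tmp_path / "model.json"
        model.save(p)
        back = TrainedModel.load(p)
        c1 = st.classify_raw(model, expr)
        c2 = st.classify_raw(back, expr)
        assert np.allclose(
            c1.probabilities.to_numpy(), c2.probabilities.to_numpy(), atol=1e-12
        )
        assert back.metadata["seed"] == model.metadata["seed"]

    def test_matches_reference_mlp_implementation(self, std_cohort, std_panel):
        """Cross-check against an independent MLP of identical architecture."""
        from sklearn.neural_network import MLPClassifier

        expr, _, truth = std_cohort
        ref = st.fit_reference(expr, std_panel)
        feats = st.map_to_reference(expr, ref)
        _, labels = st.label_cohort(expr, std_panel)
        x = feats.to_array().T
        n_tr = 300
        ours = st.train_model(
            st.ExpressionMatrix(feats.values.iloc[:, :n_tr]),
            labels.labels.iloc[:n_tr],
            TrainConfig(seed=2),
        )
        theirs = MLPClassifier(
            hidden_layer_sizes=(2,),
            activation="tanh",
            solver="lbfgs",
            alpha=1e-4,
            max_iter=1000,
            random_state=2,
        ).fit(x[:n_tr], labels.labels.iloc[:n_tr])
        ours_acc = (
            st.predict_subtypes(
                ours, st.ExpressionMatrix(feats.values.iloc[:, n_tr:])
            ).subtype.to_numpy()
            == labels.labels.iloc[n_tr:].to_numpy()
        ).mean()
        theirs_acc = (
            theirs.predict(x[n_tr:]) == labels.labels.iloc[n_tr:].to_numpy()
        ).mean()
        assert ours_acc >= 0.9
        assert abs(ours_acc - theirs_acc) <= 0.05


class TestLatentGeometry:
    def test_latent_equals_predict_intermediate(self, std_model, std_cohort):
        model, _ = std_model
        expr, _, _ = std_cohort
        feats = st.map_to_reference(expr, model.reference)
        calls = st.predict_subtypes(model, feats)
        lat = st.latent_coordinates(model, feats)
        pd.testing.assert_frame_equal(lat, calls.latent)

    def test_output_layer_reproduces_probabilities(self, std_calls, std_model):
        model, _ = std_model
        p = output_layer_probabilities(model, std_calls.latent.to_numpy())
        assert np.allclose(p, std_calls.probabilities.to_numpy(), atol=1e-9)

    def test_distance_from_origin_tracks_confidence(self):
        cfg = st.SimConfig(n_samples=400, seed=7, latent_mode="continuous",
                           latent_sd=1.0)
        expr, _, _ = st.simulate_cohort(cfg)
        model, _ = st.train_from_raw(
            expr, cfg.panel(), TrainConfig(seed=7, alpha=1e-2)
        )
        calls = st.classify_raw(model, expr)
        dist = np.hypot(calls.table["neuron1"], calls.table["neuron2"])
        rho = spearmanr(dist, calls.max_probability).statistic
        assert rho > 0.5


@pytest.fixture(scope="module")
def small_training():
    cfg = st.SimConfig(n_samples=120, seed=5, loading_effect=3.0)
    expr, _, _ = st.simulate_cohort(cfg)
    panel = cfg.panel()
    ref = st.fit_reference(expr, panel)
    feats = st.map_to_reference(expr, ref)
    _, labels = st.label_cohort(expr, panel)
    return feats, labels.labels


class TestCrossValidation:
    def test_single_grid_point_is_returned(self, small_training):
        feats, labels = small_training
        cfg = TrainConfig(seed=5, cv_folds=4, cv_repeats=1, alpha_grid=(0.01,))
        cv = st.cross_validate(feats, labels, cfg)
        assert cv.best_alpha == 0.01

    def test_empty_grid_errors(self, small_training):
        feats, labels = small_training
        with pytest.raises(ValueError, match="grid"):
            st.cross_validate(
                feats, labels, TrainConfig(cv_folds=4, cv_repeats=1, alpha_grid=())
            )

    def test_each_sample_validated_once_per_repeat(self, small_training):
        feats, labels = small_training
        cfg = TrainConfig(seed=5, cv_folds=4, cv_repeats=2, alpha_grid=(0.01,))
        from sklearn.model_selection import RepeatedStratifiedKFold

        splitter = RepeatedStratifiedKFold(n_splits=4, n_repeats=2, random_state=5)
        y = labels.reindex(feats.sample_ids).to_numpy()
        x = feats.to_array().T
        seen = np.zeros((2, len(y)), dtype=int)
        for split_no, (_, va) in enumerate(splitter.split(x, y)):
            seen[split_no // 4, va] += 1
        assert (seen == 1).all()

    def test_heavy_regularization_underfits_and_is_rejected(self, small_training):
        feats, labels = small_training
        cfg = TrainConfig(seed=5, cv_folds=4, cv_repeats=1, alpha_grid=(1e-4, 100.0))
        cv = st.cross_validate(feats, labels, cfg)
        assert cv.best_alpha == 1e-4
        means = cv.summary.set_index("alpha")["mean"]
        assert means[1e-4] > means[100.0]


class TestNeuronAxisAlignment:
    def test_constructed_perfect_alignment(self):
        genes = [f"i{k}" for k in range(5)] + [f"a{k}" for k in range(5)]
        panel = GenePanel(
            [PanelEntry(g, "immune") for g in genes[:5]]
            + [PanelEntry(g, "angiogenesis") for g in genes[5:]]
        )
        w1 = np.full((10, 2), -1.0)
        w1[:5, 0] = 1.0  # neuron 1: +1 for immune genes, −1 otherwise
        model = TrainedModel(
            w1, np.zeros(2), np.zeros((2, 4)), np.zeros(4), gene_order=genes
        )
        rep = st.neuron_axis_alignment(model, panel)
        assert rep.assignment["immune"] == 0
        assert rep.alignment["immune"] == 1.0
        assert rep.interpretable or rep.alignment["angiogenesis"] >= 0.0

    def test_trained_models_align_with_biology(self, std_model, std_panel):
        model, _ = std_model
        rep = st.neuron_axis_alignment(model, std_panel)
        assert rep.alignment["immune"] >= 0.8
        assert rep.alignment["angiogenesis"] >= 0.8
        assert rep.interpretable

    def test_permuted_annotations_destroy_alignment(self, std_model, std_panel):
        model, _ = std_model
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            axes = rng.permutation(
                ["immune"] * 62 + ["angiogenesis"] * 62
            )
            shuffled = GenePanel(
                [PanelEntry(g, a) for g, a in zip(std_panel.gene_ids, axes)]
            )
            rep = st.neuron_axis_alignment(model, shuffled)
            vals.append(rep.mean_alignment)
        assert abs(np.mean(vals) - 0.5) < 0.15
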