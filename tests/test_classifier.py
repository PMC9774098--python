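import numpy as np
import pytest

from sozloc.classifier import (
    AttentionNetClassifier,
    attention_forward,
    focal_loss,
    leave_one_patient_out,
    lopo_folds,
)
from sozloc.simulate import generate_feature_table


class TestAttentionForward:
    def test_identical_tokens_collapse_to_first(self, rng):
        e = np.tile(rng.standard_normal(4), (7, 1))
        W = rng.standard_normal((4, 4))
        b = rng.standard_normal(4)
        u = rng.standard_normal(4)
        v, h = attention_forward(e, W, b, u)
        np.testing.assert_allclose(v, e[0], atol=1e-12)

    def test_weights_are_probability_distribution(self, rng):
        e = rng.standard_normal((12, 6))
        v, h = attention_forward(
            e, rng.standard_normal((6, 6)), rng.standard_normal(6), rng.standard_normal(6)
        )
        assert h.min() >= 0
        assert h.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_computation_on_toy(self):
        # 3 tokens of dimension 1 with hand-set parameters
        e = np.array([[1.0], [2.0], [3.0]])
        W, b, u = np.array([[0.5]]), np.array([0.1]), np.array([2.0])
        ut = np.tanh(0.5 * e[:, 0] + 0.1)
        scores = 2.0 * ut
        hand_h = np.exp(scores) / np.exp(scores).sum()
        hand_v = (hand_h * e[:, 0]).sum()
        v, h = attention_forward(e, W, b, u)
        np.testing.assert_allclose(h, hand_h, rtol=1e-12)
        assert v[0] == pytest.approx(hand_v, rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            attention_forward(np.ones((3, 2)), np.ones((2, 3)), np.ones(2), np.ones(2))


class TestFocalLoss:
    def test_gamma_zero_uniform_alpha_is_cross_entropy(self, rng):
        p = rng.uniform(0.01, 0.99, size=(50, 2))
        p /= p.sum(axis=1, keepdims=True)
        y = rng.integers(0, 2, 50)
        ce = -np.mean(np.log(p[np.arange(50), y]))
        assert focal_loss(p, y, gamma=0.0, alpha=None) == pytest.approx(ce, abs=1e-9)

    def test_confident_correct_prediction_near_zero(self):
        p = np.array([[1e-7, 1 - 1e-7]])
        assert focal_loss(p, np.array([1]), gamma=2.0, alpha=None) < 1e-10

    def test_hand_computed_toy_batch(self):
        p_pos = np.array([0.9, 0.3, 0.6])
        y = np.array([1, 0, 1])
        gamma, alpha = 2.0, 0.25
        p_true = np.array([0.9, 0.7, 0.6])
        a = np.array([0.25, 0.75, 0.25])
        hand = np.mean(-a * (1 - p_true) ** gamma * np.log(p_true))
        assert focal_loss(p_pos, y, gamma, alpha) == pytest.approx(hand, rel=1e-12)

    def test_degenerate_probabilities_clipped_finite(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1, 1])
        assert np.isfinite(focal_loss(p, y, gamma=2.0, alpha=0.25))


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Finite-difference check of the hand-derived backprop."""
        rng = np.random.default_rng(0)
        n, d = 6, 5
        X = rng.standard_normal((n, d))
        y = rng.integers(0, 2, n)
        clf = AttentionNetClassifier(
            hidden=8, epochs=1, dropout=0.0, gamma=2.0, alpha=0.25, random_state=0
        )
        # build parameters without training: run fit on 1 epoch then reuse
        clf.fit(X, y)
        params = {k: v.copy() for k, v in clf.weights_.items()}
        Xs = (X - clf.mean_) / clf.scale_
        yi = np.searchsorted(clf.classes_, y)

        def loss_at(params):
            p, _ = clf._forward(Xs, params)
            return focal_loss(p, yi, clf.gamma, clf.alpha)

        _, cache = clf._forward(Xs, params)
        grads = clf._backward(cache, yi, params)
        eps = 1e-6
        for key in ("W1", "W4", "ww", "bw", "uw", "b2"):
            g = grads[key]
            flat_idx = [(0,) if g.ndim == 1 else (0, 0), (-1,) if g.ndim == 1 else (-1, -1)]
            for idx in flat_idx:
                pert = {k: v.copy() for k, v in params.items()}
                pert[key][idx] += eps
                up = loss_at(pert)
                pert[key][idx] -= 2 * eps
                down = loss_at(pert)
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(g[idx], rel=1e-3, abs=1e-7), key


@pytest.fixture(scope="module")
def separable():
    df = generate_feature_table(120, 280, 5, 45, 3.0, seed=0, n_patients=10)
    cols = [c for c in df.columns if c.startswith("f")]
    return df, cols


class TestTraining:
    def test_heldout_accuracy_on_separable_table(self, separable):
        df, cols = separable
        tr = df[~df.patient_id.isin(["P09", "P10"])]
        va = df[df.patient_id == "P09"]
        te = df[df.patient_id == "P10"]
        clf = AttentionNetClassifier(random_state=0).fit(
            tr[cols].to_numpy(), tr.label.to_numpy(),
            X_val=va[cols].to_numpy(), y_val=va.label.to_numpy(),
        )
        acc = (clf.predict(te[cols].to_numpy()) == te.label.to_numpy()).mean()
        assert acc >= 0.9

    def test_label_shuffle_gives_chance_accuracy(self, separable):
        df, cols = separable
        df = df.copy()
        df["label"] = np.random.default_rng(1).permutation(df["label"].to_numpy())
        tr = df[~df.patient_id.isin(["P09", "P10"])]
        va = df[df.patient_id == "P09"]
        te = df[df.patient_id == "P10"]
        clf = AttentionNetClassifier(random_state=0).fit(
            tr[cols].to_numpy(), tr.label.to_numpy(),
            X_val=va[cols].to_numpy(), y_val=va.label.to_numpy(),
        )
        acc = (clf.predict(te[cols].to_numpy()) == te.label.to_numpy()).mean()
        prior = max((te.label == 0).mean(), (te.label == 1).mean())
        assert abs(acc - prior) <= 0.1

    def test_inference_deterministic(self, separable):
        df, cols = separable
        clf = AttentionNetClassifier(epochs=2, random_state=0).fit(
            df[cols].to_numpy(), df.label.to_numpy()
        )
        a = clf.predict_proba(df[cols].to_numpy()[:20])
        b = clf.predict_proba(df[cols].to_numpy()[:20])
        np.testing.assert_array_equal(a, b)

    def test_probabilities_valid(self, separable):
        df, cols = separable
        clf = AttentionNetClassifier(epochs=2, random_state=0).fit(
            df[cols].to_numpy(), df.label.to_numpy()
        )
        p = clf.predict_proba(df[cols].to_numpy())
        assert (p >= 0).all() and (p <= 1).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_attention_weights_sum_to_one(self, separable):
        df, cols = separable
        clf = AttentionNetClassifier(epochs=1, random_state=0).fit(
            df[cols].to_numpy(), df.label.to_numpy()
        )
        h = clf.attention_weights(df[cols].to_numpy()[:10])
        assert h.min() >= 0
        np.testing.assert_allclose(h.sum(axis=1), 1.0, atol=1e-6)

    def test_no_features_rejected(self):
        with pytest.raises(ValueError):
            AttentionNetClassifier().fit(np.empty((10, 0)), np.repeat([0, 1], 5))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            AttentionNetClassifier().fit(np.zeros((9, 2)), np.arange(9) % 3)


class TestLeaveOnePatientOut:
    def test_fold_structure_each_patient_tested_once(self):
        patients = [f"P{i:02d}" for i in range(1, 11)]
        folds = lopo_folds(patients)
        assert len(folds) == 10
        assert sorted(f["test"] for f in folds) == sorted(patients)
        for f in folds:
            assert f["val"] != f["test"]
            assert set(f["train"]) == set(patients) - {f["test"], f["val"]}
            assert len(f["train"]) == 8

    def test_published_fold_pattern(self):
        # test on patient 1 trains/validates on patients 2-10, and so on
        patients = [f"Pt{i}" for i in range(1, 11)]
        folds = lopo_folds(sorted(patients))
        by_test = {f["test"]: f for f in folds}
        f1 = by_test["Pt1"]
        assert set(f1["train"]) | {f1["val"]} == set(patients) - {"Pt1"}

    def test_requires_three_patients(self):
        with pytest.raises(ValueError):
            lopo_folds(["P1", "P2"])

    def test_predictions_cover_every_contact_once(self):
        df = generate_feature_table(30, 60, 3, 7, 3.0, seed=4, n_patients=5)
        cols = [c for c in df.columns if c.startswith("f")]
        preds, folds = leave_one_patient_out(
            df, cols, classifier_params={"epochs": 3}, seed=0
        )
        assert len(preds) == len(df)
        assert set(preds["contact"]) == set(df["contact"])
        assert preds.groupby("patient_id")["fold"].nunique().max() == 1

    def test_deterministic_per_seed(self):
        df = generate_feature_table(20, 40, 3, 5, 3.0, seed=5, n_patients=4)
        cols = [c for c in df.columns if c.startswith("f")]
        a, _ = leave_one_patient_out(df, cols, classifier_params={"epochs": 2}, seed=1)
        b, _ = leave_one_patient_out(df, cols, classifier_params={"epochs": 2}, seed=1)
        np.testing.assert_allclose(a["probability"], b["probability"])
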