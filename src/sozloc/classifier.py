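"""SOZ/nSOZ contact classification: attention MLP + focal loss + LOPO-CV.

The network follows the published table of layers -- four fully connected
layers (features -> 128 -> 128 -> 128 -> 2) with 0.3 dropout after the
first and third -- augmented by a soft attention block and trained with
focal loss by NAdam (20 epochs, batch 4, learning rate 1e-4).

Attention here operates over the hidden-unit axis of the third FC
activation (contact rows have no time axis): each of the 128 units is a
one-dimensional token ``e_t``; with trainable scalars ``w_w, b_w, u_w``,

    u_t = tanh(w_w e_t + b_w),  h_t = softmax_t(u_t u_w),

and the block re-weights the activation vector by the attention
distribution (scaled by the unit count so uniform attention is the
identity) before the output layer.  ``attention_forward`` implements the
generic sequence form ``v = sum_t h_t e_t`` for vector tokens.

The whole network is implemented in NumPy with hand-derived gradients,
which keeps training exactly reproducible on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "attention_forward",
    "focal_loss",
    "AttentionNetClassifier",
    "leave_one_patient_out",
    "lopo_folds",
]

EPS = 1e-12


def attention_forward(
    e: np.ndarray, W_w: np.ndarray, b_w: np.ndarray, u_w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Soft attention over a sequence of hidden activations.

    ``e`` has shape (T, d).  Returns ``(v, h)`` where
    ``u_t = tanh(W_w e_t + b_w)``, ``h = softmax_t(u_t . u_w)`` and
    ``v = sum_t h_t e_t`` (shape (d,)).  ``h`` is a probability
    distribution over t for every input.
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    W_w = np.atleast_2d(np.asarray(W_w, dtype=float))
    b_w = np.atleast_1d(np.asarray(b_w, dtype=float))
    u_w = np.atleast_1d(np.asarray(u_w, dtype=float))
    if W_w.shape[1] != e.shape[1] or W_w.shape[0] != b_w.size or b_w.size != u_w.size:
        raise ValueError("attention parameter shapes do not match the input")
    u = np.tanh(e @ W_w.T + b_w)  # (T, k)
    scores = u @ u_w  # (T,)
    scores = scores - scores.max()
    h = np.exp(scores)
    h /= h.sum()
    v = h @ e
    return v, h


def focal_loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    gamma: float = 2.0,
    alpha: float | tuple[float, float] | None = 0.25,
) -> float:
    """Mean focal loss ``-alpha_y (1 - p_y)^gamma log(p_y)``.

    ``probabilities`` is (n, 2) class probabilities or (n,) probabilities
    of the positive class.  ``alpha`` may be ``None`` (uniform weight 1),
    a scalar (weight of the positive class, ``1 - alpha`` for the
    negative -- the canonical imbalance weighting), or an explicit pair
    ``(alpha_neg, alpha_pos)``.  With ``gamma=0`` and uniform alpha the
    loss reduces to cross-entropy.  Probabilities at 0/1 are clipped.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.ndim == 1:
        p_true = np.where(y == 1, p, 1.0 - p)
    else:
        p_true = p[np.arange(y.size), y]
    p_true = np.clip(p_true, EPS, 1.0 - EPS)
    if alpha is None:
        a = np.ones_like(p_true)
    elif np.isscalar(alpha):
        a = np.where(y == 1, float(alpha), 1.0 - float(alpha))
    else:
        a = np.where(y == 1, alpha[1], alpha[0])
    return float(np.mean(-a * (1.0 - p_true) ** gamma * np.log(p_true)))


class _NAdam:
    """NAdam (Adam with Nesterov momentum) over a dict of ndarrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** (t + 1))
            g_hat = g / (1 - b1**t)
            v_hat = self.v[k] / (1 - b2**t)
            params[k] -= self.lr * (b1 * m_hat + (1 - b1) * g_hat) / (
                np.sqrt(v_hat) + self.eps
            )


class AttentionNetClassifier(ClassifierMixin, BaseEstimator):
    """Attention MLP with focal loss for imbalanced binary classification.

    Parameters mirror the published trainer configuration; inputs are
    z-scored internally.  When a validation set is passed to :meth:`fit`
    the epoch with the lowest validation focal loss is kept.

    Attributes (after fit): ``classes_``, ``weights_`` (parameter dict),
    ``loss_curve_``, ``validation_loss_curve_``, ``best_epoch_``.
    """

    def __init__(
        self,
        hidden: int = 128,
        epochs: int = 20,
        batch_size: int = 4,
        learning_rate: float = 1e-4,
        dropout: float = 0.3,
        gamma: float = 2.0,
        alpha: float | None = 0.25,
        use_attention: bool = True,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.gamma = gamma
        self.alpha = alpha
        self.use_attention = use_attention
        self.random_state = random_state

    # ---------------------------------------------------------------- forward
    def _forward(self, X, params, rng=None):
        """Returns (probabilities, cache).  ``rng`` enables dropout."""
        H = self.hidden
        a1 = np.maximum(X @ params["W1"] + params["b1"], 0.0)
        d1 = self._dropout_mask(a1.shape, rng)
        a1d = a1 * d1
        a2 = np.maximum(a1d @ params["W2"] + params["b2"], 0.0)
        e = np.maximum(a2 @ params["W3"] + params["b3"], 0.0)
        if self.use_attention:
            u = np.tanh(params["ww"] * e + params["bw"])  # (B, H)
            s = u * params["uw"]
            s = s - s.max(axis=1, keepdims=True)
            h = np.exp(s)
            h /= h.sum(axis=1, keepdims=True)
            g = H * h * e
        else:
            u = h = None
            g = e
        d3 = self._dropout_mask(g.shape, rng)
        gd = g * d3
        z4 = gd @ params["W4"] + params["b4"]
        z4 = z4 - z4.max(axis=1, keepdims=True)
        p = np.exp(z4)
        p /= p.sum(axis=1, keepdims=True)
        cache = dict(X=X, a1=a1, d1=d1, a1d=a1d, a2=a2, e=e, u=u, h=h, g=g, d3=d3, gd=gd, p=p)
        return p, cache

    def _dropout_mask(self, shape, rng):
        if rng is None or self.dropout <= 0:
            return np.ones(shape)
        keep = 1.0 - self.dropout
        return (rng.random(shape) < keep) / keep

    def _backward(self, cache, y, params):
        B = y.size
        H = self.hidden
        p = cache["p"]
        p_true = np.clip(p[np.arange(B), y], EPS, 1 - EPS)
        if self.alpha is None:
            a = np.ones(B)
        elif np.isscalar(self.alpha):
            a = np.where(y == 1, float(self.alpha), 1.0 - float(self.alpha))
        else:
            a = np.where(y == 1, self.alpha[1], self.alpha[0])
        onehot = np.zeros_like(p)
        onehot[np.arange(B), y] = 1.0
        # d focal / d logits
        coeff = (1 - p_true) ** self.gamma - self.gamma * (1 - p_true) ** max(
            self.gamma - 1, 0.0
        ) * p_true * np.log(p_true)
        if self.gamma == 0:
            coeff = np.ones(B)
        dz4 = (-a * coeff)[:, None] * (onehot - p) / B

        grads = {}
        grads["W4"] = cache["gd"].T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        dgd = dz4 @ params["W4"].T
        dg = dgd * cache["d3"]
        if self.use_attention:
            e, u, h = cache["e"], cache["u"], cache["h"]
            de = H * h * dg
            dh = H * e * dg
            ds = h * (dh - (h * dh).sum(axis=1, keepdims=True))
            grads["uw"] = np.array([(ds * u).sum()])
            du = ds * params["uw"]
            dzu = du * (1 - u**2)
            grads["ww"] = np.array([(dzu * e).sum()])
            grads["bw"] = np.array([dzu.sum()])
            de = de + dzu * params["ww"]
        else:
            de = dg
        de = de * (cache["e"] > 0)
        grads["W3"] = cache["a2"].T @ de
        grads["b3"] = de.sum(axis=0)
        da2 = (de @ params["W3"].T) * (cache["a2"] > 0)
        grads["W2"] = cache["a1d"].T @ da2
        grads["b2"] = da2.sum(axis=0)
        da1 = (da2 @ params["W2"].T) * cache["d1"] * (cache["a1"] > 0)
        grads["W1"] = cache["X"].T @ da1
        grads["b1"] = da1.sum(axis=0)
        return grads

    # ------------------------------------------------------------------- fit
    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-D with at least one feature")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary labels required")
        yi = np.searchsorted(self.classes_, y)

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        H, d = self.hidden, X.shape[1]

        def he(fan_in, shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        params = {
            "W1": he(d, (d, H)),
            "b1": np.zeros(H),
            "W2": he(H, (H, H)),
            "b2": np.zeros(H),
            "W3": he(H, (H, H)),
            "b3": np.zeros(H),
            "W4": he(H, (H, 2)),
            "b4": np.zeros(2),
            "ww": np.ones(1),
            "bw": np.zeros(1),
            "uw": np.zeros(1),
        }
        opt = _NAdam(params, self.learning_rate)
        n = Xs.shape[0]
        self.loss_curve_, self.validation_loss_curve_ = [], []
        best = (np.inf, None, -1)
        if X_val is not None:
            Xv = (np.asarray(X_val, dtype=float) - self.mean_) / self.scale_
            yv = np.searchsorted(self.classes_, np.asarray(y_val))

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                p, cache = self._forward(Xs[idx], params, rng)
                epoch_loss += focal_loss(p, yi[idx], self.gamma, self.alpha) * idx.size
                grads = self._backward(cache, yi[idx], params)
                opt.step(params, grads)
            self.loss_curve_.append(epoch_loss / n)
            if X_val is not None:
                pv, _ = self._forward(Xv, params)
                vloss = focal_loss(pv, yv, self.gamma, self.alpha)
                self.validation_loss_curve_.append(vloss)
                if vloss < best[0]:
                    best = (vloss, {k: v.copy() for k, v in params.items()}, epoch)
        if X_val is not None and best[1] is not None:
            params = best[1]
            self.best_epoch_ = best[2]
        else:
            self.best_epoch_ = self.epochs - 1
        self.weights_ = params
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        p, _ = self._forward(Xs, self.weights_)
        return p

    def predict(self, X, threshold: float = 0.5):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= threshold).astype(int)]

    def attention_weights(self, X) -> np.ndarray:
        """Per-sample attention distribution over the hidden units."""
        check_is_fitted(self, "weights_")
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        _, cache = self._forward(Xs, self.weights_)
        return cache["h"]


# ---------------------------------------------------------------------------
# leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

def lopo_folds(patients: list[str]) -> list[dict]:
    """Fold plan: each patient is tested once; the next patient in
    rotation validates; the rest train."""
    if len(patients) < 3:
        raise ValueError("leave-one-patient-out needs >= 3 patients")
    folds = []
    for i, test in enumerate(patients):
        val = patients[(i + 1) % len(patients)]
        train = [p for p in patients if p not in (test, val)]
        folds.append({"test": test, "val": val, "train": train})
    return folds


def leave_one_patient_out(
    feature_table: pd.DataFrame,
    feature_columns: list[str],
    classifier_params: dict | None = None,
    selector_factory=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Cross-validate SOZ prediction with one patient held out per fold.

    ``feature_table`` needs ``contact``, ``patient_id``, ``label`` columns
    plus ``feature_columns``.  If ``selector_factory`` is given (a
    callable returning an unfitted selector with fit/get_support), feature
    selection is re-run inside each fold on the training patients only.
    Returns (predictions, folds): predictions has one row per contact with
    the SOZ probability from the fold in which its patient was the test
    patient.  Patients with zero contacts are excluded with a warning.
    """
    import warnings

    classifier_params = dict(classifier_params or {})
    counts = feature_table["patient_id"].value_counts()
    empty = [p for p in counts.index if counts[p] == 0]
    if empty:
        warnings.warn(f"patients with zero contacts excluded: {empty}")
    patients = sorted(p for p in feature_table["patient_id"].unique() if counts[p] > 0)
    folds = lopo_folds(patients)

    pred_rows = []
    for k, fold in enumerate(folds):
        tr = feature_table[feature_table["patient_id"].isin(fold["train"])]
        va = feature_table[feature_table["patient_id"] == fold["val"]]
        te = feature_table[feature_table["patient_id"] == fold["test"]]
        assert not set(te.index) & (set(tr.index) | set(va.index))

        cols = list(feature_columns)
        if selector_factory is not None:
            sel = selector_factory()
            sel.fit(tr[cols], tr["label"].to_numpy())
            mask = sel.get_support()
            if mask.any():
                cols = [c for c, m in zip(cols, mask) if m]
        clf = AttentionNetClassifier(
            random_state=seed + k, **classifier_params
        ).fit(
            tr[cols].to_numpy(),
            tr["label"].to_numpy(),
            X_val=va[cols].to_numpy(),
            y_val=va["label"].to_numpy(),
        )
        proba = clf.predict_proba(te[cols].to_numpy())[:, 1]
        for (_, row), pr in zip(te.iterrows(), proba):
            pred_rows.append(
                {
                    "contact": row["contact"],
                    "patient_id": row["patient_id"],
                    "probability": float(pr),
                    "label": int(row["label"]),
                    "fold": k,
                }
            )
        fold["n_selected"] = len(cols)
    return pd.DataFrame(pred_rows), folds
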