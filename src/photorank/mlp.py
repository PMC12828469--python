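"""Dual-input multilayer perceptron photocatalyst recommender.

The model maps a pair of 64-bit reaction fingerprints — a Morgan
fingerprint of the substrates and a DRFP of the reaction core — to a
probability vector over the photocatalyst registry.  Each input block is
processed through its own hidden layer; the two hidden representations
are concatenated, passed through two further hidden layers, and projected
to one logit per catalyst.  Softmax over the logits yields the ranking.

Training uses weighted cross-entropy to counter the heavy class imbalance
of photocatalysis data (the literature corpus the method targets spans
>7000 records for popular catalysts down to ~20 for rare ones): class c
receives weight N / (C_nonzero * n_c), the standard balanced inverse
frequency heuristic, whose weighted mean over observed samples is 1.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad

_ACTIVATIONS: dict[str, Callable[[ad.Tensor], ad.Tensor]] = {
    "relu": ad.relu,
    "gelu": ad.gelu,
    "tanh": ad.tanh,
}


def class_weights(label_counts: Sequence[int]) -> np.ndarray:
    """Balanced inverse-frequency class weights.

    weight_c = N / (C_nonzero * n_c) for observed classes, 0 for absent
    ones; the sample-weighted mean of the returned weights equals 1.
    """
    counts = np.asarray(label_counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("negative class count")
    total = counts.sum()
    if total == 0:
        raise ValueError("all class counts are zero")
    nonzero = int((counts > 0).sum())
    weights = np.zeros_like(counts)
    mask = counts > 0
    weights[mask] = total / (nonzero * counts[mask])
    return weights


class MLPRecommender(BaseEstimator, ClassifierMixin):
    """Two-branch MLP over (Morgan | DRFP) fingerprint blocks.

    Parameters
    ----------
    n_bits_morgan : width of the leading Morgan block in X (the DRFP block
        is everything after it).
    hidden_morgan, hidden_drfp : per-branch hidden layer widths.
    hidden_post : widths of the two hidden layers after concatenation.
    activation : 'relu', 'gelu' or 'tanh'.
    weighted : train with balanced class weights (recommended for the
        imbalanced corpora this model is meant for).
    registry_size : output dimensionality; defaults to max(y)+1 at fit
        time.  Set it to the registry size (31) so rare catalysts missing
        from a training fold still own an output slot.
    epochs, batch_size, learning_rate, random_state : training scalars.

    Attributes
    ----------
    classes_ : ndarray of class indices the output refers to.
    training_report_ : per-epoch mean training loss.
    """

    def __init__(
        self,
        n_bits_morgan: int = 64,
        hidden_morgan: int = 128,
        hidden_drfp: int = 128,
        hidden_post: tuple[int, int] = (128, 64),
        activation: str = "relu",
        weighted: bool = True,
        registry_size: int | None = None,
        epochs: int = 50,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.n_bits_morgan = n_bits_morgan
        self.hidden_morgan = hidden_morgan
        self.hidden_drfp = hidden_drfp
        self.hidden_post = hidden_post
        self.activation = activation
        self.weighted = weighted
        self.registry_size = registry_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, xm: np.ndarray, xd: np.ndarray) -> ad.Tensor:
        act = _ACTIVATIONS[self.activation]
        p = self.params_
        hm = act(ad.linear(ad.Tensor(xm), p["w_m"], p["b_m"]))
        hd = act(ad.linear(ad.Tensor(xd), p["w_d"], p["b_d"]))
        h = ad.concatenate([hm, hd], axis=-1)
        h = act(ad.linear(h, p["w_1"], p["b_1"]))
        h = act(ad.linear(h, p["w_2"], p["b_2"]))
        return ad.linear(h, p["w_out"], p["b_out"])

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.float64)
        return X[:, : self.n_bits_morgan], X[:, self.n_bits_morgan :]

    def _init_params(self, n_morgan: int, n_drfp: int, n_out: int, rng) -> None:
        h1, h2 = self.hidden_post
        p: dict[str, ad.Tensor] = {}
        p["w_m"] = ad.parameter(rng, (n_morgan, self.hidden_morgan))
        p["b_m"] = ad.zeros_parameter((self.hidden_morgan,))
        p["w_d"] = ad.parameter(rng, (n_drfp, self.hidden_drfp))
        p["b_d"] = ad.zeros_parameter((self.hidden_drfp,))
        merged = self.hidden_morgan + self.hidden_drfp
        p["w_1"] = ad.parameter(rng, (merged, h1))
        p["b_1"] = ad.zeros_parameter((h1,))
        p["w_2"] = ad.parameter(rng, (h1, h2))
        p["b_2"] = ad.zeros_parameter((h2,))
        p["w_out"] = ad.parameter(rng, (h2, n_out))
        p["b_out"] = ad.zeros_parameter((n_out,))
        self.params_ = p

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y) -> "MLPRecommender":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to train")
        n_out = self.registry_size or int(y.max()) + 1
        if y.max() >= n_out:
            raise ValueError("label outside registry_size")
        xm, xd = self._split(X)
        rng = np.random.default_rng(self.random_state)
        self._init_params(xm.shape[1], xd.shape[1], n_out, rng)
        self.classes_ = np.arange(n_out)
        self.n_features_in_ = X.shape[1]

        counts = np.bincount(y, minlength=n_out)
        if self.weighted:
            cw = class_weights(counts)
        else:
            cw = np.ones(n_out)
        sample_w = cw[y]

        opt = ad.Adam(list(self.params_.values()), lr=self.learning_rate)
        report: list[float] = []
        n = len(y)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(xm[idx], xd[idx])
                loss = ad.cross_entropy(logits, y[idx], sample_weights=sample_w[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss {loss.data!r}; "
                        "lower the learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data) * len(idx))
            report.append(float(np.sum(losses) / n))
        self.training_report_ = report
        return self

    def decision_function(self, X) -> np.ndarray:
        xm, xd = self._split(np.asarray(X, dtype=np.float64))
        return self._forward(xm, xd).data

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config + learned weights (.npz)."""
        arrays = {k: v.data for k, v in self.params_.items()}
        arrays["__classes__"] = self.classes_
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.get_params()).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MLPRecommender":
        with np.load(path) as archive:
            config = json.loads(bytes(archive["__config__"]).decode())
            config["hidden_post"] = tuple(config["hidden_post"])
            model = cls(**config)
            model.params_ = {
                k: ad.Tensor(archive[k], requires_grad=True)
                for k in archive.files
                if not k.startswith("__")
            }
            model.classes_ = archive["__classes__"]
        model.n_features_in_ = (
            model.params_["w_m"].shape[0] + model.params_["w_d"].shape[0]
        )
        return model


def train_mlp(
    morgan: np.ndarray, diff: np.ndarray, labels: Sequence[int], **params
) -> MLPRecommender:
    """Functional wrapper: fit an :class:`MLPRecommender` on the two
    fingerprint blocks."""
    X = np.hstack([morgan, diff])
    model = MLPRecommender(n_bits_morgan=morgan.shape[1], **params)
    return model.fit(X, np.asarray(labels))


def predict_proba(model: MLPRecommender, morgan: np.ndarray, diff: np.ndarray) -> np.ndarray:
    return model.predict_proba(np.hstack([morgan, diff]))
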