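"""Recurrent sequence classifiers and the weighted two-stage pipeline.

A classifier maps a padded multi-hot visit sequence to a scalar risk
probability: the hidden state after the last real visit (padding carries
the state unchanged) feeds a sigmoid output head.  Training minimizes the
weighted binary cross-entropy

    sum_i w_i * BCE(f(X_i), y_i)

over pre-shift training patients by mini-batch Adam, with early stopping
on pre-shift validation AUROC.  The sample weights are fixed during
classifier training (two-stage protocol: weights first, then frozen) and
play no role at inference.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, GRULayer, LSTMLayer, sigmoid, uniform_init
from .data import Cohort, PaddedBatch, batch_from_cohort
from .reweighting import ReweightConfig, SampleReweighter

__all__ = [
    "TrainConfig",
    "SequenceClassifier",
    "train_weighted_classifier",
    "predict",
    "run_two_stage",
    "TwoStageResult",
]


@dataclass
class TrainConfig:
    """Classifier training settings.

    The canonical search grids are lr in {1e-3, 1e-4}, hidden in
    {128, 256, 512}, layers in {2, 3}; mini-batches of 32 patients and an
    early-stopping patience of 10 validation epochs.
    """

    backbone: str = "gru"
    learning_rate: float = 1e-3
    hidden: int = 128
    n_layers: int = 2
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0


class SequenceClassifier(ClassifierMixin, BaseEstimator):
    """GRU/LSTM risk classifier over padded multi-hot visit sequences.

    fit consumes a :class:`PaddedBatch` (plus optional per-patient
    ``sample_weight`` and a validation batch for early stopping); inference
    is unweighted.  Deterministic given ``seed``.
    """

    def __init__(self, backbone: str = "gru", hidden: int = 128, n_layers: int = 2,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 100, patience: int = 10, seed: int = 0):
        self.backbone = backbone
        self.hidden = hidden
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    # -- construction -------------------------------------------------

    def _build(self, C: int, rng: np.random.Generator) -> None:
        layer_cls = {"gru": GRULayer, "lstm": LSTMLayer}.get(self.backbone)
        if layer_cls is None:
            raise ValueError(f"unknown backbone {self.backbone!r}; use 'gru' or 'lstm'")
        self.layers_ = []
        dim = C
        for _ in range(self.n_layers):
            self.layers_.append(layer_cls(dim, self.hidden, rng))
            dim = self.hidden
        self.head_ = {
            "v": uniform_init(rng, (self.hidden, 1), self.hidden),
            "c": uniform_init(rng, (1,), self.hidden),
        }

    def _all_params(self) -> dict[str, np.ndarray]:
        params = {}
        for li, layer in enumerate(self.layers_):
            for k, v in layer.params.items():
                params[f"l{li}_{k}"] = v
        params["head_v"] = self.head_["v"]
        params["head_c"] = self.head_["c"]
        return params

    # -- forward / backward -------------------------------------------

    def _forward(self, X: np.ndarray, mask: np.ndarray, keep_cache: bool = False):
        h = X
        caches = []
        for layer in self.layers_:
            h, cache = layer.forward(h, mask)
            caches.append(cache)
        h_last = h[:, -1, :]  # masked carry => state after the last real visit
        logits = (h_last @ self.head_["v"]).ravel() + self.head_["c"][0]
        p = sigmoid(logits)
        if keep_cache:
            return p, h_last, caches
        return p

    def _backward(self, X, mask, p, y, w, h_last, caches) -> dict[str, np.ndarray]:
        B = X.shape[0]
        # weighted BCE, reduced by batch size (not by the weight sum)
        dlogit = (w * (p - y) / B)[:, None]
        grads = {
            "head_v": h_last.T @ dlogit,
            "head_c": np.array([dlogit.sum()]),
        }
        dh_seq = np.zeros((B, X.shape[1], self.hidden))
        dh_seq[:, -1, :] = dlogit * self.head_["v"].ravel()
        for li in range(len(self.layers_) - 1, -1, -1):
            dh_seq, layer_grads = self.layers_[li].backward(dh_seq, caches[li])
            for k, g in layer_grads.items():
                grads[f"l{li}_{k}"] = g
        return grads

    @staticmethod
    def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
        eps = 1e-12
        per = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        return float((w * per).sum())

    # -- training ------------------------------------------------------

    def fit(
        self,
        batch: PaddedBatch,
        y: np.ndarray | None = None,
        sample_weight: np.ndarray | None = None,
        valid_batch: PaddedBatch | None = None,
    ) -> "SequenceClassifier":
        from .evaluation import auroc

        X, mask = batch.X, batch.visit_mask
        labels = batch.labels if y is None else np.asarray(y)
        n = X.shape[0]
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (n,):
                raise ValueError("sample_weight length mismatch")
            if (w < 0).any():
                raise ValueError("sample weights must be non-negative")
            if not (w > 0).any():
                raise ValueError("all sample weights are zero: nothing to learn from")

        rng = np.random.default_rng(self.seed)
        self._build(batch.C, rng)
        params = self._all_params()
        opt = Adam(params, lr=self.learning_rate)

        best_metric = -np.inf
        best_params = None
        stall = 0
        history = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Xb, mb, yb, wb = X[idx], mask[idx], labels[idx], w[idx]
                p, h_last, caches = self._forward(Xb, mb, keep_cache=True)
                total += self._weighted_bce(p, yb, wb)
                grads = self._backward(Xb, mb, p, yb, wb, h_last, caches)
                opt.step(grads)
            row: dict[str, Any] = {"epoch": epoch, "train_loss": total / n}
            if valid_batch is not None:
                scores = self._forward(valid_batch.X, valid_batch.visit_mask)
                metric = auroc(scores, valid_batch.labels)
                row["valid_auroc"] = metric
                if metric > best_metric:
                    best_metric = metric
                    best_params = copy.deepcopy(params)
                    stall = 0
                else:
                    stall += 1
                history.append(row)
                if stall >= self.patience:
                    break
            else:
                history.append(row)
        if best_params is not None:
            for k, v in best_params.items():
                params[k][...] = v
        self.history_ = pd.DataFrame(history)
        self.best_valid_auroc_ = best_metric if valid_batch is not None else None
        self.classes_ = np.array([0, 1])
        return self

    # -- inference -----------------------------------------------------

    def predict_risk(self, batch: PaddedBatch) -> np.ndarray:
        """Per-patient probability of the positive outcome."""
        if not hasattr(self, "layers_"):
            raise RuntimeError("classifier is not fitted")
        if batch.C != self.layers_[0].D:
            raise ValueError(
                f"batch has {batch.C} codes, model expects {self.layers_[0].D}"
            )
        return self._forward(batch.X, batch.visit_mask)

    def predict_proba(self, batch: PaddedBatch) -> np.ndarray:
        p = self.predict_risk(batch)
        return np.column_stack([1 - p, p])

    def predict(self, batch: PaddedBatch) -> np.ndarray:
        return (self.predict_risk(batch) >= 0.5).astype(int)


def train_weighted_classifier(
    pre_batch: PaddedBatch,
    weights: np.ndarray | None,
    valid_batch: PaddedBatch | None,
    config: TrainConfig,
) -> SequenceClassifier:
    """Stage-2 training: frozen weights multiply the per-sample BCE."""
    clf = SequenceClassifier(
        backbone=config.backbone, hidden=config.hidden, n_layers=config.n_layers,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        max_epochs=config.max_epochs, patience=config.patience, seed=config.seed,
    )
    return clf.fit(pre_batch, sample_weight=weights, valid_batch=valid_batch)


def predict(model: SequenceClassifier, batch: PaddedBatch) -> np.ndarray:
    """Unweighted inference: one risk probability per patient."""
    return model.predict_risk(batch)


@dataclass
class TwoStageResult:
    weights: np.ndarray
    weight_trace: pd.DataFrame
    classifiers: dict[str, SequenceClassifier]
    metrics: dict[str, dict[str, dict[str, float]]]
    patient_ids: list[str] = field(default_factory=list)

    @property
    def report(self) -> dict:
        return {
            "metrics": self.metrics,
            "weight_sum": float(self.weights.sum()),
            "n_pre_train": int(self.weights.shape[0]),
        }


def run_two_stage(
    cohort: Cohort,
    reweight_config: ReweightConfig | None = None,
    train_config: TrainConfig | None = None,
    variants: tuple[str, ...] = ("basic", "weighted"),
) -> TwoStageResult:
    """Full pipeline: learn weights, then train basic and weighted models.

    Stage 1 trains the auto-encoder and the sample weights on pre-shift
    training + post-shift training data; stage 2 trains the classifier on
    weighted pre-shift training data (weights frozen), early-stopped on
    pre-shift validation.  Both a ``basic`` (w = 1) and a ``weighted``
    variant are trained and evaluated on the pre-shift test and post-shift
    test splits.
    """
    from .evaluation import compute_metrics

    reweight_config = reweight_config or ReweightConfig()
    train_config = train_config or TrainConfig()

    subsets = {
        "pre_train": cohort.subset("pre", "train"),
        "pre_valid": cohort.subset("pre", "valid"),
        "pre_test": cohort.subset("pre", "test"),
        "post_train": cohort.subset("post", "train"),
        "post_test": cohort.subset("post", "test"),
    }
    for name in ("pre_train", "pre_valid", "post_train", "post_test"):
        if len(subsets[name]) == 0:
            raise ValueError(f"cohort is missing the {name.replace('_', '/')} split")
    batches = {k: batch_from_cohort(v) for k, v in subsets.items() if len(v)}

    # Stage 1: sample reweighting
    rw = SampleReweighter(
        alpha=reweight_config.alpha, beta=reweight_config.beta,
        learning_rate=reweight_config.learning_rate,
        n_epochs=reweight_config.n_epochs, ae_hidden=reweight_config.ae_hidden,
        ae_learning_rate=reweight_config.ae_learning_rate,
        ae_epochs=reweight_config.ae_epochs, seed=reweight_config.seed,
    )
    rw.fit(batches["pre_train"], batches["post_train"])

    # Stage 2: frozen weights multiply the classification losses
    classifiers: dict[str, SequenceClassifier] = {}
    metrics: dict[str, dict[str, dict[str, float]]] = {}
    for variant in variants:
        weights = rw.weights_ if variant == "weighted" else None
        clf = train_weighted_classifier(
            batches["pre_train"], weights, batches["pre_valid"], train_config
        )
        classifiers[variant] = clf
        metrics[variant] = {}
        for split in ("pre_test", "post_test"):
            if split in batches:
                scores = clf.predict_risk(batches[split])
                metrics[variant][split] = compute_metrics(
                    scores, batches[split].labels, variant=variant
                ).to_dict()
    return TwoStageResult(
        weights=rw.weights_,
        weight_trace=rw.loss_trace_,
        classifiers=classifiers,
        metrics=metrics,
        patient_ids=batches["pre_train"].patient_ids,
    )
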