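"""Minimal trainable message-passing predictor and baseline explainers.

The predictor is a light L-layer graph convolution network written directly
on numpy/scipy sparse matrices:

* ``gin_like`` layers aggregate ``(1 + eps) * h_u + sum_{v in N(u)} h_v`` with
  ``eps = 0`` (i.e. ``(A + I) H``) followed by an affine map and ReLU — a
  one-layer-MLP instance of the sum-aggregation scheme whose injectivity
  motivates GIN-style networks.
* ``gcn_like`` layers use the symmetric-normalized aggregation
  ``D^{-1/2} (A + I) D^{-1/2} H``.

A linear softmax head maps the last-layer embedding ``z_u`` to class
probabilities.  Training is full-batch Adam on the cross-entropy of the train
split; the forward and backward passes are exact, so the vanilla-gradient
(saliency) explainer differentiates the predicted-class logit analytically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .generator import ShapeGGenDataset, _stratified_split
from .model import ExplanationMask, SubgraphData, SyntheticGraph

__all__ = [
    "PredictorConfig",
    "Predictor",
    "train",
    "random_explainer",
    "gradient_explainer",
    "split_dataset",
]


@dataclass
class PredictorConfig:
    """Architecture and optimization settings.

    The defaults are the benchmark protocol for the GIN-style model (Adam,
    learning rate 1e-2, weight decay 1e-5, 1000 epochs); for the GCN-style
    model the protocol uses learning rate 3e-2, no weight decay and 1500
    epochs (see :meth:`gcn_protocol`).
    """

    layers: int = 3
    hidden_dim: int = 16
    arch: str = "gin_like"
    learning_rate: float = 1e-2
    weight_decay: float = 1e-5
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("need at least one layer")
        if self.epochs < 1:
            raise ValueError("need at least one training epoch")
        if self.arch not in ("gin_like", "gcn_like"):
            raise ValueError("arch must be 'gin_like' or 'gcn_like'")

    @classmethod
    def gcn_protocol(cls, **kw) -> "PredictorConfig":
        base = dict(arch="gcn_like", learning_rate=3e-2, weight_decay=0.0,
                    epochs=1500)
        base.update(kw)
        return cls(**base)


def _aggregator(edges: np.ndarray, n: int, arch: str) -> sp.csr_matrix:
    """(A + I), optionally symmetric-normalized; edges are unique canonical pairs."""
    if len(edges) > 0:
        rows = np.concatenate([edges[:, 0], edges[:, 1], np.arange(n)])
        cols = np.concatenate([edges[:, 1], edges[:, 0], np.arange(n)])
    else:
        rows = cols = np.arange(n)
    vals = np.ones(len(rows))
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    if arch == "gcn_like":
        d = np.asarray(A.sum(axis=1)).ravel()
        dinv = 1.0 / np.sqrt(np.maximum(d, 1e-12))
        A = sp.diags(dinv) @ A @ sp.diags(dinv)
    return A.tocsr()


class Predictor:
    """Trained L-layer message-passing classifier.

    ``predict_proba``/``predict_logits``/``predict_embedding`` evaluate the
    model on a :class:`SubgraphData` and return the center node's softmax
    vector, pre-softmax class scores, and last-layer embedding respectively.
    """

    def __init__(self, config: PredictorConfig, in_dim: int, num_classes: int,
                 params: Optional[dict] = None):
        self.config = config
        self.in_dim = int(in_dim)
        self.num_classes = int(num_classes)
        self.val_accuracy: Optional[float] = None
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng(config.seed)
            dims = [in_dim] + [config.hidden_dim] * config.layers
            self.params = {}
            for l in range(config.layers):
                fan_in, fan_out = dims[l], dims[l + 1]
                s = np.sqrt(6.0 / (fan_in + fan_out))
                self.params[f"W{l}"] = rng.uniform(-s, s, size=(fan_in, fan_out))
                self.params[f"b{l}"] = np.zeros(fan_out)
            s = np.sqrt(6.0 / (config.hidden_dim + num_classes))
            self.params["Wc"] = rng.uniform(-s, s, size=(config.hidden_dim, num_classes))
            self.params["bc"] = np.zeros(num_classes)

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, A: sp.csr_matrix):
        L = self.config.layers
        H = X
        cache = {"H-1": X}
        for l in range(L):
            M = A @ H
            Z = M @ self.params[f"W{l}"] + self.params[f"b{l}"]
            H = np.maximum(Z, 0.0)
            cache[f"M{l}"], cache[f"Z{l}"], cache[f"H{l}"] = M, Z, H
        logits = H @ self.params["Wc"] + self.params["bc"]
        cache["logits"] = logits
        return logits, H, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def _backward_to_input(self, cache, A: sp.csr_matrix,
                           d_logits: np.ndarray) -> np.ndarray:
        """Gradient of a scalar (with given d_logits) w.r.t. the input features."""
        dH = d_logits @ self.params["Wc"].T
        for l in reversed(range(self.config.layers)):
            dZ = dH * (cache[f"Z{l}"] > 0)
            dM = dZ @ self.params[f"W{l}"].T
            dH = A.T @ dM
        return dH

    # -- subgraph-level API ------------------------------------------------

    def _eval(self, data: SubgraphData):
        A = _aggregator(data.edges, data.num_nodes, self.config.arch)
        logits, H, cache = self._forward(data.features, A)
        return logits, H, cache, A

    def predict_proba(self, data: SubgraphData) -> np.ndarray:
        logits, _, _, _ = self._eval(data)
        return self._softmax(logits[data.center_local])

    def predict_logits(self, data: SubgraphData) -> np.ndarray:
        logits, _, _, _ = self._eval(data)
        return logits[data.center_local]

    def predict_embedding(self, data: SubgraphData) -> np.ndarray:
        _, H, _, _ = self._eval(data)
        return H[data.center_local]

    def predict_class(self, data: SubgraphData) -> int:
        return int(np.argmax(self.predict_proba(data)))

    def input_saliency(self, data: SubgraphData) -> np.ndarray:
        """|d logit_c / d X| for the center's predicted class c; (n, d) matrix."""
        logits, _, cache, A = self._eval(data)
        c = int(np.argmax(logits[data.center_local]))
        d_logits = np.zeros_like(logits)
        d_logits[data.center_local, c] = 1.0
        return np.abs(self._backward_to_input(cache, A, d_logits))

    # -- whole-graph convenience -------------------------------------------

    def forward_graph(self, graph: SyntheticGraph):
        edges = np.array(graph.undirected_edges, dtype=int).reshape(-1, 2)
        A = _aggregator(edges, graph.num_nodes, self.config.arch)
        logits, H, _ = self._forward(graph.features, A)
        return logits, self._softmax(logits), H

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        blob = {
            "header": {
                "arch": self.config.arch,
                "layers": self.config.layers,
                "hidden_dim": self.config.hidden_dim,
                "in_dim": self.in_dim,
                "num_classes": self.num_classes,
                "seed": self.config.seed,
                "config": asdict(self.config),
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "Predictor":
        with open(path) as fh:
            blob = json.load(fh)
        head = blob["header"]
        cfg = PredictorConfig(**head["config"])
        params = {k: np.array(v, dtype=float) for k, v in blob["params"].items()}
        return cls(cfg, head["in_dim"], head["num_classes"], params=params)


def train(dataset: ShapeGGenDataset, config: Optional[PredictorConfig] = None) -> Predictor:
    """Train on the dataset's train split; seeded and reproducible.

    Full-batch Adam on cross-entropy; no early stopping (fixed epoch budget).
    Validation accuracy after the final epoch is stored on
    ``predictor.val_accuracy``.
    """
    config = config or PredictorConfig()
    graph = dataset.graph
    if graph.features is None or graph.labels is None:
        raise ValueError("dataset must carry features and labels")
    model = Predictor(config, graph.features.shape[1], int(graph.labels.max()) + 1)
    edges = np.array(graph.undirected_edges, dtype=int).reshape(-1, 2)
    A = _aggregator(edges, graph.num_nodes, config.arch)
    X, y = graph.features, graph.labels
    train_idx = dataset.train_nodes
    if len(train_idx) == 0:
        raise ValueError("empty train split")
    # Adam state
    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    n_tr = len(train_idx)
    for t in range(1, config.epochs + 1):
        logits, H, cache = model._forward(X, A)
        probs = model._softmax(logits)
        if not np.isfinite(logits).all():
            raise FloatingPointError(
                f"non-finite loss at epoch {t}; lower the learning rate"
            )
        d_logits = np.zeros_like(logits)
        d_logits[train_idx] = probs[train_idx]
        d_logits[train_idx, y[train_idx]] -= 1.0
        d_logits /= n_tr
        # backward
        grads = {}
        grads["Wc"] = cache[f"H{config.layers-1}"].T @ d_logits
        grads["bc"] = d_logits.sum(axis=0)
        dH = d_logits @ model.params["Wc"].T
        for l in reversed(range(config.layers)):
            dZ = dH * (cache[f"Z{l}"] > 0)
            grads[f"W{l}"] = cache[f"M{l}"].T @ dZ
            grads[f"b{l}"] = dZ.sum(axis=0)
            if l > 0:
                dH = A.T @ (dZ @ model.params[f"W{l}"].T)
        for k, g in grads.items():
            if config.weight_decay and k.startswith("W"):
                g = g + config.weight_decay * model.params[k]
            mom[k] = b1 * mom[k] + (1 - b1) * g
            vel[k] = b2 * vel[k] + (1 - b2) * g * g
            mhat = mom[k] / (1 - b1 ** t)
            vhat = vel[k] / (1 - b2 ** t)
            model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
    logits, _, _ = model._forward(X, A)
    val_idx = dataset.val_nodes
    if len(val_idx) > 0:
        model.val_accuracy = float(
            np.mean(np.argmax(logits[val_idx], axis=1) == y[val_idx])
        )
    return model


# ---------------------------------------------------------------------------
# explainers
# ---------------------------------------------------------------------------


def random_explainer(
    data: SubgraphData,
    rng: np.random.Generator,
    channel: str = "all",
) -> ExplanationMask:
    """Reference baseline: uninformed importance scores.

    Node and edge scores are uniform(0,1); feature scores are a d-dimensional
    Gaussian vector.  ``channel`` restricts which score vectors are populated
    (``"all"`` fills the three of them).
    """
    node = feat = edge = None
    if channel in ("node", "all"):
        node = rng.random(data.num_nodes)
    if channel in ("feature", "all"):
        feat = rng.standard_normal(data.features.shape[1])
    if channel in ("edge", "all"):
        edge = rng.random(len(data.edges))
    if node is None and feat is None and edge is None:
        raise ValueError(f"unknown channel {channel!r}")
    return ExplanationMask(kind="predicted", node_scores=node,
                           feature_scores=feat, edge_scores=edge)


def gradient_explainer(predictor: Predictor, data: SubgraphData) -> ExplanationMask:
    """Vanilla-gradient saliency of the predicted-class logit.

    Per-entry scores are |d logit / d x|; node scores are row sums, feature
    scores column sums, and each edge scores the mean of its endpoints.
    """
    sal = predictor.input_saliency(data)
    node = sal.sum(axis=1)
    feat = sal.sum(axis=0)
    if len(data.edges) > 0:
        edge = 0.5 * (node[data.edges[:, 0]] + node[data.edges[:, 1]])
    else:
        edge = np.zeros(0)
    return ExplanationMask(kind="predicted", node_scores=node,
                           feature_scores=feat, edge_scores=edge)


def split_dataset(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.05, 0.25),
    seed: int = 0,
) -> np.ndarray:
    """Stratified-by-class seeded train/val/test assignment."""
    labels = np.asarray(labels, dtype=int)
    for c in np.unique(labels):
        if np.sum(labels == c) < sum(f > 0 for f in fractions):
            raise ValueError(f"class {c} too small to stratify")
    return _stratified_split(labels, tuple(fractions), np.random.default_rng(seed))
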