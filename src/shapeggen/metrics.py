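"""Evaluation metrics for graph-explanation quality.

Five complementary views of an explanation's reliability:

* **GEA** (accuracy): best Jaccard overlap between the top-k binarized
  predicted mask and any mask in the ground-truth set.
* **GEF** (unfaithfulness): ``1 - exp(-KL(f(S) || f(S')))`` where ``S'`` keeps
  only the top-k attributes named by the explanation.  0 = the explanation
  preserves the model's prediction exactly.
* **GES** (instability): worst cosine distance between the explanation of a
  subgraph and of any small perturbation of it that leaves the model's
  behavior within a ``delta``-ball.
* **GECF** (counterfactual-fairness mismatch): cosine distance between the
  explanations of a subgraph and of its protected-attribute-flipped
  counterpart.
* **GEGF** (group-fairness mismatch): absolute change in statistical parity
  when predictions are made from explanation-masked inputs instead of the
  originals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .model import (
    EnclosingSubgraph,
    ExplanationMask,
    GroundTruthSet,
    SubgraphData,
    apply_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "MetricResult",
    "binarize_topk",
    "jaccard",
    "gea",
    "gef",
    "perturb_neighborhood",
    "ges",
    "gecf",
    "statistical_parity",
    "gegf",
    "cosine_distance",
]


@dataclass
class MetricConfig:
    """Shared metric parameters.

    ``k_fraction`` is the top-k fraction used to binarize soft masks (25% per
    the benchmark protocol).  The stability parameters define the perturbation
    ball: Gaussian feature noise of ``feature_noise_scale`` times the
    per-column standard deviation, independent edge rewiring with probability
    ``edge_perturb_prob``, and a model-behavior tolerance ``delta`` in
    ``norm_order``-norm on ``behavior_source`` (``None`` means calibrate
    ``delta`` to the 95th percentile of the observed behavior shifts).
    """

    k_fraction: float = 0.25
    stability_samples: int = 25
    feature_noise_scale: float = 0.01
    edge_perturb_prob: float = 0.001
    delta: Optional[float] = None
    norm_order: int = 2
    behavior_source: str = "logits"  # or "embeddings"
    kl_epsilon: float = 1e-12

    def __post_init__(self):
        if not (0 < self.k_fraction <= 1):
            raise ValueError("k_fraction must be in (0, 1]")
        if self.kl_epsilon <= 0:
            raise ValueError("kl_epsilon must be positive")
        if self.behavior_source not in ("logits", "embeddings"):
            raise ValueError("behavior_source must be 'logits' or 'embeddings'")


@dataclass
class MetricResult:
    metric_name: str
    value: float
    per_node_values: Optional[np.ndarray] = None
    n_evaluated: int = 0

    def __post_init__(self):
        if self.per_node_values is not None:
            self.per_node_values = np.asarray(self.per_node_values, dtype=float)
            if self.n_evaluated == 0:
                self.n_evaluated = len(self.per_node_values)
            self.value = float(np.mean(self.per_node_values))


def binarize_topk(scores: np.ndarray, k_fraction: float) -> np.ndarray:
    """Keep the ``ceil(k_fraction * n)`` highest scores; ties favor low index."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot binarize an empty score vector")
    if not (0 < k_fraction <= 1):
        raise ValueError("k_fraction must be in (0, 1]")
    k = int(np.ceil(k_fraction * scores.size))
    order = np.argsort(-scores, kind="stable")
    out = np.zeros(scores.size)
    out[order[:k]] = 1.0
    return out


def jaccard(gt: np.ndarray, pred: np.ndarray) -> float:
    """TP / (TP + FP + FN); two all-zero masks agree vacuously (1.0)."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("mask length mismatch")
    tp = int(np.sum((gt == 1) & (pred == 1)))
    fp = int(np.sum((gt == 0) & (pred == 1)))
    fn = int(np.sum((gt == 1) & (pred == 0)))
    if tp + fp + fn == 0:
        return 1.0
    return tp / (tp + fp + fn)


def gea(
    gts: GroundTruthSet,
    pred: ExplanationMask,
    channel: str = "node",
    k_fraction: float = 0.25,
) -> float:
    """Graph explanation accuracy: max Jaccard over the ground-truth set."""
    if len(gts) == 0:
        raise ValueError("empty ground-truth set")
    binarized = binarize_topk(pred.channel(channel), k_fraction)
    return max(jaccard(m.channel(channel), binarized) for m in gts)


def _kl(p: np.ndarray, q: np.ndarray, eps: float) -> float:
    p = np.clip(np.asarray(p, dtype=float), eps, None)
    q = np.clip(np.asarray(q, dtype=float), eps, None)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def gef(
    predictor,
    subgraph: "EnclosingSubgraph | SubgraphData",
    pred: ExplanationMask,
    channel: str = "node",
    config: Optional[MetricConfig] = None,
) -> float:
    """Graph explanation unfaithfulness, in [0, 1).

    Compares the predictor's softmax on the subgraph against the softmax on
    the top-k-masked subgraph; 0 means the masked input reproduces the
    prediction exactly.
    """
    config = config or MetricConfig()
    data = subgraph.to_data() if isinstance(subgraph, EnclosingSubgraph) else subgraph
    p_full = predictor.predict_proba(data)
    masked = apply_mask(data, pred, channel, config.k_fraction)
    p_masked = predictor.predict_proba(masked)
    if not (np.isfinite(p_full).all() and np.isfinite(p_masked).all()):
        raise ValueError("non-finite predictor output")
    kl = _kl(p_full, p_masked, config.kl_epsilon)
    return float(1.0 - np.exp(-kl))


def perturb_neighborhood(
    subgraph: "EnclosingSubgraph | SubgraphData",
    predictor,
    config: MetricConfig,
    rng: np.random.Generator,
) -> list[SubgraphData]:
    """Sample perturbed copies whose model behavior stays within delta.

    Each copy adds zero-mean Gaussian noise (``feature_noise_scale`` times the
    per-column std) to the features, and independently perturbs each edge with
    probability ``edge_perturb_prob`` (coin flip: delete it, or keep it and add
    one random absent intra-subgraph edge).  Copies whose behavior shift
    exceeds ``delta`` are dropped; with ``delta=None`` the 95th percentile of
    the observed shifts is used.  May return an empty list.
    """
    if config.stability_samples < 1:
        raise ValueError("stability_samples must be >= 1")
    data = subgraph.to_data() if isinstance(subgraph, EnclosingSubgraph) else subgraph
    ref = _behavior(predictor, data, config)
    col_std = data.features.std(axis=0)
    n = data.num_nodes
    existing = {tuple(e) for e in data.edges.tolist()}
    copies: list[SubgraphData] = []
    shifts: list[float] = []
    for _ in range(config.stability_samples):
        c = data.copy()
        if config.feature_noise_scale > 0:
            c.features = c.features + rng.standard_normal(c.features.shape) * (
                config.feature_noise_scale * col_std[None, :]
            )
        if config.edge_perturb_prob > 0 and len(c.edges) > 0:
            keep = rng.random(len(c.edges)) >= config.edge_perturb_prob
            flagged = np.nonzero(~keep)[0]
            edges = [tuple(e) for e in c.edges.tolist()]
            new_edges = [e for i, e in enumerate(edges) if keep[i]]
            for i in flagged:
                if rng.random() < 0.5:
                    continue  # delete
                new_edges.append(edges[i])  # keep, and add one absent edge
                for _ in range(10):
                    a, b = rng.integers(n, size=2)
                    if a == b:
                        continue
                    e = (min(a, b), max(a, b))
                    if e not in existing:
                        new_edges.append((int(e[0]), int(e[1])))
                        break
            c.edges = np.array(sorted(set(new_edges)), dtype=int).reshape(-1, 2)
        shifts.append(
            float(np.linalg.norm(_behavior(predictor, c, config) - ref,
                                 ord=config.norm_order))
        )
        copies.append(c)
    delta = config.delta
    if delta is None:
        delta = float(np.percentile(shifts, 95))
    accepted = [c for c, s in zip(copies, shifts) if s <= delta]
    return accepted


def _behavior(predictor, data: SubgraphData, config: MetricConfig) -> np.ndarray:
    if config.behavior_source == "logits":
        return predictor.predict_logits(data)
    return predictor.predict_embedding(data)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cosine similarity; defined as 1 (maximal) if either vector is zero."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("zero-norm mask in cosine distance; returning maximal distance")
        return 1.0
    return float(1.0 - np.dot(a, b) / (na * nb))


def ges(
    explainer: Callable[[SubgraphData], ExplanationMask],
    predictor,
    subgraph: "EnclosingSubgraph | SubgraphData",
    config: MetricConfig,
    rng: np.random.Generator,
    channel: str = "node",
) -> float:
    """Graph explanation instability: worst-case mask drift over the ball."""
    data = subgraph.to_data() if isinstance(subgraph, EnclosingSubgraph) else subgraph
    base = explainer(data).channel(channel)
    ball = perturb_neighborhood(data, predictor, config, rng)
    if not ball:
        logger.warning("empty perturbation ball; GES defined as 0")
        return 0.0
    return max(
        cosine_distance(base, explainer(c).channel(channel)) for c in ball
    )


def gecf(pred: ExplanationMask, pred_cf: ExplanationMask, channel: str = "node") -> float:
    """Counterfactual-fairness mismatch: cosine distance of the two masks."""
    a = pred.channel(channel)
    b = pred_cf.channel(channel)
    if a.shape != b.shape:
        raise ValueError("counterfactual masks are not aligned")
    return cosine_distance(a, b)


def statistical_parity(preds: np.ndarray, protected: np.ndarray) -> float:
    """|P(y_hat=1 | protected=1) - P(y_hat=1 | protected=0)|."""
    preds = np.asarray(preds)
    protected = np.asarray(protected)
    if preds.shape != protected.shape:
        raise ValueError("length mismatch")
    g1 = preds[protected == 1]
    g0 = preds[protected == 0]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both protected groups must be nonempty")
    return float(abs(np.mean(g1 == 1) - np.mean(g0 == 1)))


def gegf(
    preds_original: np.ndarray,
    preds_masked: np.ndarray,
    protected: np.ndarray,
) -> float:
    """Group-fairness mismatch: |SP(original) - SP(masked)| over the same nodes."""
    return float(
        abs(
            statistical_parity(preds_original, protected)
            - statistical_parity(preds_masked, protected)
        )
    )
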