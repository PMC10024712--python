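"""Core graph containers, enclosing-subgraph extraction and the masking operator.

The objects here are shared by the dataset generator, the predictor harness and
the explanation metrics:

* :class:`SyntheticGraph` -- an undirected node-classification graph with a
  node-feature matrix, class labels and a registry of planted motifs.  Each
  undirected edge is stored in both orientations, so "directed edge counts"
  (as printed in dataset statistics) equal twice the number of undirected edges.
* :class:`EnclosingSubgraph` -- the induced subgraph on all nodes within ``L``
  hops of a center node: the receptive field of an ``L``-layer message-passing
  classifier, and the canvas on which explanation masks live.
* :class:`ExplanationMask` -- per-node / per-feature / per-edge importance
  scores over an enclosing subgraph; binary for ground truth, real-valued for
  explainer output.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MotifInstance",
    "SyntheticGraph",
    "EnclosingSubgraph",
    "SubgraphData",
    "ExplanationMask",
    "GroundTruthSet",
    "enclosing_subgraph",
    "apply_mask",
    "motif_count",
]


def canonical_edge(u: int, v: int) -> tuple[int, int]:
    """Undirected edge key with the smaller endpoint first."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class MotifInstance:
    """A planted template subgraph (e.g. a 5-node house or a triangle).

    The motif's nodes and internal edges constitute the structural part of the
    ground-truth explanation for every node whose label it generates.
    """

    shape_name: str
    node_ids: tuple[int, ...]
    edge_set: frozenset[tuple[int, int]]

    def __post_init__(self):
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("motif node ids must be distinct")


class SyntheticGraph:
    """Undirected graph with features, labels and a motif registry.

    Parameters
    ----------
    num_nodes:
        Number of nodes; ids are the contiguous integers ``0..num_nodes-1``.
    edges:
        Iterable of ordered pairs.  Both orientations of every undirected edge
        are stored; the constructor symmetrizes and deduplicates its input and
        rejects self-loops.
    features:
        ``(num_nodes, n_f)`` real matrix, or ``None`` for a structure-only graph.
    labels:
        Integer class ids in ``{0..K-1}``, or ``None``.
    motifs:
        Planted :class:`MotifInstance` objects.
    """

    def __init__(
        self,
        num_nodes: int,
        edges: Iterable[tuple[int, int]],
        features: Optional[np.ndarray] = None,
        labels: Optional[np.ndarray] = None,
        motifs: Optional[Sequence[MotifInstance]] = None,
        informative_feature_indices: Optional[Sequence[int]] = None,
        protected_feature_index: Optional[int] = None,
    ):
        self.num_nodes = int(num_nodes)
        und = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < num_nodes and 0 <= v < num_nodes):
                raise ValueError(f"edge ({u},{v}) references unknown node")
            und.add(canonical_edge(u, v))
        self._undirected = sorted(und)
        self.features = None if features is None else np.asarray(features, dtype=float)
        self.labels = None if labels is None else np.asarray(labels, dtype=int)
        self.motifs = list(motifs) if motifs is not None else []
        self.informative_feature_indices = (
            tuple(int(i) for i in informative_feature_indices)
            if informative_feature_indices is not None
            else ()
        )
        self.protected_feature_index = (
            None if protected_feature_index is None else int(protected_feature_index)
        )
        self._build_index()
        self.validate()

    # -- derived structure ------------------------------------------------

    def _build_index(self) -> None:
        nbrs: list[list[int]] = [[] for _ in range(self.num_nodes)]
        for u, v in self._undirected:
            nbrs[u].append(v)
            nbrs[v].append(u)
        self._neighbors = [np.array(sorted(n), dtype=int) for n in nbrs]
        # node -> indices of motifs containing it
        memb: list[list[int]] = [[] for _ in range(self.num_nodes)]
        for mi, motif in enumerate(self.motifs):
            for u in motif.node_ids:
                memb[u].append(mi)
        self._node_motifs = memb

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Every undirected edge in both orientations."""
        out = []
        for u, v in self._undirected:
            out.append((u, v))
            out.append((v, u))
        return out

    @property
    def undirected_edges(self) -> list[tuple[int, int]]:
        return list(self._undirected)

    @property
    def num_directed_edges(self) -> int:
        return 2 * len(self._undirected)

    def neighbors(self, u: int) -> np.ndarray:
        return self._neighbors[u]

    def degree(self, u: int) -> int:
        return len(self._neighbors[u])

    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self._neighbors], dtype=int)

    def has_edge(self, u: int, v: int) -> bool:
        return canonical_edge(u, v) in self._edge_lookup()

    def _edge_lookup(self) -> set:
        if not hasattr(self, "_edge_set_cache"):
            self._edge_set_cache = set(self._undirected)
        return self._edge_set_cache

    def motifs_of(self, u: int) -> list[int]:
        return self._node_motifs[u]

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if self.features is not None and self.features.shape[0] != self.num_nodes:
            raise ValueError("feature matrix row count != num_nodes")
        if self.labels is not None:
            if len(self.labels) != self.num_nodes:
                raise ValueError("label vector length != num_nodes")
            if self.labels.min(initial=0) < 0:
                raise ValueError("negative class label")
        if self.features is not None:
            n_f = self.features.shape[1]
            idx = set(self.informative_feature_indices)
            if any(not (0 <= i < n_f) for i in idx):
                raise ValueError("informative feature index out of range")
            if self.protected_feature_index is not None:
                if not (0 <= self.protected_feature_index < n_f):
                    raise ValueError("protected feature index out of range")
                if self.protected_feature_index in idx:
                    raise ValueError("protected feature overlaps informative set")
        for motif in self.motifs:
            for u in motif.node_ids:
                if not (0 <= u < self.num_nodes):
                    raise ValueError("motif node not in graph")
            for e in motif.edge_set:
                if canonical_edge(*e) not in self._edge_lookup():
                    raise ValueError(f"motif edge {e} missing from graph")


@dataclass
class EnclosingSubgraph:
    """Induced subgraph on all nodes within ``hops`` of ``center``.

    ``node_ids`` are sorted parent ids; ``local_index_map`` sends a parent id to
    its position in that order, which fixes the layout of every mask vector.
    ``edges`` is the sorted list of canonical (small-id-first) undirected pairs.
    """

    center: int
    hops: int
    node_ids: np.ndarray
    edges: list[tuple[int, int]]
    local_index_map: dict[int, int]
    graph: SyntheticGraph = field(repr=False)

    @property
    def num_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def to_data(self, features: Optional[np.ndarray] = None) -> "SubgraphData":
        """Concrete array view (features + local edge list) for the predictor."""
        if features is None:
            if self.graph.features is None:
                raise ValueError("parent graph has no features")
            features = self.graph.features[self.node_ids]
        loc = self.local_index_map
        local_edges = np.array(
            [(loc[u], loc[v]) for u, v in self.edges], dtype=int
        ).reshape(-1, 2)
        return SubgraphData(
            center_local=loc[self.center],
            node_ids=np.asarray(self.node_ids, dtype=int),
            features=np.array(features, dtype=float),
            edges=local_edges,
        )


@dataclass
class SubgraphData:
    """Tensorized subgraph view: local features and local undirected edges."""

    center_local: int
    node_ids: np.ndarray
    features: np.ndarray
    edges: np.ndarray  # (m, 2) local indices, canonical orientation, unique

    @property
    def num_nodes(self) -> int:
        return self.features.shape[0]

    def copy(self) -> "SubgraphData":
        return SubgraphData(
            center_local=self.center_local,
            node_ids=self.node_ids.copy(),
            features=self.features.copy(),
            edges=self.edges.copy(),
        )


@dataclass
class ExplanationMask:
    """Importance scores over an enclosing subgraph.

    ``node_scores`` follows the subgraph's local node order, ``edge_scores``
    its canonical edge order, and ``feature_scores`` has length ``n_f``.
    Ground-truth masks are binary; predicted masks are real-valued and are
    binarized at a top-k fraction before accuracy evaluation.
    """

    kind: str  # "ground_truth" | "predicted"
    node_scores: Optional[np.ndarray] = None
    feature_scores: Optional[np.ndarray] = None
    edge_scores: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("ground_truth", "predicted"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        for name in ("node_scores", "feature_scores", "edge_scores"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if self.kind == "ground_truth" and not np.isin(v, (0.0, 1.0)).all():
                    raise ValueError("ground-truth masks must be binary")
                setattr(self, name, v)

    def channel(self, which: str) -> np.ndarray:
        m = {"node": self.node_scores, "feature": self.feature_scores,
             "edge": self.edge_scores}
        if which not in m:
            raise ValueError(f"unknown channel {which!r}")
        if m[which] is None:
            raise ValueError(f"mask has no {which} channel")
        return m[which]


@dataclass
class GroundTruthSet:
    """The set of equally valid ground-truth explanations for one node."""

    masks: list[ExplanationMask]

    def __post_init__(self):
        if not self.masks:
            raise ValueError("ground-truth set must be nonempty")
        if any(m.kind != "ground_truth" for m in self.masks):
            raise ValueError("all masks in a GroundTruthSet must be ground truth")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def enclosing_subgraph(graph: SyntheticGraph, center: int, hops: int) -> EnclosingSubgraph:
    """Induced subgraph on all nodes at shortest-path distance <= hops of center.

    Local node order is ascending parent id, making mask vectors reproducible.
    """
    if not (0 <= center < graph.num_nodes):
        raise ValueError(f"unknown node id {center}")
    if hops < 0:
        raise ValueError("hops must be >= 0")
    seen = {center}
    frontier = deque([(center, 0)])
    while frontier:
        u, d = frontier.popleft()
        if d == hops:
            continue
        for v in graph.neighbors(u):
            v = int(v)
            if v not in seen:
                seen.add(v)
                frontier.append((v, d + 1))
    node_ids = np.array(sorted(seen), dtype=int)
    loc = {int(u): i for i, u in enumerate(node_ids)}
    edges = []
    for u in node_ids:
        for v in graph.neighbors(int(u)):
            v = int(v)
            if u < v and v in seen:
                edges.append((int(u), v))
    edges.sort()
    return EnclosingSubgraph(
        center=center, hops=hops, node_ids=node_ids, edges=edges,
        local_index_map=loc, graph=graph,
    )


def _binarize_topk(scores: np.ndarray, k_fraction: float) -> np.ndarray:
    # local copy to avoid an import cycle with metrics; same tie rule
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    k = int(np.ceil(k_fraction * scores.size))
    order = np.argsort(-scores, kind="stable")  # ties -> lowest index first
    out = np.zeros(scores.size)
    out[order[:k]] = 1.0
    return out


def apply_mask(
    subgraph: "EnclosingSubgraph | SubgraphData",
    mask: ExplanationMask,
    mode: str,
    k_fraction: float = 1.0,
) -> SubgraphData:
    """Keep only the top-k scored attributes of one channel; zero/remove the rest.

    ``mode="feature"`` zeroes feature columns outside the kept set,
    ``mode="node"`` zeroes the feature rows of non-kept nodes (structure kept),
    ``mode="edge"`` removes non-kept undirected edges.  The input is never
    modified.
    """
    if not (0 < k_fraction <= 1):
        raise ValueError("k_fraction must be in (0, 1]")
    data = subgraph.to_data() if isinstance(subgraph, EnclosingSubgraph) else subgraph.copy()
    scores = mask.channel(mode)
    if mode == "feature":
        if len(scores) != data.features.shape[1]:
            raise ValueError("feature mask length mismatch")
        keep = _binarize_topk(scores, k_fraction).astype(bool)
        data.features = data.features * keep[None, :]
    elif mode == "node":
        if len(scores) != data.num_nodes:
            raise ValueError("node mask length mismatch")
        keep = _binarize_topk(scores, k_fraction).astype(bool)
        data.features = data.features * keep[:, None]
    elif mode == "edge":
        if len(scores) != len(data.edges):
            raise ValueError("edge mask length mismatch")
        keep = _binarize_topk(scores, k_fraction).astype(bool)
        data.edges = data.edges[keep]
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    return data


def motif_count(graph: SyntheticGraph, v: int) -> int:
    """Number of planted motifs intersecting the closed neighborhood of ``v``.

    The closed neighborhood (node plus its 1-hop neighbors) is used so that a
    motif member always counts its own motif; the node's label is this count
    minus one, clipped to the class range.
    """
    if not (0 <= v < graph.num_nodes):
        raise ValueError(f"unknown node id {v}")
    hit: set[int] = set(graph.motifs_of(v))
    for u in graph.neighbors(v):
        hit.update(graph.motifs_of(int(u)))
    return len(hit)
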