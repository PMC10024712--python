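"""Seeded generator of motif-planted graphs with ground-truth explanations.

The construction, end to end:

1. **Growth** -- ``N_s`` subgraphs are grown independently.  Each starts from a
   copy of the motif (house or triangle) and adds ``n' ~ Poisson(n_s - |motif|)``
   nodes one at a time; every new node attaches with ``m`` edges to existing
   nodes of its subgraph, sampled with probability proportional to the square
   of their current degree.  The superlinear kernel concentrates attachment on
   a few local hubs and gives the assembled graph the heavy-tailed degree
   distribution seen in real social and financial networks.
2. **Wiring** -- for every ordered pair of distinct subgraphs an inter-subgraph
   bridge edge is added with probability ``p``.  Bridge endpoints are drawn
   from each subgraph's motif nodes and their direct neighbors, again with a
   degree-squared preference (motif nodes carry a fixed down-weight so the
   chance of landing on an actual motif node stays moderate), preferring nodes
   that still have fewer than ``K`` motifs in their 1-hop neighborhood.
3. **Labels** -- a node's class is the number of motifs intersecting its closed
   1-hop neighborhood, minus one, clipped to ``{0..K-1}``.  Bridge endpoints
   whose partner endpoint is a motif node therefore move to class 1.
4. **Features** -- ``n_i`` informative columns follow a latent hypercube
   cluster model (``K*c_f`` centroids at vertices of ``{-s_f,+s_f}^{n_i}``,
   unit Gaussian noise), the protected column equals the binarized label
   XOR-flipped with probability ``phi``, and the remaining columns are
   standard-normal noise whose directions are then mixed with (``eta > 0``) or
   against (``eta < 0``) the neighborhood average to control homophily.
5. **Ground truth** -- for each node, binary node/feature/edge masks over its
   ``L``-hop enclosing subgraph: motif membership for nodes, informative
   columns for features, and motif-or-center incidence for edges.  When
   several motifs intersect the subgraph the ground-truth set also contains
   one mask per motif, since each motif alone is an equally valid rationale.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .model import (
    EnclosingSubgraph,
    ExplanationMask,
    GroundTruthSet,
    MotifInstance,
    SyntheticGraph,
    canonical_edge,
    enclosing_subgraph,
    motif_count,
)

__all__ = [
    "GeneratorConfig",
    "ShapeGGenDataset",
    "GroundTruthMap",
    "make_motif",
    "grow_subgraph",
    "connect_subgraphs",
    "assign_labels",
    "generate_informative_features",
    "add_redundant_and_protected",
    "apply_homophily",
    "build_ground_truth",
    "generate",
    "preset",
    "PRESETS",
    "ba_shapes",
]

# Calibration constants of the reconstruction (see docs/methods.md): the
# attachment kernel exponent used both in growth and bridge-endpoint sampling,
# and the sampling down-weight of motif nodes among bridge-endpoint candidates.
ATTACH_KERNEL_EXP = 2.0
BRIDGE_MOTIF_WEIGHT = 0.3

SPLIT_FRACTIONS = (0.70, 0.05, 0.25)

_HOUSE_EDGES = ((0, 1), (1, 2), (2, 3), (3, 0), (1, 4), (2, 4))
_TRIANGLE_EDGES = ((0, 1), (1, 2), (2, 0))


@dataclass(frozen=True)
class GeneratorConfig:
    """All generation parameters plus the RNG seed.

    ``motif_shape`` is ``"house"`` (5 nodes: 4-cycle base plus a roof apex
    joined to the two top base nodes), ``"triangle"``, or a custom
    :class:`MotifInstance` template with 0-based local node ids.
    """

    motif_shape: Union[str, MotifInstance] = "house"
    num_subgraphs: int = 1200          # N_s
    connection_prob: float = 0.006     # p
    subgraph_size: int = 11            # n_s (expected nodes per subgraph)
    num_classes: int = 2               # K
    num_features: int = 11             # n_f
    num_informative: int = 4           # n_i
    class_sep: float = 0.6             # s_f
    clusters_per_class: int = 2        # c_f
    protected_noise: float = 0.5       # phi
    homophily: float = 1.0             # eta
    gnn_layers: int = 3                # L
    attach_edges: int = 1              # m, edges per attached node
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if not (0 <= self.connection_prob <= 1):
            raise ValueError("connection_prob must be in [0, 1]")
        if not (0 <= self.protected_noise <= 1):
            raise ValueError("protected_noise must be in [0, 1]")
        if self.num_informative >= self.num_features:
            raise ValueError("num_informative must leave room for the protected column")
        motif = make_motif(self.motif_shape)
        if len(motif.node_ids) > self.subgraph_size:
            raise ValueError("subgraph_size smaller than the motif")
        if self.attach_edges < 1:
            raise ValueError("attach_edges must be >= 1")

    # flat key/value serialization with the field-file names S, N_s, ...
    _KEYMAP = {
        "S": "motif_shape", "N_s": "num_subgraphs", "p": "connection_prob",
        "n_s": "subgraph_size", "K": "num_classes", "n_f": "num_features",
        "n_i": "num_informative", "s_f": "class_sep", "c_f": "clusters_per_class",
        "phi": "protected_noise", "eta": "homophily", "L": "gnn_layers",
        "m": "attach_edges", "seed": "seed",
    }

    def to_dict(self) -> dict:
        d = {}
        for short, name in self._KEYMAP.items():
            v = getattr(self, name)
            if isinstance(v, MotifInstance):
                v = {"shape_name": v.shape_name,
                     "node_ids": list(v.node_ids),
                     "edges": sorted(map(list, v.edge_set))}
            d[short] = v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        kwargs = {}
        for short, v in d.items():
            if short not in cls._KEYMAP:
                raise ValueError(f"unknown config key {short!r}")
            if short == "S" and isinstance(v, Mapping):
                v = MotifInstance(
                    shape_name=v["shape_name"],
                    node_ids=tuple(v["node_ids"]),
                    edge_set=frozenset(canonical_edge(*e) for e in v["edges"]),
                )
            kwargs[cls._KEYMAP[short]] = v
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def make_motif(shape: Union[str, MotifInstance]) -> MotifInstance:
    """Motif template with local node ids 0..n-1."""
    if isinstance(shape, MotifInstance):
        return shape
    if shape == "house":
        edges = _HOUSE_EDGES
        n = 5
    elif shape == "triangle":
        edges = _TRIANGLE_EDGES
        n = 3
    else:
        raise ValueError(f"unknown motif shape {shape!r}; expected 'house' or 'triangle'")
    return MotifInstance(
        shape_name=shape,
        node_ids=tuple(range(n)),
        edge_set=frozenset(canonical_edge(*e) for e in edges),
    )


PRESETS: dict[str, GeneratorConfig] = {
    "SG-Base": GeneratorConfig(),
    "SG-Heterophilic": GeneratorConfig(homophily=-1.0),
    "SG-SmallEx": GeneratorConfig(
        motif_shape="triangle", num_subgraphs=1300, subgraph_size=12, class_sep=0.5
    ),
    "SG-Unfair": GeneratorConfig(protected_noise=0.75),
    "SG-MoreInform": GeneratorConfig(num_informative=8),
    "SG-LessInform": GeneratorConfig(num_features=21),
}


def preset(name: str) -> GeneratorConfig:
    """Named parameter sets for the published benchmark instances."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None


@dataclass
class LocalSubgraph:
    """One grown subgraph before assembly (local 0-based ids)."""

    num_nodes: int
    edges: list[tuple[int, int]]
    motif: MotifInstance  # local ids


def grow_subgraph(
    template: MotifInstance,
    n_s: int,
    m: int,
    rng: np.random.Generator,
) -> LocalSubgraph:
    """Grow one subgraph: motif plus ``Poisson(n_s - |motif|)`` attached nodes.

    Each new node attaches with ``min(m, existing)`` edges to distinct existing
    nodes drawn with probability proportional to degree**ATTACH_KERNEL_EXP.
    """
    motif_n = len(template.node_ids)
    if n_s < motif_n:
        raise ValueError("n_s must be at least the motif size")
    lam = n_s - motif_n
    n_extra = int(rng.poisson(lam)) if lam > 0 else 0
    edges = [canonical_edge(*e) for e in sorted(template.edge_set)]
    deg = np.zeros(motif_n + n_extra, dtype=float)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    n = motif_n
    for _ in range(n_extra):
        w = deg[:n] ** ATTACH_KERNEL_EXP
        k = min(m, n)
        targets = rng.choice(n, size=k, replace=False, p=w / w.sum())
        for t in targets:
            edges.append(canonical_edge(int(t), n))
            deg[t] += 1
            deg[n] += 1
        n += 1
    return LocalSubgraph(num_nodes=n, edges=edges, motif=template)


def connect_subgraphs(
    subgraphs: list[LocalSubgraph],
    p: float,
    K: int,
    rng: np.random.Generator,
) -> SyntheticGraph:
    """Relabel subgraphs into one id space and add inter-subgraph bridges.

    For every ordered pair of distinct subgraphs, with probability ``p`` one
    bridge edge is added.  Each endpoint is drawn from its subgraph's motif
    nodes and their direct neighbors, proportional to current
    degree**ATTACH_KERNEL_EXP (motif nodes additionally weighted by
    BRIDGE_MOTIF_WEIGHT), restricted to nodes with fewer than ``K`` motifs in
    their closed 1-hop neighborhood whenever any such node remains.
    """
    if len(subgraphs) < 2:
        raise ValueError("need at least two subgraphs")
    offset = 0
    all_edges: list[tuple[int, int]] = []
    motifs: list[MotifInstance] = []
    pools: list[tuple[np.ndarray, np.ndarray]] = []  # (global ids, is_motif)
    motif_sets: list[set[int]] = []
    for sg in subgraphs:
        g_edges = [(u + offset, v + offset) for u, v in sg.edges]
        all_edges.extend(g_edges)
        g_motif = MotifInstance(
            shape_name=sg.motif.shape_name,
            node_ids=tuple(u + offset for u in sg.motif.node_ids),
            edge_set=frozenset(
                canonical_edge(u + offset, v + offset) for u, v in sg.motif.edge_set
            ),
        )
        motifs.append(g_motif)
        mset = set(g_motif.node_ids)
        adj: set[int] = set()
        for u, v in g_edges:
            if u in mset and v not in mset:
                adj.add(v)
            elif v in mset and u not in mset:
                adj.add(u)
        ids = np.array(sorted(mset) + sorted(adj), dtype=int)
        pools.append((ids, np.isin(ids, sorted(mset))))
        motif_sets.append(mset)
        offset += sg.num_nodes
    num_nodes = offset

    deg = np.zeros(num_nodes, dtype=float)
    for u, v in all_edges:
        deg[u] += 1
        deg[v] += 1
    # motifs in the closed 1-hop neighborhood; pool members see their own motif
    count = np.zeros(num_nodes, dtype=int)
    for ids, _ in pools:
        count[ids] += 1

    n_sub = len(subgraphs)

    def pick_endpoint(i: int) -> int:
        ids, is_m = pools[i]
        eligible = count[ids] < K
        cand = ids[eligible] if eligible.any() else ids
        cm = is_m[eligible] if eligible.any() else is_m
        w = deg[cand] ** ATTACH_KERNEL_EXP * np.where(cm, BRIDGE_MOTIF_WEIGHT, 1.0)
        return int(rng.choice(cand, p=w / w.sum()))

    for i in range(n_sub):
        hits = np.nonzero(rng.random(n_sub) < p)[0]
        for j in hits:
            if j == i:
                continue
            u = pick_endpoint(i)
            v = pick_endpoint(int(j))
            all_edges.append(canonical_edge(u, v))
            deg[u] += 1
            deg[v] += 1
            if v in motif_sets[j]:
                count[u] += 1
            if u in motif_sets[i]:
                count[v] += 1

    return SyntheticGraph(num_nodes=num_nodes, edges=all_edges, motifs=motifs)


def assign_labels(graph: SyntheticGraph, K: int) -> np.ndarray:
    """Label(v) = (# motifs intersecting closed 1-hop neighborhood) - 1, clipped.

    Preferentially attached nodes more than one hop from every motif have a
    count of zero and take class 0, the same class as single-motif nodes.
    """
    counts = np.array([motif_count(graph, v) for v in range(graph.num_nodes)])
    return np.clip(counts - 1, 0, K - 1).astype(int)


def generate_informative_features(
    labels: np.ndarray,
    n_i: int,
    s_f: float,
    c_f: int,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent hypercube cluster model for the informative feature block.

    ``K*c_f`` centroids sit at distinct vertices of ``{-s_f, +s_f}^{n_i}``;
    each class owns ``c_f`` of them.  A node picks one of its class's
    centroids uniformly and adds unit Gaussian noise.
    """
    if n_i < 1:
        raise ValueError("need at least one informative feature")
    n_vertices = 2 ** n_i
    if K * c_f > n_vertices:
        raise ValueError("not enough hypercube vertices for K*c_f centroids")
    vertex_ids = rng.choice(n_vertices, size=K * c_f, replace=False)
    bits = ((vertex_ids[:, None] >> np.arange(n_i)) & 1).astype(float)
    centroids = np.where(bits > 0, s_f, -s_f)  # (K*c_f, n_i)
    labels = np.asarray(labels, dtype=int)
    choice = rng.integers(0, c_f, size=len(labels))
    centroid_idx = labels * c_f + choice
    return centroids[centroid_idx] + rng.standard_normal((len(labels), n_i))


def add_redundant_and_protected(
    informative: np.ndarray,
    labels: np.ndarray,
    n_f: int,
    n_i: int,
    phi: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[int, ...], int]:
    """Assemble the full feature matrix.

    Layout: columns ``0..n_i-1`` informative, ``n_i..n_f-2`` redundant
    standard-normal noise, column ``n_f-1`` the binary protected attribute
    (binarized label XOR a Bernoulli(phi) flip).  Returns the matrix together
    with the informative index set and the protected column index.
    """
    if n_f < n_i + 1:
        raise ValueError("n_f must exceed n_i (room for the protected column)")
    n = len(labels)
    X = np.empty((n, n_f))
    X[:, :n_i] = informative
    n_red = n_f - n_i - 1
    if n_red > 0:
        X[:, n_i:n_i + n_red] = rng.standard_normal((n, n_red))
    flips = rng.random(n) < phi
    X[:, n_f - 1] = ((np.asarray(labels) > 0) ^ flips).astype(float)
    return X, tuple(range(n_i)), n_f - 1


def apply_homophily(
    graph: SyntheticGraph,
    features: np.ndarray,
    eta: float,
    redundant_indices: tuple[int, ...],
) -> np.ndarray:
    """Mix each node's redundant block with its neighborhood average.

    One synchronous pass: ``x_r(v) <- unit(x_r(v) + eta * mean_u x_r(u))`` over
    neighbors ``u``.  Positive ``eta`` pulls adjacent nodes together
    (homophily), negative pushes them apart (heterophily).  Informative and
    protected columns are untouched; isolated nodes keep their block.
    """
    if not redundant_indices:
        return features.copy()
    idx = np.asarray(redundant_indices, dtype=int)
    X = features.copy()
    R = features[:, idx]
    neigh_mean = np.zeros_like(R)
    degs = np.zeros(graph.num_nodes)
    for u, v in graph.undirected_edges:
        neigh_mean[u] += R[v]
        neigh_mean[v] += R[u]
        degs[u] += 1
        degs[v] += 1
    has = degs > 0
    neigh_mean[has] /= degs[has, None]
    new = R.copy()
    new[has] = R[has] + eta * neigh_mean[has]
    norms = np.linalg.norm(new, axis=1)
    ok = has & (norms > 0)
    new[ok] /= norms[ok, None]
    X[:, idx] = np.where(has[:, None], new, R)
    return X


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _ground_truth_for(
    graph: SyntheticGraph,
    v: int,
    L: int,
    informative_idx: tuple[int, ...],
    n_f: int,
) -> GroundTruthSet:
    sub = enclosing_subgraph(graph, v, L)
    in_sub = set(int(u) for u in sub.node_ids)
    feature_mask = np.zeros(n_f)
    feature_mask[list(informative_idx)] = 1.0

    # motifs intersecting the enclosing subgraph
    hit_motifs: list[int] = sorted(
        {mi for u in sub.node_ids for mi in graph.motifs_of(int(u))}
    )

    def masks_for(node_set: set[int]) -> ExplanationMask:
        node_mask = np.array(
            [1.0 if int(u) in node_set else 0.0 for u in sub.node_ids]
        )
        keep = node_set | {v}
        edge_mask = np.array(
            [1.0 if (a in keep and b in keep) else 0.0 for a, b in sub.edges]
        )
        return ExplanationMask(
            kind="ground_truth",
            node_scores=node_mask,
            feature_scores=feature_mask.copy(),
            edge_scores=edge_mask,
        )

    # One mask per motif: each motif alone is an equally valid rationale for
    # the label, so the ground-truth set enumerates them rather than their
    # union (with a single motif the two coincide).
    masks = [
        masks_for({u for u in graph.motifs[mi].node_ids if u in in_sub})
        for mi in hit_motifs
    ]
    if not masks:  # no motif reaches Sub(v;L); vacuous all-zero truth
        masks = [masks_for(set())]
    return GroundTruthSet(masks=masks)


class GroundTruthMap(Mapping):
    """Node id -> :class:`GroundTruthSet`, computed on first access and cached.

    Masks are a pure function of the graph, so lazy evaluation is
    indistinguishable from eager construction while keeping generation of
    graphs with tens of thousands of nodes fast.
    """

    def __init__(self, graph: SyntheticGraph, L: int,
                 informative_idx: tuple[int, ...], n_f: int):
        self._graph = graph
        self._L = int(L)
        self._informative = tuple(informative_idx)
        self._n_f = int(n_f)
        self._cache: dict[int, GroundTruthSet] = {}

    @property
    def hops(self) -> int:
        return self._L

    def __getitem__(self, v: int) -> GroundTruthSet:
        v = int(v)
        if not (0 <= v < self._graph.num_nodes):
            raise KeyError(v)
        if v not in self._cache:
            self._cache[v] = _ground_truth_for(
                self._graph, v, self._L, self._informative, self._n_f
            )
        return self._cache[v]

    def __len__(self) -> int:
        return self._graph.num_nodes

    def __iter__(self):
        return iter(range(self._graph.num_nodes))


def build_ground_truth(
    graph: SyntheticGraph,
    L: int,
    informative_idx: tuple[int, ...],
    n_f: Optional[int] = None,
) -> GroundTruthMap:
    """Ground-truth explanation masks for every node over its L-hop subgraph."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if n_f is None:
        if graph.features is None:
            raise ValueError("n_f required for a graph without features")
        n_f = graph.features.shape[1]
    return GroundTruthMap(graph, L, tuple(informative_idx), n_f)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class ShapeGGenDataset:
    """A generated graph with ground truth, configuration and node splits."""

    graph: SyntheticGraph
    ground_truth: GroundTruthMap
    config: object
    split: np.ndarray  # array of "train" | "val" | "test" tokens

    def nodes_in(self, part: str) -> np.ndarray:
        return np.nonzero(self.split == part)[0]

    @property
    def train_nodes(self) -> np.ndarray:
        return self.nodes_in("train")

    @property
    def val_nodes(self) -> np.ndarray:
        return self.nodes_in("val")

    @property
    def test_nodes(self) -> np.ndarray:
        return self.nodes_in("test")


def _stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(labels)
    split = np.empty(n, dtype=object)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        n_tr = int(round(fractions[0] * len(idx)))
        n_va = int(round(fractions[1] * len(idx)))
        split[idx[:n_tr]] = "train"
        split[idx[n_tr:n_tr + n_va]] = "val"
        split[idx[n_tr + n_va:]] = "test"
    return split.astype(str)


def generate(config: GeneratorConfig) -> ShapeGGenDataset:
    """Run the full pipeline; byte-identical output for identical configs."""
    rng = np.random.default_rng(config.seed)
    template = make_motif(config.motif_shape)
    subs = [
        grow_subgraph(template, config.subgraph_size, config.attach_edges, rng)
        for _ in range(config.num_subgraphs)
    ]
    graph = connect_subgraphs(subs, config.connection_prob, config.num_classes, rng)
    labels = assign_labels(graph, config.num_classes)
    informative = generate_informative_features(
        labels, config.num_informative, config.class_sep,
        config.clusters_per_class, config.num_classes, rng,
    )
    X, inf_idx, prot_idx = add_redundant_and_protected(
        informative, labels, config.num_features, config.num_informative,
        config.protected_noise, rng,
    )
    redundant = tuple(range(config.num_informative, config.num_features - 1))
    graph.features = X
    graph.labels = labels
    graph.informative_feature_indices = inf_idx
    graph.protected_feature_index = prot_idx
    X = apply_homophily(graph, X, config.homophily, redundant)
    graph.features = X
    graph.validate()
    gt = build_ground_truth(graph, config.gnn_layers, inf_idx, config.num_features)
    split = _stratified_split(labels, SPLIT_FRACTIONS, rng)
    return ShapeGGenDataset(graph=graph, ground_truth=gt, config=config, split=split)


# ---------------------------------------------------------------------------
# BA-Shapes
# ---------------------------------------------------------------------------


def ba_shapes(
    num_nodes: int,
    num_houses: int,
    perturb_edges: int = 0,
    seed: int = 0,
    num_features: int = 10,
    hops: int = 3,
) -> ShapeGGenDataset:
    """Classic house-planting benchmark on a Barabasi-Albert base graph.

    A BA graph on ``num_nodes`` nodes (one edge per arriving node) gets
    ``num_houses`` five-node houses, each attached by a single edge to a
    uniformly chosen base node, plus ``perturb_edges`` random extra edges.
    Labels are binary house membership; node features are pure noise (the
    ground-truth feature mask is empty).
    """
    import networkx as nx

    if num_nodes < 5:
        raise ValueError("need at least 5 base nodes")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(num_nodes, 1, seed=int(rng.integers(2 ** 31)))
    edges = [canonical_edge(u, v) for u, v in base.edges()]
    motifs = []
    n = num_nodes
    house = make_motif("house")
    for _ in range(num_houses):
        ids = tuple(range(n, n + 5))
        motifs.append(
            MotifInstance(
                shape_name="house",
                node_ids=ids,
                edge_set=frozenset(
                    canonical_edge(u + n, v + n) for u, v in house.edge_set
                ),
            )
        )
        edges.extend(canonical_edge(u + n, v + n) for u, v in house.edge_set)
        anchor = int(rng.integers(num_nodes))
        edges.append(canonical_edge(anchor, n + int(rng.integers(5))))
        n += 5
    existing = set(edges)
    added = 0
    while added < perturb_edges:
        u, v = rng.integers(n, size=2)
        if u == v:
            continue
        e = canonical_edge(int(u), int(v))
        if e in existing:
            continue
        existing.add(e)
        edges.append(e)
        added += 1
    labels = np.zeros(n, dtype=int)
    for m in motifs:
        labels[list(m.node_ids)] = 1
    X = rng.standard_normal((n, num_features))
    graph = SyntheticGraph(
        num_nodes=n, edges=edges, features=X, labels=labels, motifs=motifs,
        informative_feature_indices=(), protected_feature_index=None,
    )
    gt = build_ground_truth(graph, hops, (), num_features)
    split = _stratified_split(labels, SPLIT_FRACTIONS, rng)
    cfg = {"generator": "ba_shapes", "num_nodes": num_nodes,
           "num_houses": num_houses, "perturb_edges": perturb_edges,
           "num_features": num_features, "hops": hops, "seed": seed}
    return ShapeGGenDataset(graph=graph, ground_truth=gt, config=cfg, split=split)
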