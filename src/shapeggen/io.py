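"""Dataset bundle serialization (plain-text formats, exact round trip).

A bundle directory contains:

* ``edges.tsv``      -- directed edge list, both orientations of each edge
* ``graph.graphml``  -- same structure with labels/features as node attributes
* ``features.csv``   -- node-feature matrix; header flags each column as
  informative / redundant / protected
* ``labels.csv``     -- node_id, label
* ``split.csv``      -- node_id, split (train | val | test)
* ``motifs.json``    -- planted motif registry
* ``config.json``    -- generator parameters (flat key/value, incl. seed)
* ``masks.json``     -- optional ground-truth masks per node

Ground-truth masks are a pure function of the graph, so ``read_dataset``
rebuilds them from the structure rather than trusting the mask file; the file
exists for consumption by external tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .generator import (
    GeneratorConfig,
    GroundTruthMap,
    ShapeGGenDataset,
    build_ground_truth,
)
from .model import MotifInstance, SyntheticGraph, canonical_edge, enclosing_subgraph

__all__ = ["DatasetBundle", "write_dataset", "read_dataset"]

_FILES = ("edges.tsv", "graph.graphml", "features.csv", "labels.csv",
          "split.csv", "motifs.json", "config.json")


@dataclass
class DatasetBundle:
    root: Path

    @property
    def edges(self) -> Path:
        return self.root / "edges.tsv"

    @property
    def graphml(self) -> Path:
        return self.root / "graph.graphml"

    @property
    def features(self) -> Path:
        return self.root / "features.csv"

    @property
    def labels(self) -> Path:
        return self.root / "labels.csv"

    @property
    def split(self) -> Path:
        return self.root / "split.csv"

    @property
    def motifs(self) -> Path:
        return self.root / "motifs.json"

    @property
    def config(self) -> Path:
        return self.root / "config.json"

    @property
    def masks(self) -> Path:
        return self.root / "masks.json"


def _column_names(graph: SyntheticGraph) -> list[str]:
    n_f = graph.features.shape[1]
    inf = set(graph.informative_feature_indices)
    names = []
    for j in range(n_f):
        if j in inf:
            kind = "informative"
        elif j == graph.protected_feature_index:
            kind = "protected"
        else:
            kind = "redundant"
        names.append(f"f{j}:{kind}")
    return names


def write_dataset(
    dataset: ShapeGGenDataset,
    out_dir: Union[str, Path],
    masks: Union[str, Iterable[int]] = "all",
) -> DatasetBundle:
    """Write the bundle; ``masks`` is ``"all"``, ``"none"`` or a node-id list."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    bundle = DatasetBundle(root)
    graph = dataset.graph

    with open(bundle.edges, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")

    pd.DataFrame(graph.features, columns=_column_names(graph)).to_csv(
        bundle.features, index_label="node_id", float_format="%.17g"
    )
    pd.DataFrame({"label": graph.labels}).to_csv(bundle.labels, index_label="node_id")
    pd.DataFrame({"split": dataset.split}).to_csv(bundle.split, index_label="node_id")

    with open(bundle.motifs, "w") as fh:
        json.dump(
            [
                {
                    "shape_name": m.shape_name,
                    "node_ids": list(m.node_ids),
                    "edges": sorted(map(list, m.edge_set)),
                }
                for m in graph.motifs
            ],
            fh,
        )

    cfg = dataset.config
    with open(bundle.config, "w") as fh:
        if isinstance(cfg, GeneratorConfig):
            json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
        else:
            json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")

    _write_graphml(graph, bundle.graphml)

    if masks != "none":
        node_ids = range(graph.num_nodes) if masks == "all" else masks
        payload = {}
        for v in node_ids:
            gts = dataset.ground_truth[int(v)]
            sub_nodes = None
            entries = []
            for mask in gts:
                entries.append(
                    {
                        "node_mask": mask.node_scores.astype(int).tolist(),
                        "edge_mask": mask.edge_scores.astype(int).tolist(),
                    }
                )
            # subgraph layout shared by all masks of this node
            sub = enclosing_subgraph(graph, int(v), dataset.ground_truth.hops)
            payload[str(int(v))] = {
                "nodes": sub.node_ids.tolist(),
                "edges": [list(e) for e in sub.edges],
                "feature_mask": gts.masks[0].feature_scores.astype(int).tolist(),
                "masks": entries,
            }
        with open(bundle.masks, "w") as fh:
            json.dump(payload, fh)
    return bundle


def _write_graphml(graph: SyntheticGraph, path: Path) -> None:
    import networkx as nx

    G = nx.Graph()
    for v in range(graph.num_nodes):
        attrs = {"label": int(graph.labels[v])} if graph.labels is not None else {}
        if graph.features is not None:
            for j, x in enumerate(graph.features[v]):
                attrs[f"f{j}"] = float(x)
        G.add_node(v, **attrs)
    G.add_edges_from(graph.undirected_edges)
    nx.write_graphml(G, path)


def read_dataset(in_dir: Union[str, Path]) -> ShapeGGenDataset:
    """Reconstruct a dataset from a bundle; validates structural invariants."""
    root = Path(in_dir)
    bundle = DatasetBundle(root)
    for name in _FILES:
        if not (root / name).exists():
            raise FileNotFoundError(f"bundle incomplete: missing {root / name}")

    edges_df = pd.read_csv(bundle.edges, sep="\t")
    if list(edges_df.columns) != ["source", "target"]:
        raise ValueError(f"{bundle.edges}: expected columns source, target")
    directed = set(zip(edges_df["source"].astype(int), edges_df["target"].astype(int)))
    for u, v in directed:
        if (v, u) not in directed:
            raise ValueError(
                f"{bundle.edges}: edge ({u},{v}) present without its reverse"
            )

    feat_df = pd.read_csv(bundle.features, index_col="node_id",
                          float_precision="round_trip")
    informative, protected = [], None
    for j, col in enumerate(feat_df.columns):
        name, _, kind = col.partition(":")
        if name != f"f{j}":
            raise ValueError(f"{bundle.features}: unexpected column {col!r}")
        if kind == "informative":
            informative.append(j)
        elif kind == "protected":
            protected = j
        elif kind != "redundant":
            raise ValueError(f"{bundle.features}: unknown column kind {kind!r}")
    features = feat_df.to_numpy(dtype=float)

    labels = pd.read_csv(bundle.labels, index_col="node_id")["label"].to_numpy(int)
    split = pd.read_csv(bundle.split, index_col="node_id")["split"].to_numpy(str)
    if len(labels) != len(features) or len(split) != len(features):
        raise ValueError(f"{bundle.labels}/{bundle.split}: length mismatch with features")

    with open(bundle.motifs) as fh:
        motifs = [
            MotifInstance(
                shape_name=m["shape_name"],
                node_ids=tuple(m["node_ids"]),
                edge_set=frozenset(canonical_edge(*e) for e in m["edges"]),
            )
            for m in json.load(fh)
        ]

    graph = SyntheticGraph(
        num_nodes=len(features),
        edges=directed,
        features=features,
        labels=labels,
        motifs=motifs,
        informative_feature_indices=informative,
        protected_feature_index=protected,
    )

    with open(bundle.config) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict) and raw.get("generator") == "ba_shapes":
        config: object = raw
        hops = int(raw["hops"])
    else:
        config = GeneratorConfig.from_dict(raw)
        hops = config.gnn_layers
    gt = build_ground_truth(graph, hops, tuple(informative), features.shape[1])
    return ShapeGGenDataset(graph=graph, ground_truth=gt, config=config,
                            split=split)
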