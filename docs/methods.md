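# Methods

This note documents the generative model, its parameters, the evaluation
metrics, and the design choices made where the construction was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model

### Structure

The generator assembles `N_s` subgraphs and wires them together.

**Growth.** Each subgraph starts from a copy of the motif (house: 5 nodes,
6 edges — a 4-cycle base with a roof apex joined to the two top base nodes;
triangle: K₃) and adds `n′ ~ Poisson(n_s − |motif|)` nodes sequentially.
Each new node attaches with `m` edges (default `m = 1`) to distinct existing
nodes of its subgraph, sampled with probability proportional to
degree<sup>2</sup>.  The superlinear kernel concentrates attachment on a few
local hubs; together with Poisson-dispersed subgraph sizes this produces the
hub-dominated, heavy-tailed degree distribution characteristic of social and
financial networks (the test suite contrasts it with an equal-density
Erdős–Rényi control, whose maximum degree stays close to the mean).

**Wiring.** For every *ordered* pair of distinct subgraphs, one bridge edge
is added with probability `p`, so a graph carries `N_s(N_s−1)·p` bridges in
expectation.  Each endpoint is sampled from its subgraph's *motif pool* —
the motif nodes plus their direct neighbors — with weight
degree<sup>2</sup> × 0.3<sup>[motif node]</sup>, preferring nodes that still
have fewer than `K` motifs in their closed 1-hop neighborhood whenever any
such node remains.  A bridge endpoint whose partner endpoint is an actual
motif node thereby acquires a second motif in its neighborhood.

The degree-squared kernel and the motif down-weight 0.3 are the two
calibration constants of the reconstruction.  They were fixed once so that
the `SG-Base` and `SG-SmallEx` presets jointly land on the published scale —
≈13,150 / ≈15,505 nodes, ≈46,500 / ≈51,800 directed edges, average degree
≈3.53 / ≈3.34, and a ⅓ / ½ class split — and are deliberately not exposed as
user parameters.

### Labels

With **S** the set of planted motifs and 𝒩<sub>v</sub> the closed 1-hop
neighborhood of `v`,

    f(v) = |{ S_i ∈ S : V_{S_i} ∩ 𝒩_v ≠ ∅ }| − 1,  clipped to {0..K−1}.

The closed neighborhood (including `v` itself) makes every motif member
count its own motif.  Nodes attached more than one hop away from their
subgraph's motif see zero motifs and take class 0 — the same class as
plain single-motif nodes.  This is a known, documented departure from the
idealized description in which *every* node has between 1 and K motifs in
its neighborhood: enforcing that property would require attaching every
grown node directly to a motif node, which collapses subgraphs into stars
and destroys both the degree distribution and the published class balance.
In practice 5–8% of nodes are such zero-count nodes.

### Node features

Feature columns `0..n_i−1` are informative, `n_i..n_f−2` redundant, and
`n_f−1` is the protected attribute.

* **Informative** (latent hypercube cluster model): `K·c_f` centroids are
  placed at distinct, randomly chosen vertices of `{−s_f, +s_f}^{n_i}`;
  each class owns `c_f` of them.  A node picks one of its class's centroids
  uniformly and adds unit Gaussian noise.  Larger `s_f` separates the
  classes; with `c_f ≥ 2` the class regions need not be linearly separable.
* **Protected**: binarized label (`label > 0`) XOR Bernoulli(φ).  The
  empirical correlation with the binarized label is `1 − 2φ` (recovered to
  ±0.05 at the default graph size by the test suite).  The binarization rule
  extends the construction to `K > 2`, where the flip semantics are
  otherwise undefined.
* **Redundant**: standard normal, then one synchronous homophily pass

      x_r(v) ← unit( x_r(v) + η · mean_{u ∈ N(v)} x_r(u) ),

  leaving isolated nodes untouched.  η > 0 aligns adjacent nodes' features,
  η < 0 anti-aligns them; a single pass suffices to produce a measurable
  neighbor-cosine gap between η = +1 and η = −1, which is what the
  benchmark varies.  Only the redundant block is modified, so homophily can
  be controlled without touching the label-generating signal.

### Ground-truth explanations

For node `v`, masks live on the enclosing subgraph Sub(v; L) — the induced
subgraph on all nodes within `L` hops (the receptive field of an `L`-layer
message-passing model).  Local node order is ascending parent id; the edge
list is the sorted canonical undirected pairs.  The ground-truth set ζ
contains **one mask triple per motif** intersecting Sub(v; L):

* node mask: membership indicator of that motif's nodes;
* feature mask: indicator of the informative columns (protected and
  redundant columns are 0);
* edge mask: 1 for edges with both endpoints in the motif ∪ {v}, else 0.

Enumerating motifs separately (rather than taking their union) treats each
motif as an independently valid rationale, exactly as multiple benzene rings
each constitute a valid explanation of a benzene-containing molecule.  The
evaluation metric takes the best match over ζ, so an explainer is never
penalized for committing to one of several equally correct answers.  Under
the union reading, the random-baseline accuracy on `SG-Base` roughly doubles
and is incompatible with the published baseline level; the per-motif reading
reproduces it (see `tests/test_acceptance.py`).

Ground truth is computed lazily per node and cached; it is a pure function
of the graph, so laziness is observationally equivalent to eager
construction and keeps generation of 13k-node instances under a second.

## Parameters

| symbol | name                 | default (SG-Base) | meaning                                        |
| ------ | -------------------- | ----------------- | ---------------------------------------------- |
| S      | `motif_shape`        | house             | planted motif (structural ground truth)        |
| N_s    | `num_subgraphs`      | 1200              | subgraphs grown                                |
| p      | `connection_prob`    | 0.006             | bridge probability per ordered subgraph pair   |
| n_s    | `subgraph_size`      | 11                | expected nodes per subgraph (⇒ ≈ N_s·n_s total)|
| K      | `num_classes`        | 2                 | classes; label = motif count − 1, clipped      |
| n_f    | `num_features`       | 11                | feature dimensionality                         |
| n_i    | `num_informative`    | 4                 | informative columns (= feature ground truth)   |
| s_f    | `class_sep`          | 0.6               | hypercube half-width; higher ⇒ easier task     |
| c_f    | `clusters_per_class` | 2                 | centroids per class; higher ⇒ harder task      |
| φ      | `protected_noise`    | 0.5               | protected-label flip prob.; corr = 1 − 2φ      |
| η      | `homophily`          | 1                 | sign/strength of neighbor feature alignment    |
| L      | `gnn_layers`         | 3                 | receptive field ⇒ explanation subgraph radius  |
| m      | `attach_edges`       | 1                 | edges per grown node                           |

Presets: `SG-Heterophilic` (η = −1), `SG-SmallEx` (triangle, N_s = 1300,
n_s = 12, s_f = 0.5), `SG-Unfair` (φ = 0.75), `SG-MoreInform` (n_i = 8),
`SG-LessInform` (n_f = 21).  The SG-SmallEx subgraph count follows the
published statistics table (1300 × 12 ≈ the printed 15,505 nodes).

Splits are 70/5/25 train/val/test, stratified by class with the dataset
seed; stratification stabilizes metrics on the minority class.

## Predictor and explainers

The predictor is an `L`-layer numpy message-passing network: `gin_like`
layers compute `H ← ReLU((A + I) H W + b)` (sum aggregation with ε = 0 and a
one-layer MLP), `gcn_like` layers use `D^{−1/2}(A + I)D^{−1/2}` aggregation;
a linear softmax head maps the final embedding to class probabilities.
Training is full-batch Adam on the train-split cross-entropy — GIN protocol:
lr 1e-2, weight decay 1e-5, 1000 epochs; GCN protocol: lr 3e-2, no decay,
1500 epochs — with no early stopping.  Forward and backward passes are
exact, so the gradient explainer's saliency |∂ logit_ŷ / ∂X| is analytic
(differentiating the predicted-class logit, the standard saliency
convention); the tests verify it against central finite differences.
Because an intact Sub(v; L) is the model's whole receptive field, predicting
on the subgraph equals predicting on the full graph — masked subgraphs are
where the two diverge, which is precisely what the faithfulness metric
measures.

Baseline explainers: uniform(0,1) node/edge scores and a Gaussian
feature-score vector (`random_explainer`), and vanilla-gradient saliency
(`gradient_explainer`; node scores are row sums, feature scores column sums,
edge scores the mean of the endpoint scores).

## Metrics: numerical choices

* **Top-k binarization** keeps `ceil(k·n)` entries; ties break toward the
  lowest index (deterministic).
* **Jaccard** of two all-zero masks is defined as 1 (vacuous agreement
  avoids 0/0).
* **GEF** uses KL(f(S_u) ‖ f(S_u′)) in that order; probabilities are floored
  at `kl_epsilon = 1e-12` and renormalized so point-mass predictions cannot
  produce infinite divergence.  GEF < 1 for any finite divergence.
* **GES** perturbations: Gaussian feature noise scaled by 0.01 × per-column
  std and per-edge rewiring with probability 0.001 (coin flip between
  deleting the edge and keeping it while adding one random absent edge);
  25 samples.  The behavior ball uses the ℓ2 norm of the logit shift; with
  `delta = None` the threshold is calibrated to the 95th percentile of the
  observed shifts.  An empty ball yields GES = 0 and a zero-norm mask yields
  distance 1; both are logged, never silent.
* **GES/GECF distances** are computed on soft scores: cosine distance on
  binarized masks is degenerate for very sparse masks.
* **GEGF** re-predicts each node from its own explanation masked at the same
  top-k fraction and compares statistical parity over the evaluated node
  set.

## What the generator does and does not emulate

The synthetic graphs reproduce heavy-tailed degrees, controllable
homophily/heterophily, a protected attribute with tunable label correlation,
non-unique ground-truth rationales, and a mixture of structural and feature
signal.  They do **not** emulate: feature distributions of real molecular or
tabular data (features are Gaussian/hypercube by construction), edge
attributes, degree-correlated features, multiple motif shapes within one
graph, or label noise.  Passing metrics here therefore certifies an
explainer's behavior under a known, clean generative process — not its
performance on any particular real-world dataset.

## Known limitations

* The inter-subgraph wiring rule and the attachment kernel are
  reconstructions calibrated to the published summary statistics; other
  rules could match the same marginals.
* Zero-motif-count nodes (above) mean the "every node sees ≥1 motif"
  idealization holds only approximately.
* The counterfactual-fairness separation between `SG-Unfair` and `SG-Base`
  is robust on the feature channel of the gradient explainer (where the
  protected column lives) but is within noise on the node channel; the test
  suite asserts the feature-channel comparison.
* The stability metric's δ-ball depends on the predictor's logit scale;
  cross-model GES comparisons should use a common calibration sample.

## Problem sizes used in the test suite

Full-scale presets (≈13k–15k nodes) are used where the published statistics
are checked (5 seeds), for the random-explainer accuracy (3 seeds, all test
nodes) and for the fairness separation (2 trained models, 150 test nodes
each).  Module-level tests run on 20–100-subgraph instances with a raised
connection probability (bridge counts scale with N_s², so small instances
need a larger `p` to populate class 1), and brute-force oracles run on
~200-node graphs where exhaustive recomputation is instant.
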