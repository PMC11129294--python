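"""Message-passing network over molecular graphs.

One round of message passing does three things: an *edge update* maps each
directed edge's endpoint embeddings (h_u, h_v) through a feed-forward layer to
a message; a *neighborhood aggregation* pools the messages arriving at each
node with an index-invariant operator (sum or mean); a *node update* combines
the node's current embedding with the pooled messages through another
feed-forward layer. After K rounds every atom carries a continuous embedding
of its K-hop chemical environment — a learned, differentiable replacement for
discrete atom types. Because aggregation is index-invariant the whole scheme
is permutation-equivariant: relabeling atoms permutes the output rows the
same way.

Everything here is plain NumPy in double precision; the matching gradients
live in :mod:`qeqnet.model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .chem import BatchedGraph, MolGraph
from .errors import DimensionError, NumericalError

AGGREGATIONS = ("sum", "mean")
ACTIVATIONS = ("tanh", "relu")


@dataclass(frozen=True)
class GNNConfig:
    """Architecture hyperparameters (held out of the code: they were tuned,
    not derived).

    n_layers      number of message-passing rounds K (receptive field = K hops)
    hidden_dim    node/edge embedding width D
    aggregation   'sum' or 'mean' (both index-invariant)
    activation    elementwise nonlinearity of the update networks
    share_weights reuse one (edge, node) layer pair across all K rounds
    """

    n_layers: int = 3
    hidden_dim: int = 128
    aggregation: str = "sum"
    activation: str = "tanh"
    share_weights: bool = False

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "hidden_dim": self.hidden_dim,
            "aggregation": self.aggregation,
            "activation": self.activation,
            "share_weights": self.share_weights,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GNNConfig":
        return cls(**d)


def activation_fn(name: str):
    if name == "tanh":
        return np.tanh
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    raise ValueError(name)


def activation_grad(name: str, out: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """d activation / d pre-activation, expressed via cached values."""
    if name == "tanh":
        return 1.0 - out * out
    if name == "relu":
        return (pre > 0.0).astype(pre.dtype)
    raise ValueError(name)


@dataclass
class GNNParams:
    """Weights of the message-passing stack plus its input projection.

    ``weights`` maps parameter names to arrays:
      proj_W (F, D), proj_b (D)
      edge{k}_W (2D, D), edge{k}_b (D)   -- edge-update network, layer k
      node{k}_W (2D, D), node{k}_b (D)   -- node-update network, layer k
    With ``share_weights`` only layer 0 exists and is reused.
    """

    config: GNNConfig
    in_dim: int
    weights: dict[str, np.ndarray]

    def layer_names(self, k: int) -> tuple[str, str, str, str]:
        kk = 0 if self.config.share_weights else k
        return (f"edge{kk}_W", f"edge{kk}_b", f"node{kk}_W", f"node{kk}_b")


def init_gnn_params(
    in_dim: int, config: GNNConfig | None = None, rng: np.random.Generator | None = None
) -> GNNParams:
    """Fan-in-scaled random initialization from a seeded generator."""
    config = config or GNNConfig()
    rng = rng or np.random.default_rng(0)
    d = config.hidden_dim

    def lin(n_in: int, n_out: int) -> np.ndarray:
        return rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))

    w: dict[str, np.ndarray] = {
        "proj_W": lin(in_dim, d),
        "proj_b": np.zeros(d),
    }
    n_layer_blocks = 1 if config.share_weights else config.n_layers
    for k in range(n_layer_blocks):
        w[f"edge{k}_W"] = lin(2 * d, d)
        w[f"edge{k}_b"] = np.zeros(d)
        w[f"node{k}_W"] = lin(2 * d, d)
        w[f"node{k}_b"] = np.zeros(d)
    return GNNParams(config=config, in_dim=in_dim, weights=w)


def edge_update(
    h_u: np.ndarray, h_v: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "tanh"
) -> np.ndarray:
    """Message for the directed edge u -> v: phi_e([h_u, h_v]).

    Deterministic in its inputs; the concatenation order makes the two
    directions of a bond distinct in general.
    """
    h_u = np.atleast_2d(h_u)
    h_v = np.atleast_2d(h_v)
    if h_u.shape != h_v.shape or 2 * h_u.shape[1] != W.shape[0]:
        raise DimensionError(
            f"edge_update: embeddings {h_u.shape}/{h_v.shape} vs weight {W.shape}"
        )
    z = np.concatenate([h_u, h_v], axis=1) @ W + b
    return np.squeeze(activation_fn(activation)(z))


def scatter_sum(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Row-wise segment sum: out[k] = sum of values[i] with idx[i] == k.

    Implemented with a flattened bincount, which is markedly faster than
    ``np.add.at`` for the edge counts molecular graphs produce.
    """
    values = np.atleast_2d(values)
    d = values.shape[1]
    if values.shape[0] == 0:
        return np.zeros((n, d))
    flat_idx = (idx[:, None] * d + np.arange(d)[None, :]).ravel()
    return np.bincount(flat_idx, weights=values.ravel(), minlength=n * d).reshape(n, d)


def aggregate_neighbors(
    messages: np.ndarray,
    dst: np.ndarray,
    num_nodes: int,
    aggregation: str = "sum",
) -> np.ndarray:
    """Pool incoming edge messages per destination node.

    Invariant to any reordering of the incident-edge multiset. MEAN over an
    empty neighborhood is defined as the zero vector so isolated atoms
    (monatomic ions) pass through without special-casing.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    out = scatter_sum(np.atleast_2d(messages), dst, num_nodes)
    if aggregation == "mean" and messages.size:
        counts = np.bincount(dst, minlength=num_nodes).astype(np.float64)
        out /= np.maximum(counts, 1.0)[:, None]
    return out


def node_update(
    h_v: np.ndarray, a_v: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "tanh"
) -> np.ndarray:
    """Next-layer embedding: phi_v([h_v, a_v])."""
    h_v = np.atleast_2d(h_v)
    a_v = np.atleast_2d(a_v)
    if h_v.shape != a_v.shape or 2 * h_v.shape[1] != W.shape[0]:
        raise DimensionError(
            f"node_update: embeddings {h_v.shape}/{a_v.shape} vs weight {W.shape}"
        )
    z = np.concatenate([h_v, a_v], axis=1) @ W + b
    return np.squeeze(activation_fn(activation)(z))


Graph = Union[MolGraph, BatchedGraph]


def embed(graph: Graph, params: GNNParams, _cache: list | None = None) -> np.ndarray:
    """K rounds of message passing; returns the N x D embedding matrix.

    Works identically on a single graph and on a block-diagonal batch: since
    messages only travel along edges and no edge crosses a molecule boundary,
    batched embeddings equal the concatenation of per-molecule embeddings.

    ``_cache``, if supplied, collects intermediates for backpropagation.
    """
    x = graph.node_features
    if x.shape[1] != params.in_dim:
        raise DimensionError(
            f"graph feature width {x.shape[1]} != model input width {params.in_dim}"
        )
    cfg = params.config
    act = activation_fn(cfg.activation)
    w = params.weights
    src = graph.edges[:, 0]
    dst = graph.edges[:, 1]
    n = graph.num_nodes

    h = x.astype(np.float64) @ w["proj_W"] + w["proj_b"]
    if _cache is not None:
        _cache.append(("input", x, h))
    d = cfg.hidden_dim
    for k in range(cfg.n_layers):
        we, be, wn, bn = params.layer_names(k)
        h_in = h
        # [h_src, h_dst] @ W computed as two half-matmuls: avoids building the
        # (n_edges, 2D) concatenation, which dominates memory traffic on
        # large batches
        hw_src = h_in @ w[we][:d]
        hw_dst = h_in @ w[we][d:]
        z_e = hw_src[src] + hw_dst[dst] + w[be]
        m = act(z_e)
        a = aggregate_neighbors(m, dst, n, cfg.aggregation)
        z_n = h_in @ w[wn][:d] + a @ w[wn][d:] + w[bn]
        h = act(z_n)
        if _cache is not None:
            _cache.append(("layer", k, h_in, z_e, m, a, z_n, h))
    if not np.all(np.isfinite(h)):
        raise NumericalError("non-finite embedding produced by message passing")
    return h
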