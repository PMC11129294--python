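"""End-to-end charge model: featurize -> message passing -> (e, s) -> QEq.

A :class:`ChargeModel` bundles a featurization scheme, a message-passing
stack, and two small feed-forward readout heads that map each atom's final
embedding to an unconstrained electronegativity e_i and a hardness s_i. The
hardness head output passes through a softplus (plus a small floor), which
keeps s_i strictly positive and the equilibration problem strictly convex.
The analytic equilibration step then converts (e, s, Q) to partial charges
that satisfy the total-charge constraint exactly, per molecule, even inside a
block-diagonal batch.

The model is a pure NumPy computation. ``loss_and_grad`` implements
reverse-mode differentiation of the squared charge loss through the full
pipeline — including the closed-form equilibration — and is checked against
finite differences in the test suite.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .chem import (
    BatchedGraph,
    FeaturizationConfig,
    MolGraph,
    Molecule,
    batch_graphs,
    build_graph,
    total_formal_charge,
    unbatch,
)
from .errors import CheckpointError, NumericalError, QeqnetError
from .gnn import GNNConfig, GNNParams, activation_grad, embed, init_gnn_params, scatter_sum
from .qeq import (
    ChargeParams,
    ChargeResult,
    charging_energy,
    qeq_backward_from_solution,
    qeq_solve_batch,
)

CHECKPOINT_FORMAT = "qeqnet-checkpoint"
CHECKPOINT_VERSION = 1

#: additive floor under softplus; keeps hardness clear of the convexity guard.
S_FLOOR = 1e-4


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AssignmentFailure:
    """Per-record failure marker returned when a batch runs with on_error='record'."""

    name: str
    error: str


Assignment = Union[ChargeResult, AssignmentFailure]


class ChargeModel:
    """Featurization scheme + GNN + readout heads, with (de)serialization."""

    def __init__(
        self,
        gnn: GNNParams,
        head_weights: dict[str, np.ndarray],
        feature_config: FeaturizationConfig,
        head_hidden: int,
    ):
        self.gnn = gnn
        self.head_weights = head_weights
        self.feature_config = feature_config
        self.head_hidden = head_hidden

    # ------------------------------------------------------------------ setup
    @classmethod
    def initialize(
        cls,
        seed: int = 0,
        feature_config: FeaturizationConfig | None = None,
        gnn_config: GNNConfig | None = None,
        head_hidden: int = 64,
    ) -> "ChargeModel":
        """Fresh model with fan-in-scaled random weights from a seeded generator."""
        feature_config = feature_config or FeaturizationConfig()
        gnn_config = gnn_config or GNNConfig()
        rng = np.random.default_rng(seed)
        gnn = init_gnn_params(feature_config.n_features, gnn_config, rng)
        d = gnn_config.hidden_dim

        def lin(n_in, n_out):
            return rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))

        heads = {
            "e_W1": lin(d, head_hidden),
            "e_b1": np.zeros(head_hidden),
            "e_w2": lin(head_hidden, 1)[:, 0],
            "e_b2": np.zeros(1),
            "s_W1": lin(d, head_hidden),
            "s_b1": np.zeros(head_hidden),
            "s_w2": lin(head_hidden, 1)[:, 0],
            # softplus(1) ~ 1.31: start hardness near unity, not near zero
            "s_b2": np.ones(1),
        }
        return cls(gnn, heads, feature_config, head_hidden)

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        """Flat view of all learnable arrays (gnn.* and head.* namespaced)."""
        out = {f"gnn.{k}": v for k, v in self.gnn.weights.items()}
        out.update({f"head.{k}": v for k, v in self.head_weights.items()})
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            scope, name = k.split(".", 1)
            target = self.gnn.weights if scope == "gnn" else self.head_weights
            target[name] = np.asarray(v, dtype=np.float64)

    def copy(self) -> "ChargeModel":
        m = ChargeModel(
            GNNParams(self.gnn.config, self.gnn.in_dim, copy.deepcopy(self.gnn.weights)),
            copy.deepcopy(self.head_weights),
            self.feature_config,
            self.head_hidden,
        )
        return m

    # ------------------------------------------------------------ computation
    def embed(self, graph) -> np.ndarray:
        return embed(graph, self.gnn)

    def predict_e_s(
        self, embeddings: np.ndarray, _cache: dict | None = None
    ) -> ChargeParams:
        """Per-atom readout heads: e unconstrained, s = softplus(raw) + floor.

        Identical embeddings give identical (e, s) pairs, so topologically
        equivalent atoms get identical parameters and hence identical charges.
        """
        h = np.asarray(embeddings, dtype=np.float64)
        w = self.head_weights
        ge_pre = h @ w["e_W1"] + w["e_b1"]
        ge = np.tanh(ge_pre)
        e = ge @ w["e_w2"] + w["e_b2"][0]
        gs_pre = h @ w["s_W1"] + w["s_b1"]
        gs = np.tanh(gs_pre)
        s_raw = gs @ w["s_w2"] + w["s_b2"][0]
        s = _softplus(s_raw) + S_FLOOR
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(s))):
            raise NumericalError("non-finite electronegativity/hardness from readout")
        if _cache is not None:
            _cache.update(ge=ge, gs=gs, s_raw=s_raw)
        return ChargeParams(e=e, s=s)

    def charges_for_batch(self, batched: BatchedGraph) -> np.ndarray:
        """Charges for every atom of a batch, constraint applied per molecule."""
        h = self.embed(batched)
        cp = self.predict_e_s(h)
        return qeq_solve_batch(cp.e, cp.s, batched.total_charges, batched.segment_ids)

    # ---------------------------------------------------------- training loss
    def loss_and_grad(
        self,
        batched: BatchedGraph,
        ref_charges: np.ndarray,
    ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
        """Squared charge loss and its gradient w.r.t. every parameter.

        Loss = sum over atoms of (q_i - q_i^ref)^2, summed across the batch.
        Returns (loss, grads keyed like ``parameters``, predicted charges).
        """
        cfg = self.gnn.config
        w = self.gnn.weights
        hw = self.head_weights
        src = batched.edges[:, 0]
        dst = batched.edges[:, 1]
        n = batched.num_nodes

        cache: list = []
        h = embed(batched, self.gnn, _cache=cache)
        head_cache: dict = {}
        cp = self.predict_e_s(h, _cache=head_cache)
        q = qeq_solve_batch(cp.e, cp.s, batched.total_charges, batched.segment_ids)

        ref = np.asarray(ref_charges, dtype=np.float64)
        resid = q - ref
        loss = float(np.sum(resid * resid))

        grads: dict[str, np.ndarray] = {}
        g_q = 2.0 * resid
        de, ds = qeq_backward_from_solution(cp.e, cp.s, q, batched.segment_ids, g_q)

        ge, gs, s_raw = head_cache["ge"], head_cache["gs"], head_cache["s_raw"]
        ds_raw = ds * _sigmoid(s_raw)
        # e head
        grads["head.e_w2"] = ge.T @ de
        grads["head.e_b2"] = np.array([np.sum(de)])
        d_ge = np.outer(de, hw["e_w2"]) * (1.0 - ge * ge)
        grads["head.e_W1"] = h.T @ d_ge
        grads["head.e_b1"] = d_ge.sum(axis=0)
        dh = d_ge @ hw["e_W1"].T
        # s head
        grads["head.s_w2"] = gs.T @ ds_raw
        grads["head.s_b2"] = np.array([np.sum(ds_raw)])
        d_gs = np.outer(ds_raw, hw["s_w2"]) * (1.0 - gs * gs)
        grads["head.s_W1"] = h.T @ d_gs
        grads["head.s_b1"] = d_gs.sum(axis=0)
        dh = dh + d_gs @ hw["s_W1"].T

        # message-passing layers, reversed; weight blocks handled separately so
        # no (n_edges, 2D) concatenation is ever materialized
        d = cfg.hidden_dim
        layer_caches = [c for c in cache if c[0] == "layer"]
        _, x_in, _h0 = cache[0]
        for entry in reversed(layer_caches):
            _, k, h_in, z_e, m, a, z_n, h_out = entry
            we, be, wn, bn = self.gnn.layer_names(k)
            d_zn = dh * activation_grad(cfg.activation, h_out, z_n)
            grads[f"gnn.{wn}"] = grads.get(f"gnn.{wn}", 0) + np.vstack(
                [h_in.T @ d_zn, a.T @ d_zn]
            )
            grads[f"gnn.{bn}"] = grads.get(f"gnn.{bn}", 0) + d_zn.sum(axis=0)
            d_hin = d_zn @ w[wn][:d].T
            d_a = d_zn @ w[wn][d:].T
            if cfg.aggregation == "mean":
                counts = np.bincount(dst, minlength=n).astype(np.float64)
                d_m = (d_a / np.maximum(counts, 1.0)[:, None])[dst]
            else:
                d_m = d_a[dst]
            d_ze = d_m * activation_grad(cfg.activation, m, z_e)
            src_scat = scatter_sum(d_ze, src, n)
            dst_scat = scatter_sum(d_ze, dst, n)
            grads[f"gnn.{we}"] = grads.get(f"gnn.{we}", 0) + np.vstack(
                [h_in.T @ src_scat, h_in.T @ dst_scat]
            )
            grads[f"gnn.{be}"] = grads.get(f"gnn.{be}", 0) + d_ze.sum(axis=0)
            d_hin += src_scat @ w[we][:d].T + dst_scat @ w[we][d:].T
            dh = d_hin
        grads["gnn.proj_W"] = x_in.astype(np.float64).T @ dh
        grads["gnn.proj_b"] = dh.sum(axis=0)
        return loss, grads, q

    # ---------------------------------------------------------- serialization
    def save(self, path: str) -> None:
        """Write a versioned JSON checkpoint (atomically)."""
        payload = {
            "format": CHECKPOINT_FORMAT,
            "version": CHECKPOINT_VERSION,
            "feature_config": self.feature_config.to_dict(),
            "gnn_config": self.gnn.config.to_dict(),
            "head_hidden": self.head_hidden,
            "gnn_weights": {k: v.tolist() for k, v in self.gnn.weights.items()},
            "head_weights": {k: v.tolist() for k, v in self.head_weights.items()},
        }
        tmp = f"{path}.tmp.{os.getpid()}"
        with open(tmp, "w") as fh:
            json.dump(payload, fh)
        os.replace(tmp, path)

    @classmethod
    def load(
        cls, path: str, expected_feature_version: str | None = None
    ) -> "ChargeModel":
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise CheckpointError(f"cannot read checkpoint {path!r}: {exc}") from exc
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise CheckpointError(f"{path!r} is not a charge-model checkpoint")
        fc = FeaturizationConfig.from_dict(payload["feature_config"])
        expected = expected_feature_version or FeaturizationConfig().version
        if fc.version != expected:
            raise CheckpointError(
                f"checkpoint featurization version {fc.version!r} does not match "
                f"expected {expected!r}; refusing to assign charges with "
                "mismatched features"
            )
        gcfg = GNNConfig.from_dict(payload["gnn_config"])
        gw = {k: np.asarray(v, dtype=np.float64) for k, v in payload["gnn_weights"].items()}
        hw = {k: np.asarray(v, dtype=np.float64) for k, v in payload["head_weights"].items()}
        gnn = GNNParams(config=gcfg, in_dim=fc.n_features, weights=gw)
        return cls(gnn, hw, fc, int(payload["head_hidden"]))


#: soft cap on atoms per sub-batch: large enough to amortize per-call
#: overhead, small enough that the working set stays cache-resident.
MAX_BATCH_ATOMS = 1024


def _chunk_spans(node_counts: Sequence[int], batch_size: int, max_atoms: int):
    """Split molecule indices into contiguous sub-batches.

    A sub-batch closes when it reaches ``batch_size`` molecules or would
    exceed ``max_atoms`` total atoms (a single oversized molecule still gets
    its own sub-batch).
    """
    spans: list[tuple[int, int]] = []
    start = 0
    atoms = 0
    for i, c in enumerate(node_counts):
        if i > start and (i - start >= batch_size or atoms + c > max_atoms):
            spans.append((start, i))
            start = i
            atoms = 0
        atoms += c
    if start < len(node_counts):
        spans.append((start, len(node_counts)))
    return spans


def assign_charges(
    mols: Union[Molecule, Sequence[Molecule]],
    model: ChargeModel,
    *,
    batch_size: int = 64,
    max_batch_atoms: int = MAX_BATCH_ATOMS,
    on_error: str = "raise",
) -> list[Assignment]:
    """Assign partial charges to one molecule or a sequence of molecules.

    Molecules are featurized, batched block-diagonally in sub-batches of up
    to ``batch_size`` molecules and roughly ``max_batch_atoms`` atoms,
    embedded, read out to (e, s), and equilibrated with each molecule's own
    total-charge constraint. Batched results are identical to sequential
    per-molecule calls (up to floating-point association).

    With ``on_error='record'`` a molecule that fails (out-of-vocabulary
    element, numerical problem) yields an :class:`AssignmentFailure` in its
    slot instead of aborting the whole batch.
    """
    if on_error not in ("raise", "record"):
        raise ValueError("on_error must be 'raise' or 'record'")
    single = isinstance(mols, Molecule)
    mol_list = [mols] if single else list(mols)
    results: list[Assignment] = [None] * len(mol_list)  # type: ignore[list-item]

    graphs: list[MolGraph] = []
    charges: list[float] = []
    indices: list[int] = []
    for idx, mol in enumerate(mol_list):
        try:
            graphs.append(build_graph(mol, model.feature_config))
            charges.append(float(total_formal_charge(mol)))
            indices.append(idx)
        except QeqnetError as exc:
            if on_error == "raise":
                raise
            results[idx] = AssignmentFailure(name=mol.name, error=str(exc))

    spans = _chunk_spans(
        [g.num_nodes for g in graphs], max(1, batch_size), max_batch_atoms
    )
    for start, stop in spans:
        chunk = slice(start, stop)
        batched = batch_graphs(graphs[chunk], charges[chunk])
        try:
            cp = model.predict_e_s(model.embed(batched))
            q_all = qeq_solve_batch(
                cp.e, cp.s, batched.total_charges, batched.segment_ids
            )
        except QeqnetError as exc:
            if on_error == "raise":
                raise
            for idx in indices[chunk]:
                results[idx] = AssignmentFailure(name=mol_list[idx].name, error=str(exc))
            continue
        q_parts = unbatch(batched, q_all)
        e_parts = unbatch(batched, cp.e)
        s_parts = unbatch(batched, cp.s)
        for j, idx in enumerate(indices[chunk]):
            results[idx] = ChargeResult(
                q=q_parts[j],
                Q=charges[start + j],
                energy=charging_energy(e_parts[j], s_parts[j], q_parts[j]),
                name=mol_list[idx].name,
            )
    return results
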