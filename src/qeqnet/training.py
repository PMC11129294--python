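"""Fitting the charge model to reference charges and evaluating it.

Training minimizes a squared loss on per-atom charges — summed over atoms and
molecules, not averaged — with Adam, molecule-disjoint 80/10/10 splits, early
stopping on validation loss, and the best-validation checkpoint returned.
Because the constraint layer is inside the model, every prediction during
training already conserves total charge; the loss only has to shape how charge
is distributed.

Evaluation follows the conventions of charge-model benchmarking: the
per-molecule RMSE over atoms, its unweighted mean over molecules, a bootstrap
(over molecules, with replacement) percentile confidence interval of that
mean, and stratified tables by total molecular charge and by molecule size,
with per-bin molecule counts — accuracy of charge surrogates is strongly tied
to how well a region of chemical space is represented in training data, and
the stratified view makes that visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import Molecule, build_graph, batch_graphs, total_formal_charge
from .errors import DimensionError, EmptyMoleculeError, TrainingDivergedError
from .gnn import GNNConfig
from .model import ChargeModel, assign_charges
from .qeq import qeq_solve_batch

SPLITS = ("train", "val", "test")


@dataclass
class ChargeDataset:
    """(Molecule, reference charge vector) records with split labels.

    Reference vectors must match atom counts and sum to the molecule's
    integer total charge within 0.01 (tolerance for upstream rounding).
    """

    molecules: list[Molecule]
    charges: list[np.ndarray]
    split: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.molecules) != len(self.charges):
            raise DimensionError("molecules and charge vectors differ in count")
        self.charges = [np.asarray(c, dtype=np.float64) for c in self.charges]
        for mol, ref in zip(self.molecules, self.charges):
            if len(ref) != mol.num_atoms:
                raise DimensionError(
                    f"molecule {mol.name!r}: {len(ref)} reference charges for "
                    f"{mol.num_atoms} atoms"
                )
            q = total_formal_charge(mol)
            if abs(float(ref.sum()) - q) > 0.01:
                raise ValueError(
                    f"molecule {mol.name!r}: reference charges sum to "
                    f"{ref.sum():.4f}, formal charge is {q}"
                )
        if self.split is not None and len(self.split) != len(self.molecules):
            raise DimensionError("split labels differ in count from molecules")

    def __len__(self) -> int:
        return len(self.molecules)

    def subset(self, label: str) -> "ChargeDataset":
        if self.split is None:
            raise ValueError("dataset has no split labels")
        idx = [i for i, s in enumerate(self.split) if s == label]
        return ChargeDataset(
            molecules=[self.molecules[i] for i in idx],
            charges=[self.charges[i] for i in idx],
            split=[label] * len(idx),
        )

    def with_random_split(
        self, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
    ) -> "ChargeDataset":
        """Assign disjoint train/val/test labels by seeded shuffle of molecules."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        n = len(self)
        order = np.random.default_rng(seed).permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        labels = [""] * n
        for rank, i in enumerate(order):
            if rank < n_train:
                labels[i] = "train"
            elif rank < n_train + n_val:
                labels[i] = "val"
            else:
                labels[i] = "test"
        return ChargeDataset(self.molecules, self.charges, labels)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. These were tuned, not derived — change freely."""

    epochs: int = 200
    learning_rate: float = 5e-3
    batch_size: int = 64
    seed: int = 0
    optimizer: str = "adam"
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    patience: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainResult:
    model: ChargeModel
    history: pd.DataFrame
    best_epoch: int
    dataset: ChargeDataset | None = None  # with the split labels actually used


def squared_loss(pred: np.ndarray, ref: np.ndarray) -> float:
    """Sum over atoms of squared charge residuals (no mean normalization)."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise DimensionError(f"pred {pred.shape} vs ref {ref.shape}")
    d = pred - ref
    return float(np.sum(d * d))


def charge_rmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square charge deviation over the atoms of one molecule."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise DimensionError(f"pred {pred.shape} vs ref {ref.shape}")
    if pred.size == 0:
        raise EmptyMoleculeError("RMSE of an empty molecule is undefined")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def bootstrap_ci(
    values: Sequence[float], n_boot: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling molecules with replacement."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise EmptyMoleculeError("bootstrap over an empty value list")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _prepare_batches(
    dataset: ChargeDataset, model: ChargeModel, batch_size: int
) -> list[tuple]:
    """Pre-build (BatchedGraph, concatenated reference charges) minibatches."""
    graphs = [build_graph(m, model.feature_config) for m in dataset.molecules]
    qs = [float(total_formal_charge(m)) for m in dataset.molecules]
    batches = []
    for start in range(0, len(graphs), batch_size):
        sl = slice(start, start + batch_size)
        batched = batch_graphs(graphs[sl], qs[sl])
        refs = np.concatenate(dataset.charges[sl])
        batches.append((batched, refs))
    return batches


def train(
    dataset: ChargeDataset,
    config: TrainConfig | None = None,
    model: ChargeModel | None = None,
    gnn_config: GNNConfig | None = None,
) -> TrainResult:
    """Fit the model; returns the checkpoint with the best validation loss.

    Fully deterministic given the seed: parameter initialization, splits and
    minibatch shuffling all derive from ``config.seed``. With ``epochs == 0``
    the initialized model is returned untouched with an empty history.
    """
    config = config or TrainConfig()
    if dataset.split is None:
        dataset = dataset.with_random_split(config.split_fractions, config.seed)
    train_set = dataset.subset("train")
    val_set = dataset.subset("val")
    if len(train_set) == 0:
        raise ValueError("empty training split")
    if model is None:
        model = ChargeModel.initialize(seed=config.seed, gnn_config=gnn_config)

    history: list[dict] = []
    if config.epochs == 0:
        return TrainResult(model, pd.DataFrame(history), best_epoch=-1, dataset=dataset)

    rng = np.random.default_rng(config.seed + 1)
    train_batches = _prepare_batches(train_set, model, config.batch_size)
    val_batches = _prepare_batches(val_set, model, config.batch_size) if len(val_set) else []

    params = {k: v.copy() for k, v in model.parameters.items()}
    model.set_parameters(params)
    m1 = {k: np.zeros_like(v) for k, v in params.items()}
    m2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_batches))
        train_loss = 0.0
        for bi in order:
            batched, refs = train_batches[bi]
            loss, grads, _ = model.loss_and_grad(batched, refs)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            train_loss += loss
            step += 1
            for k in params:
                g = grads[k]
                if config.optimizer == "adam":
                    m1[k] = beta1 * m1[k] + (1 - beta1) * g
                    m2[k] = beta2 * m2[k] + (1 - beta2) * g * g
                    mhat = m1[k] / (1 - beta1**step)
                    vhat = m2[k] / (1 - beta2**step)
                    params[k] = params[k] - config.learning_rate * mhat / (
                        np.sqrt(vhat) + eps
                    )
                else:
                    params[k] = params[k] - config.learning_rate * g
            model.set_parameters(params)

        if val_batches:
            val_loss = 0.0
            for batched, refs in val_batches:
                cp = model.predict_e_s(model.embed(batched))
                q = qeq_solve_batch(cp.e, cp.s, batched.total_charges, batched.segment_ids)
                val_loss += squared_loss(q, refs)
            if not np.isfinite(val_loss):
                raise TrainingDivergedError(epoch)
        else:
            val_loss = train_loss
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break

    model.set_parameters(best_params)
    return TrainResult(model, pd.DataFrame(history), best_epoch=best_epoch, dataset=dataset)


# ------------------------------------------------------------------ evaluation

@dataclass
class EvalReport:
    """Dataset-level accuracy summary.

    per_molecule_rmse  one RMSE per evaluated molecule (dataset order)
    mean_rmse          unweighted mean over molecules
    ci_low/ci_high     bootstrap 95% CI of the mean
    by_charge          DataFrame: total-charge bin, molecule count, mean RMSE
    by_size            DataFrame: atom-count bin, molecule count, mean RMSE
    """

    per_molecule_rmse: np.ndarray
    mean_rmse: float
    ci_low: float
    ci_high: float
    by_charge: pd.DataFrame
    by_size: pd.DataFrame


def _bin_table(keys: np.ndarray, rmses: np.ndarray, bins: Sequence, label: str) -> pd.DataFrame:
    rows = []
    for b in bins:
        if isinstance(b, tuple):
            mask = (keys >= b[0]) & (keys <= b[1])
            name = f"{b[0]}-{b[1]}"
        else:
            mask = keys == b
            name = str(b)
        count = int(mask.sum())
        rows.append(
            {
                label: name,
                "n_molecules": count,
                "mean_rmse": float(rmses[mask].mean()) if count else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def stratified_eval(
    dataset: ChargeDataset,
    model: ChargeModel,
    charge_bins: Sequence[int] | None = None,
    size_bins: Sequence[tuple[int, int]] | None = None,
    split: str | None = "test",
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Per-molecule RMSE with bootstrap CI and charge/size stratification.

    Empty bins report a count of 0 with NaN RMSE rather than raising; bin
    counts always partition the evaluated set when the bins cover it (the
    default bins are derived from the data, so they do).
    """
    if split is not None and dataset.split is not None:
        dataset = dataset.subset(split)
    if len(dataset) == 0:
        raise EmptyMoleculeError("no molecules to evaluate")
    results = assign_charges(dataset.molecules, model)
    rmses = np.array(
        [charge_rmse(r.q, ref) for r, ref in zip(results, dataset.charges)]
    )
    qs = np.array([total_formal_charge(m) for m in dataset.molecules])
    sizes = np.array([m.num_atoms for m in dataset.molecules])
    if charge_bins is None:
        charge_bins = list(range(int(qs.min()), int(qs.max()) + 1))
    if size_bins is None:
        hi = int(np.ceil(sizes.max() / 10.0) * 10)
        size_bins = [(lo + 1, lo + 10) for lo in range(0, hi, 10)]
    mean = float(rmses.mean())
    lo, hi_ci = bootstrap_ci(rmses, n_boot=n_boot, seed=seed)
    return EvalReport(
        per_molecule_rmse=rmses,
        mean_rmse=mean,
        ci_low=lo,
        ci_high=hi_ci,
        by_charge=_bin_table(qs, rmses, charge_bins, "total_charge"),
        by_size=_bin_table(sizes, rmses, size_bins, "atom_count"),
    )
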