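"""Loss, metrics, bootstrap, training loop, stratified evaluation."""

import numpy as np
import pandas as pd
import pytest

from qeqnet import (
    ChargeDataset,
    ChargeModel,
    GNNConfig,
    TrainConfig,
    bootstrap_ci,
    charge_rmse,
    squared_loss,
    stratified_eval,
    train,
)
from qeqnet.errors import DimensionError, EmptyMoleculeError
from qeqnet.synth import eem_reference_charges, generate_toy_molecules


@pytest.fixture(scope="module")
def labeled_dataset():
    mols = generate_toy_molecules(80, seed=8, max_heavy_atoms=8)
    return ChargeDataset(mols, [eem_reference_charges(m) for m in mols])


@pytest.fixture(scope="module")
def quick_model(labeled_dataset):
    """A briefly trained model: accurate enough that label quality dominates
    the stratified error signal."""
    cfg = TrainConfig(epochs=40, seed=0, batch_size=32, learning_rate=5e-3)
    return train(labeled_dataset, cfg, gnn_config=GNNConfig(n_layers=2, hidden_dim=32)).model


class TestLossAndMetrics:
    def test_zero_on_identity(self, rng):
        q = rng.normal(size=6)
        assert squared_loss(q, q) == 0.0
        assert charge_rmse(q, q) == 0.0

    def test_hand_values(self):
        assert squared_loss(np.array([0.1, -0.1]), np.zeros(2)) == pytest.approx(0.02)
        assert charge_rmse(np.array([0.3, 0.0, 0.0]), np.zeros(3)) == pytest.approx(0.3 / np.sqrt(3))
        assert charge_rmse(np.full(5, 0.1), np.zeros(5)) == pytest.approx(0.1)

    def test_permutation_invariance(self, rng):
        pred = rng.normal(size=8)
        ref = rng.normal(size=8)
        perm = rng.permutation(8)
        assert squared_loss(pred, ref) == pytest.approx(squared_loss(pred[perm], ref[perm]))
        assert charge_rmse(pred, ref) == pytest.approx(charge_rmse(pred[perm], ref[perm]))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            squared_loss(np.zeros(2), np.zeros(3))

    def test_empty_molecule_rmse(self):
        with pytest.raises(EmptyMoleculeError):
            charge_rmse(np.zeros(0), np.zeros(0))


class TestBootstrap:
    def test_degenerate_distribution(self):
        lo, hi = bootstrap_ci([0.3] * 20, n_boot=200, seed=1)
        assert lo == pytest.approx(0.3) and hi == pytest.approx(0.3)

    def test_seed_determinism(self, rng):
        vals = rng.normal(size=40)
        assert bootstrap_ci(vals, seed=5) == bootstrap_ci(vals, seed=5)
        assert bootstrap_ci(vals, seed=5) != bootstrap_ci(vals, seed=6)

    def test_interval_brackets_sample_mean(self, rng):
        vals = rng.exponential(size=50)
        lo, hi = bootstrap_ci(vals, n_boot=2000, seed=0)
        assert lo <= vals.mean() <= hi

    def test_empty_rejected(self):
        with pytest.raises(EmptyMoleculeError):
            bootstrap_ci([])


class TestSplits:
    def test_split_fractions_and_disjointness(self, labeled_dataset):
        ds = labeled_dataset.with_random_split(seed=0)
        counts = pd.Series(ds.split).value_counts()
        assert counts["train"] == 64 and counts["val"] == 8 and counts["test"] == 8
        names = [m.name for m in ds.molecules]
        assert len(set(names)) == len(names)  # splits disjoint by molecule

    def test_split_deterministic(self, labeled_dataset):
        a = labeled_dataset.with_random_split(seed=4).split
        b = labeled_dataset.with_random_split(seed=4).split
        assert a == b

    def test_reference_sum_validated(self):
        mols = generate_toy_molecules(1, seed=0)
        bad = [np.zeros(mols[0].num_atoms) + 0.5]
        with pytest.raises(ValueError):
            ChargeDataset(mols, bad)


class TestTrainLoop:
    def test_zero_epochs_returns_initial_model(self, labeled_dataset):
        res = train(labeled_dataset, TrainConfig(epochs=0, seed=1))
        assert len(res.history) == 0 and res.best_epoch == -1

    def test_seeded_determinism(self, labeled_dataset):
        cfg = TrainConfig(epochs=3, seed=7, batch_size=32)
        gcfg = GNNConfig(n_layers=2, hidden_dim=16)
        r1 = train(labeled_dataset, cfg, gnn_config=gcfg)
        r2 = train(labeled_dataset, cfg, gnn_config=gcfg)
        pd.testing.assert_frame_equal(r1.history, r2.history)

    def test_loss_decreases_on_recoverable_labels(self, labeled_dataset):
        cfg = TrainConfig(epochs=25, seed=0, batch_size=32, learning_rate=5e-3)
        res = train(labeled_dataset, cfg, gnn_config=GNNConfig(n_layers=2, hidden_dim=32))
        first, last = res.history["val_loss"].iloc[0], res.history["val_loss"].min()
        assert last < 0.25 * first

    def test_best_so_far_validation_monotone(self, labeled_dataset):
        cfg = TrainConfig(epochs=10, seed=2, batch_size=32)
        res = train(labeled_dataset, cfg, gnn_config=GNNConfig(n_layers=2, hidden_dim=16))
        best = res.history["val_loss"].cummin()
        assert (best.diff().dropna() <= 1e-12).all()


class TestStratifiedEval:
    def test_bin_counts_partition_dataset(self, labeled_dataset, small_model):
        ds = labeled_dataset.with_random_split(seed=0)
        rep = stratified_eval(ds, small_model, split="test")
        n_test = sum(1 for s in ds.split if s == "test")
        assert rep.by_charge["n_molecules"].sum() == n_test
        assert rep.by_size["n_molecules"].sum() == n_test
        assert rep.ci_low <= rep.mean_rmse <= rep.ci_high

    def test_single_stratum_equals_dataset_mean(self, small_model):
        mols = [m for m in generate_toy_molecules(20, seed=5, charge_weights={0: 1.0})]
        ds = ChargeDataset(mols, [eem_reference_charges(m) for m in mols])
        rep = stratified_eval(ds, small_model, charge_bins=[0], split=None)
        assert rep.by_charge.loc[0, "mean_rmse"] == pytest.approx(rep.mean_rmse)

    def test_empty_bin_reports_zero_count_nan_rmse(self, labeled_dataset, small_model):
        rep = stratified_eval(labeled_dataset, small_model, charge_bins=[0, 2], split=None)
        row = rep.by_charge.set_index("total_charge").loc["2"]
        assert row["n_molecules"] == 0 and np.isnan(row["mean_rmse"])

    def test_degraded_labels_show_up_in_their_bin(self, quick_model):
        """Corrupting only the anions' labels must raise that bin's RMSE."""
        mols = generate_toy_molecules(60, seed=13, charge_weights={0: 0.5, -1: 0.5})
        rng = np.random.default_rng(0)
        labels = []
        for m in mols:
            q = eem_reference_charges(m)
            if sum(a.formal_charge for a in m.atoms) == -1:
                noise = rng.normal(0, 0.2, size=len(q))
                noise -= noise.mean()  # keep the sum intact
                q = q + noise
            labels.append(q)
        ds = ChargeDataset(mols, labels)
        rep = stratified_eval(ds, quick_model, charge_bins=[-1, 0], split=None)
        tbl = rep.by_charge.set_index("total_charge")
        assert tbl.loc["-1", "mean_rmse"] > tbl.loc["0", "mean_rmse"]

    def test_metrics_invariant_to_dataset_order(self, labeled_dataset, small_model):
        rep1 = stratified_eval(labeled_dataset, small_model, split=None, seed=3)
        rev = ChargeDataset(
            labeled_dataset.molecules[::-1], labeled_dataset.charges[::-1]
        )
        rep2 = stratified_eval(rev, small_model, split=None, seed=3)
        assert rep1.mean_rmse == pytest.approx(rep2.mean_rmse)
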