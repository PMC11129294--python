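"""End-to-end model: readout heads, charge assignment, gradients, checkpoints."""

import numpy as np
import pytest

from qeqnet import (
    ChargeModel,
    GNNConfig,
    assign_charges,
    batch_graphs,
    build_graph,
    total_formal_charge,
)
from qeqnet.errors import CheckpointError, UnsupportedElementError
from qeqnet.chem import FeaturizationConfig
from qeqnet.model import AssignmentFailure
from qeqnet.synth import eem_reference_charges, generate_toy_molecules


class TestReadout:
    def test_hardness_strictly_positive(self, small_model, toy_molecules, scheme):
        for mol in toy_molecules[:10]:
            h = small_model.embed(build_graph(mol, scheme))
            cp = small_model.predict_e_s(h)
            assert np.all(cp.s > 0)

    def test_identical_embeddings_identical_outputs(self, small_model, methane, scheme):
        h = small_model.embed(build_graph(methane, scheme))
        cp = small_model.predict_e_s(h)
        h_idx = [i for i, a in enumerate(methane.atoms) if a.element == "H"]
        assert np.ptp(cp.e[h_idx]) <= 1e-12
        assert np.ptp(cp.s[h_idx]) <= 1e-12

    def test_deterministic(self, small_model, acetate, scheme):
        h = small_model.embed(build_graph(acetate, scheme))
        cp1 = small_model.predict_e_s(h)
        cp2 = small_model.predict_e_s(h.copy())
        np.testing.assert_array_equal(cp1.e, cp2.e)
        np.testing.assert_array_equal(cp1.s, cp2.s)


class TestAssignCharges:
    def test_conservation_per_molecule(self, small_model, toy_molecules):
        results = assign_charges(toy_molecules, small_model)
        for mol, res in zip(toy_molecules, results):
            assert abs(res.q.sum() - total_formal_charge(mol)) <= 1e-8

    def test_mixed_charge_batch(self, small_model, methane, acetate):
        res = assign_charges([methane, acetate], small_model)
        assert abs(res[0].q.sum() - 0) <= 1e-8
        assert abs(res[1].q.sum() + 1) <= 1e-8

    def test_single_equals_batch_of_one(self, small_model, methane):
        r1 = assign_charges(methane, small_model)[0]
        r2 = assign_charges([methane], small_model)[0]
        np.testing.assert_allclose(r1.q, r2.q)

    def test_batched_equals_sequential(self, small_model, toy_molecules):
        batched = assign_charges(toy_molecules, small_model, batch_size=16)
        sequential = [assign_charges(m, small_model)[0] for m in toy_molecules]
        for rb, rs in zip(batched, sequential):
            np.testing.assert_allclose(rb.q, rs.q, atol=1e-6)

    def test_permutation_equivariance_end_to_end(self, small_model, toy_molecules, rng):
        for mol in toy_molecules[:10]:
            q = assign_charges(mol, small_model)[0].q
            perm = rng.permutation(mol.num_atoms)
            q_perm = assign_charges(mol.permuted(perm), small_model)[0].q
            np.testing.assert_allclose(q_perm[perm], q, atol=1e-6)

    def test_carboxylate_oxygens_equal_charges(self, small_model, acetate):
        res = assign_charges(acetate, small_model)[0]
        oidx = [i for i, a in enumerate(acetate.atoms) if a.element == "O"]
        assert abs(res.q[oidx[0]] - res.q[oidx[1]]) <= 1e-6

    def test_bad_record_does_not_abort_batch(self, small_model, methane):
        from qeqnet.chem import Atom, Molecule

        bad = Molecule([Atom("Se"), Atom("H"), Atom("H")], [(0, 1), (0, 2)], name="selane")
        out = assign_charges([methane, bad], small_model, on_error="record")
        assert not isinstance(out[0], AssignmentFailure)
        assert isinstance(out[1], AssignmentFailure) and out[1].name == "selane"

    def test_bad_record_raises_by_default(self, small_model):
        from qeqnet.chem import Atom, Molecule

        bad = Molecule([Atom("Se"), Atom("H"), Atom("H")], [(0, 1), (0, 2)])
        with pytest.raises(UnsupportedElementError):
            assign_charges([bad], small_model)


class TestGradients:
    def test_backprop_matches_finite_differences(self, scheme):
        """Hand-written reverse mode through GNN, heads and the analytic solve."""
        mols = generate_toy_molecules(3, seed=7, max_heavy_atoms=5)
        refs = np.concatenate([eem_reference_charges(m) for m in mols])
        model = ChargeModel.initialize(
            seed=3, gnn_config=GNNConfig(n_layers=2, hidden_dim=8), head_hidden=6
        )
        graphs = [build_graph(m, scheme) for m in mols]
        b = batch_graphs(graphs, [total_formal_charge(m) for m in mols])
        _, grads, _ = model.loss_and_grad(b, refs)
        params = model.parameters
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, arr in params.items():
            flat = arr.reshape(-1)
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                model.set_parameters(params)
                lp, _, _ = model.loss_and_grad(b, refs)
                flat[k] = orig - eps
                model.set_parameters(params)
                lm, _, _ = model.loss_and_grad(b, refs)
                flat[k] = orig
                model.set_parameters(params)
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name].reshape(-1)[k]
                assert numeric == pytest.approx(analytic, rel=1e-5, abs=1e-8), name

    def test_shared_weight_gradients(self, scheme):
        """Weight sharing accumulates one gradient across layers; check it too."""
        mols = generate_toy_molecules(2, seed=9, max_heavy_atoms=4)
        refs = np.concatenate([eem_reference_charges(m) for m in mols])
        model = ChargeModel.initialize(
            seed=5,
            gnn_config=GNNConfig(n_layers=3, hidden_dim=6, share_weights=True),
            head_hidden=4,
        )
        graphs = [build_graph(m, scheme) for m in mols]
        b = batch_graphs(graphs, [total_formal_charge(m) for m in mols])
        _, grads, _ = model.loss_and_grad(b, refs)
        params = model.parameters
        eps = 1e-6
        name = "gnn.edge0_W"
        flat = params[name].reshape(-1)
        for k in (0, 5, 11):
            orig = flat[k]
            flat[k] = orig + eps
            model.set_parameters(params)
            lp, _, _ = model.loss_and_grad(b, refs)
            flat[k] = orig - eps
            model.set_parameters(params)
            lm, _, _ = model.loss_and_grad(b, refs)
            flat[k] = orig
            model.set_parameters(params)
            assert (lp - lm) / (2 * eps) == pytest.approx(
                grads[name].reshape(-1)[k], rel=1e-5, abs=1e-8
            )


class TestCheckpoints:
    def test_save_load_round_trip(self, small_model, methane, tmp_path):
        path = tmp_path / "model.json"
        small_model.save(str(path))
        loaded = ChargeModel.load(str(path))
        q1 = assign_charges(methane, small_model)[0].q
        q2 = assign_charges(methane, loaded)[0].q
        np.testing.assert_array_equal(q1, q2)

    def test_feature_version_mismatch_refused(self, tmp_path):
        model = ChargeModel.initialize(
            seed=0,
            feature_config=FeaturizationConfig(version="experimental-v9"),
            gnn_config=GNNConfig(n_layers=1, hidden_dim=4),
            head_hidden=4,
        )
        path = tmp_path / "model.json"
        model.save(str(path))
        with pytest.raises(CheckpointError):
            ChargeModel.load(str(path))

    def test_garbage_file_refused(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{}")
        with pytest.raises(CheckpointError):
            ChargeModel.load(str(path))
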