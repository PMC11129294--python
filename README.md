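# qeqnet

Fast, conformation-independent partial atomic charges from a hybrid
graph-neural-network / charge-equilibration model.

## The problem

Molecular-mechanics force fields need a fixed point charge on every atom.
The standard workflows derive them from semiempirical quantum chemistry
(AM1-BCC and relatives), which costs minutes per drug-sized molecule and
scales so poorly that charging a biopolymer is impractical. Yet the quantity
being produced is simple: one real number per atom, constrained to sum to the
molecule's integer total charge Q.

`qeqnet` implements the surrogate-model approach to this problem:

1. **Chemical environment perception.** A message-passing neural network runs
   K rounds of (edge update φᵉ, index-invariant neighborhood aggregation ρ,
   node update φᵛ) over the molecular graph — atoms as nodes, bonds as edges,
   resonance-independent local descriptors as input features — producing a
   continuous embedding hᵥ of every atom's chemical environment. This
   replaces hand-written discrete atom types.
2. **Readout.** Two small feed-forward heads map each embedding to an
   electronegativity eᵢ (first derivative of the atomic charging energy with
   respect to charge) and a hardness sᵢ > 0 (second derivative).
3. **Charge equilibration (QEq).** Charges minimize the second-order charging
   energy, neglecting interatomic electrostatics,

       E(q) = Σᵢ (eᵢ qᵢ + sᵢ qᵢ²)   subject to   Σᵢ qᵢ = Q,

   which has the closed-form Lagrange solution

       qᵢ = (λ − eᵢ) / (2 sᵢ),   λ = (Q + Σⱼ eⱼ/(2 sⱼ)) / Σⱼ 1/(2 sⱼ).

   Conservation is therefore satisfied *exactly* by construction — not
   learned — and the whole pipeline costs O(N) in the number of atoms,
   because molecular graphs are sparse and the solve is two reductions.

Molecule lists are charged in batch by concatenating their adjacency
structure block-diagonally; the constraint is applied per molecule via
segment-wise reductions, so batched results equal sequential ones.

Everything is geometry-agnostic: no conformers, no 3D coordinates.

## Worked example

No pretrained weights ship with the package; the synthetic-data module
provides molecules with exactly known ground-truth charges (an
electronegativity-equalization table by element), which is enough to see the
whole pipeline work:

```python
from qeqnet import (ChargeDataset, GNNConfig, TrainConfig, assign_charges,
                    parse_molecule, train)
from qeqnet.synth import eem_reference_charges, generate_toy_molecules

mols = generate_toy_molecules(300, seed=7)
dataset = ChargeDataset(mols, [eem_reference_charges(m) for m in mols])
result = train(dataset, TrainConfig(epochs=120, seed=0),
               gnn_config=GNNConfig(n_layers=3, hidden_dim=64))

water = parse_molecule("O", "smiles", name="water")
acetate = parse_molecule("CC(=O)[O-]", "smiles", name="acetate")
for res in assign_charges([water, acetate], result.model):
    qs = "  ".join(f"{q:+.4f}" for q in res.q)
    print(f"{res.name:8s} Q={res.Q:+.0f}  sum={res.q.sum():+.6f}  q=[{qs}]")
```

prints

```
water    Q=+0  sum=+0.000000  q=[-0.2105  +0.1052  +0.1052]
acetate  Q=-1  sum=-1.000000  q=[-0.0496  -0.0520  -0.4498  -0.4498  +0.0004  +0.0004  +0.0004]
```

Water's oxygen draws negative charge and the two hydrogens are exactly
equivalent; the trained model is within ~0.001 e of the generator's reference
(`eem_reference_charges(water)` → `[-0.2116, +0.1058, +0.1058]`). Acetate's
charges sum to −1 exactly, and the two carboxylate oxygens — resonance-
equivalent at the graph level — receive identical charges.

### Command line

```bash
qeqnet train  -i labeled.sdf -o model.json --epochs 200
qeqnet charge -i library.sdf -o charged.mol2 -fi sdf -fo mol2 --model model.json
```

`charge` uses antechamber-style flags (`-i/-o/-fi/-fo`), reads SMILES/SDF/MOL2,
writes SDF (charges in a `PARTIAL_CHARGES` property tag) or TRIPOS MOL2
(charges in the per-atom charge column, charge type `QEQNET_CHARGES`), skips
unparseable records unless `--fail-fast` is given, and writes output
atomically. Written charges are rounded to six decimals with a sum-preserving
repair so every record's charges add up to its integer Q exactly.

## Scope

The model family, constraint layer and training loop are general, but this
package ships no reference AM1-BCC charges and no pretrained weights:
producing production-quality charges requires training against a large
semiempirical reference set, which is outside its scope. See
`docs/methods.md` for the model assumptions, defaults and limitations.
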