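# Methods

## Model

`qeqnet` assigns partial atomic charges in three stages.

**Featurization** (`qeqnet.chem`). Each atom gets a fixed-width row: element
one-hot over the vocabulary {H, C, N, O, S, P, F, Cl, Br, I}, degree one-hot
(0–6, clamped), a formal-charge encoding on the integer grid −2..+2,
a ring-membership flag and an aromaticity flag. All descriptors are local and
resonance-independent: no bond orders, no kekulé structure, no 3D coordinates
enter the features. Two subtleties:

- *Formal-charge symmetrization.* Raw formal charges are resonance-dependent
  (a carboxylate draws −1 on one oxygen in any single depiction). Before
  encoding, formal charges are averaged within equivalence classes computed
  by Weisfeiler-Lehman color refinement seeded on elements only (charge- and
  order-blind), so both carboxylate oxygens carry −0.5. Refinement is capped
  at 16 rounds — equivalence relevant to resonance is a local phenomenon, and
  the cap keeps featurization O(N) on chain-like molecules. Because −0.5
  cannot be one-hot encoded, the charge block is a *soft* one-hot: integer
  values give an exact one-hot, fractional values split weight linearly
  between the two adjacent bins. Width and permutation behavior are unchanged.
- *Vocabulary.* One-hot element encoding cannot generalize to unseen
  elements, so out-of-vocabulary atoms are rejected with a typed error rather
  than silently embedded. The vocabulary is a config constant
  (`FeaturizationConfig.elements`) and the scheme carries a version tag that
  model checkpoints must match.

The exact feature list of comparable published models is not public;
this set is a documented stand-in, flagged by the version tag
(`qeqnet-feat-v1`).

**Message passing** (`qeqnet.gnn`). K rounds of edge update
m_{u→v} = σ(W_e [h_u, h_v] + b_e), sum (or mean) aggregation over incoming
edges, and node update h_v ← σ(W_v [h_v, a_v] + b_v), after a linear input
projection. Defaults: K = 3, width 128, sum aggregation, tanh. These are
tuned quantities, not derived ones; they live in `GNNConfig`, and the
training experiments in this repository use width 64 (accurate and fast at
that scale). Edges carry no features of their own — bond order is partially
resonance-dependent and is deliberately excluded; messages are functions of
the endpoint embeddings only. Layers have independent weights by default
(`share_weights` flips this). Mean aggregation over an empty neighborhood is
defined as the zero vector so monatomic ions work. Weights initialize from a
seeded generator with fan-in scaling.

**Readout and charge equilibration** (`qeqnet.model`, `qeqnet.qeq`). Two
one-hidden-layer heads map embeddings to electronegativity e_i (unbounded)
and hardness s_i = softplus(raw) + 10⁻⁴ (strictly positive, no upper bound).
Charges minimize E(q) = Σ (e_i q_i + s_i q_i²) subject to Σ q_i = Q, solved
in closed form via the Lagrange multiplier λ = (Q + Σ e_j/(2s_j)) / Σ 1/(2s_j),
q_i = (λ − e_i)/(2 s_i). Note the quadratic coefficient is s_i, **not**
s_i/2; comparisons with other charge-equilibration conventions must account
for the factor of two. The sign convention is fixed by a monotonicity
property verified in the tests: raising one atom's electronegativity never
raises its charge. A hardness at or below 10⁻⁶ raises a typed error naming
the atom — the objective would not be strictly convex.

The API accepts real-valued Q (useful for fragments); the CLI always derives
integer Q from formal charges. Multi-fragment inputs are rejected: the
constraint is per-molecule and fragment-level Q would be ambiguous.

## Batching

Graphs are batched by concatenating node features and offsetting edge
indices (block-diagonal adjacency). No edge crosses a molecule boundary, so
batched embeddings equal concatenated per-molecule embeddings, and the
equilibration runs segment-wise so each molecule gets its own multiplier.
`assign_charges` splits long inputs into sub-batches of at most 64 molecules
and roughly 1024 atoms; the atom budget keeps working arrays cache-resident
on a CPU, which benchmarking showed matters more than maximizing batch
width. Batching amortizes per-call overhead and is worth ~2.5× on libraries
of drug-sized molecules; for a handful of very large molecules the
computation is compute-bound and batching is roughly cost-neutral on a
single CPU (the large batched-inference speedups reported for this model
class come from saturating parallel hardware).

## Numerical choices

Everything runs in double precision. The equilibration's conservation
contract (|Σq − Q| ≤ 10⁻⁸) binds the whole pipeline's precision; with NumPy
on CPU, float64 is native, so no mixed-precision split is used. The
training gradient — hand-written reverse mode through the GNN, the heads,
the softplus and the closed-form solve — is verified against central finite
differences to ~10⁻¹⁰ relative error in the test suite. Segment reductions
use `bincount`-based scatter-sums; written charges are rounded to six
decimals with the residual folded into the largest-|q| atom so file output
conserves Q exactly.

## Training

Squared loss, summed over atoms and molecules (no per-molecule
normalization — configurable in principle, but the plain sum is the
default). Adam (lr 5·10⁻³, β = 0.9/0.999), minibatches of 64 molecules,
molecule-disjoint 80/10/10 split by seeded shuffle, early stopping on
validation loss with patience 50, best-validation checkpoint returned.
All randomness (init, split, shuffling) derives from `TrainConfig.seed`;
two runs with the same seed are bit-identical. Evaluation reports
per-molecule RMSE over atoms, its unweighted mean over molecules, a
percentile bootstrap 95 % CI of the mean (1000 resamples over molecules by
default), and tables stratified by integer total charge and by atom count in
bins of 10 — surrogate charge models are only as good as their training
coverage, and the stratified view exposes that. Empty bins report count 0
with NaN rather than raising.

## Synthetic data

The generator (`qeqnet.synth`) emulates the *statistical structure* of a
charge-labeling task — per-atom real labels exactly constrained to the
integer molecular charge — without any quantum chemistry:

- **Molecules**: random spanning trees over the element vocabulary with
  valence bookkeeping, hydrogens completed at the end; net charges drawn
  from a configurable distribution over −2..+2 (default 60 % neutral, 20 %
  anionic via alkoxide-style O⁻, 20 % cationic via ammonium-style N⁺);
  sizes uniform in 1–12 heavy atoms; halide anions and H–X diatomics appear
  as genuine single-atom / single-bond edge cases. Deterministic given the
  seed.
- **Labels**: a fixed per-element (e₀, s₀) table — ordering
  F > O > N > Cl > C ≈ S ≈ H, values hand-chosen and *synthetic*, not fitted
  to any QM source — with e adjusted by −2.0 per unit formal charge, pushed
  through the same closed-form solve. Labels conserve Q by construction.
- **Chains**: capped alanine-like repeats (12 cap atoms + 10 per residue,
  connectivity only) for scaling experiments; they provide size structure,
  not biochemistry.

Because the labels are an exact function of (element, formal charge,
Q-partition) and element identity is in the features, the model family can
represent the generator exactly; training is therefore a parameter-recovery
experiment with a known answer. The acceptance suite trains on 600 such
molecules (K = 3, width 64, ≤ 200 epochs) and requires held-out mean RMSE
≤ 0.01 e; it reaches ~3·10⁻⁴ e. What passing shows: the architecture,
constraint layer, gradients and training loop are correct and the model can
learn element-resolved charge parameters. What it does not show: accuracy on
real chemistry — real reference charges (e.g. semiempirical with bond-charge
corrections) depend on bond orders, conformers and longer-range effects the
generator does not emulate.

## File formats

SMILES (one record per line), SDF V2000 (via RDKit) and TRIPOS MOL2. The
MOL2 reader/writer pair is minimal and self-consistent: elements in the
atom-type column, partial charges in the charge column with charge type
`QEQNET_CHARGES`, formal charges in `@<TRIPOS>UNITY_ATOM_ATTR` (absent
section ⇒ all zero), zero coordinates (the model is geometry-agnostic).
Checkpoints are versioned JSON; the loader refuses a featurization version
mismatch.

## Known limitations

- No generalization to elements outside the one-hot vocabulary.
- No conformer, tautomer or protonation-state handling; inputs are taken as
  given.
- Interatomic electrostatics are absent from the charging energy by design;
  geometry-dependent equilibration variants are out of scope.
- The synthetic labels are not physical; shipped defaults produce a working
  pipeline, not production charges.
- Single-threaded CPU implementation; no GPU dispatch.
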