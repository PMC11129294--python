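"""Synthetic molecules and ground-truth charge labels.

Real training data for a charge surrogate requires semiempirical reference
charges from an external toolkit. For development and testing this module
supplies a fully known alternative: an electronegativity-equalization (EEM)
parameter table keyed by element (with a formal-charge adjustment), pushed
through the same analytic equilibration used at inference time. Every label
therefore satisfies the total-charge constraint by construction, and — since
element identity and formal charge are in the node features — the labeling
function is exactly representable by the model family, which is what makes
parameter-recovery experiments meaningful.

The table's constants are synthetic: hand-chosen to be plausible (the
electronegativity ordering F > O > N > Cl > C ~ S ~ H holds) but not fitted
to any quantum-chemical source. Ground truth here must be *known*, not
physically authoritative.

Also provided: random valence-valid tree molecules over the feature
vocabulary, and capped polypeptide-like chain graphs for scaling experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem import Atom, Molecule, total_formal_charge
from .errors import UnsupportedElementError
from .qeq import ChargeParams, qeq_solve

#: Standard single-bond valences used by the tree-growth grammar.
VALENCES = {"H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}

#: Synthetic per-element (electronegativity, hardness) constants. Units are
#: arbitrary energy/charge and energy/charge^2; only ordering and rough
#: magnitudes are meant to look chemical.
DEFAULT_EEM_CONSTANTS: dict[str, tuple[float, float]] = {
    "H": (4.5, 6.5),
    "C": (5.0, 5.0),
    "N": (6.8, 5.9),
    "O": (8.5, 6.2),
    "S": (5.2, 4.0),
    "P": (4.8, 4.2),
    "F": (10.0, 7.0),
    "Cl": (7.5, 4.8),
    "Br": (7.0, 4.4),
    "I": (6.5, 4.0),
}


@dataclass(frozen=True)
class EEMParamTable:
    """Per-element (e0, s0) constants plus a formal-charge adjustment to e0.

    The effective per-atom electronegativity is ``e0 - charge_shift * fc``:
    an anionic site becomes *more* electronegative, so it holds the extra
    negative charge — consistent with the model's sign convention that more
    electronegative atoms draw more negative charge.
    """

    constants: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EEM_CONSTANTS)
    )
    charge_shift: float = 2.0

    def __post_init__(self) -> None:
        for el, (_, s0) in self.constants.items():
            if s0 <= 0:
                raise ValueError(f"hardness constant for {el} must be positive")

    def lookup(self, element: str, formal_charge: int = 0) -> tuple[float, float]:
        if element not in self.constants:
            raise UnsupportedElementError(
                f"element {element!r} not covered by the EEM parameter table"
            )
        e0, s0 = self.constants[element]
        return e0 - self.charge_shift * formal_charge, s0

    def to_json(self) -> str:
        return json.dumps(
            {"constants": {k: list(v) for k, v in self.constants.items()},
             "charge_shift": self.charge_shift},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EEMParamTable":
        d = json.loads(text)
        return cls(
            constants={k: tuple(v) for k, v in d["constants"].items()},
            charge_shift=d["charge_shift"],
        )


DEFAULT_EEM_TABLE = EEMParamTable()


def eem_reference_charges(mol: Molecule, table: EEMParamTable | None = None) -> np.ndarray:
    """Ground-truth charges: element/charge lookup, then the analytic solve.

    The output sums to the molecule's total formal charge to 1e-8 by
    construction, matching the invariant the model must satisfy.
    """
    table = table or DEFAULT_EEM_TABLE
    pairs = [table.lookup(a.element, a.formal_charge) for a in mol.atoms]
    e = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    return qeq_solve(ChargeParams(e=e, s=s), total_formal_charge(mol), name=mol.name).q


# --------------------------------------------------------------------- trees

#: sampling weights for neutral heavy atoms in the tree grammar
_HEAVY_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]
_HEAVY_WEIGHTS = np.array([0.50, 0.13, 0.13, 0.05, 0.03, 0.06, 0.06, 0.02, 0.02])


def _grow_tree(
    rng: np.random.Generator,
    heavy: list[tuple[str, int, int]],  # (element, formal charge, valence)
    name: str,
) -> Molecule:
    """Random spanning-tree growth with valence bookkeeping, H-filled at the end."""
    atoms = [Atom(el, fc) for el, fc, _ in heavy]
    free = [val for _, _, val in heavy]
    bonds: list[tuple[int, int]] = []
    for i in range(1, len(heavy)):
        open_sites = [j for j in range(i) if free[j] > 0]
        j = int(rng.choice(open_sites))
        bonds.append((j, i))
        free[j] -= 1
        free[i] -= 1
    for i in range(len(heavy)):
        for _ in range(free[i]):
            atoms.append(Atom("H"))
            bonds.append((i, len(atoms) - 1))
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def _sample_heavy_set(
    rng: np.random.Generator, n_heavy: int, q_target: int
) -> list[tuple[str, int, int]]:
    """Pick heavy atoms realizing the target net charge and a feasible tree.

    Positive sites are quaternary-style N+ (valence 4); negative sites are
    alkoxide-style O- (valence 1). Monovalent excess is repaired by swapping
    halogens for carbon so a spanning tree always exists.
    """
    n_plus = max(q_target, 0)
    n_minus = max(-q_target, 0)
    n_heavy = max(n_heavy, n_plus + n_minus)
    heavy: list[tuple[str, int, int]] = []
    heavy += [("N", 1, 4)] * n_plus
    heavy += [("O", -1, 1)] * n_minus
    while len(heavy) < n_heavy:
        el = _HEAVY_ELEMENTS[int(rng.choice(len(_HEAVY_ELEMENTS), p=_HEAVY_WEIGHTS))]
        heavy.append((el, 0, VALENCES[el]))
    # feasibility: a tree on n nodes needs total valence >= 2(n-1); replace
    # surplus monovalent atoms with carbon until satisfied
    def ok(hs):
        n = len(hs)
        return sum(v for _, _, v in hs) >= 2 * (n - 1) and (
            n == 1 or sum(1 for _, _, v in hs if v > 1) >= 1
        )

    hs = list(heavy)
    i = 0
    while not ok(hs) and i < len(hs):
        if hs[i][2] == 1 and hs[i][1] == 0:
            hs[i] = ("C", 0, 4)
        i += 1
    # place polyvalent atoms first so every attachment finds an open site
    hs.sort(key=lambda t: -t[2])
    order = rng.permutation(len(hs))
    hs = sorted((hs[int(k)] for k in order), key=lambda t: -t[2])
    return hs


def generate_toy_molecules(
    n: int,
    seed: int = 0,
    max_heavy_atoms: int = 12,
    charge_weights: dict[int, float] | None = None,
) -> list[Molecule]:
    """Deterministic sequence of valence-valid connected toy molecules.

    Net charges are drawn from ``charge_weights`` (default 60% neutral, 20%
    anionic, 20% cationic, matching a protonation-state-enriched small-molecule
    set in spirit); sizes are uniform in 1..max_heavy_atoms heavy atoms.
    Single-atom (halide anion) and single-bond (H-X) edge cases occur whenever
    a one-heavy-atom draw coincides with the right net charge.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    charge_weights = charge_weights or {0: 0.6, -1: 0.2, 1: 0.2}
    qs = np.array(sorted(charge_weights))
    ps = np.array([charge_weights[int(q)] for q in qs], dtype=float)
    ps /= ps.sum()
    rng = np.random.default_rng(seed)
    mols: list[Molecule] = []
    for i in range(n):
        q_target = int(qs[rng.choice(len(qs), p=ps)])
        n_heavy = int(rng.integers(1, max_heavy_atoms + 1))
        name = f"toy-{i}"
        if n_heavy == 1 and q_target == -1:
            el = str(rng.choice(["F", "Cl", "Br", "I"]))
            mols.append(Molecule(atoms=[Atom(el, -1)], bonds=[], name=name))
            continue
        heavy = _sample_heavy_set(rng, n_heavy, q_target)
        mol = _grow_tree(rng, heavy, name)
        assert total_formal_charge(mol) == q_target
        mols.append(mol)
    return mols


# -------------------------------------------------------------------- chains

# Alanine-like capped chain: an acetyl-style head cap (6 atoms), n repeats of
# a 10-atom backbone+methyl residue, and an N-methyl-style tail cap (6 atoms).
# Carbonyl oxygens appear as degree-1 oxygens (connectivity only; the graph
# carries no bond orders). Atom counts: 12 + 10 n.
_ACE = (["C", "H", "H", "H", "C", "O"], [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5)], 4)
_RESIDUE = (
    ["N", "H", "C", "H", "C", "H", "H", "H", "C", "O"],
    [(0, 1), (0, 2), (2, 3), (2, 4), (4, 5), (4, 6), (4, 7), (2, 8), (8, 9)],
    0,  # attach-in: backbone N
    8,  # attach-out: carbonyl C
)
_NME = (["N", "H", "C", "H", "H", "H"], [(0, 1), (0, 2), (2, 3), (2, 4), (2, 5)], 0)


@dataclass(frozen=True)
class ChainSpec:
    """Capped chain of ``n_residues`` alanine-like repeats (>= 1)."""

    n_residues: int

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(_ACE[0]) + len(_NME[0]) + self.n_residues * len(_RESIDUE[0])


def make_chain_graph(spec: ChainSpec) -> Molecule:
    """Connected acyclic capped-chain molecule for scaling experiments."""
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []

    def add_block(elements, internal_bonds):
        off = len(atoms)
        atoms.extend(Atom(el) for el in elements)
        bonds.extend((off + i, off + j) for i, j in internal_bonds)
        return off

    ace_off = add_block(_ACE[0], _ACE[1])
    prev_out = ace_off + _ACE[2]
    for _ in range(spec.n_residues):
        off = add_block(_RESIDUE[0], _RESIDUE[1])
        bonds.append((prev_out, off + _RESIDUE[2]))
        prev_out = off + _RESIDUE[3]
    nme_off = add_block(_NME[0], _NME[1])
    bonds.append((prev_out, nme_off + _NME[2]))
    return Molecule(atoms=atoms, bonds=bonds, name=f"chain-{spec.n_residues}")
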