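"""Closed-form charge equilibration.

Each atom i carries an electronegativity e_i (first derivative of its charging
potential energy with respect to charge) and a hardness s_i (second
derivative, strictly positive). Neglecting interatomic electrostatics, the
charging energy of a charge vector q is the separable quadratic

    E(q) = sum_i ( e_i q_i + s_i q_i^2 )

(note the coefficient of the quadratic term is s_i, not s_i/2 — comparisons
with other charge-equilibration literature must account for this factor-of-2
convention). Minimizing E subject to the total-charge constraint
sum_i q_i = Q has the analytic Lagrange solution

    q_i = (lam - e_i) / (2 s_i),
    lam = (Q + sum_j e_j / (2 s_j)) / sum_j 1 / (2 s_j),

where lam, the multiplier, is the equalized electronegativity at the optimum:
e_i + 2 s_i q_i = lam for every atom. Strict convexity (s_i > 0) makes the
minimizer unique; more electronegative atoms draw more negative charge under
this sign convention. The solve is O(N) — two reductions and one elementwise
pass — so it never dominates the network's cost.

All arithmetic here is double precision; conservation holds to 1e-8 or better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, EmptyMoleculeError, HardnessError, NumericalError

#: Hardness values at or below this guard are rejected: the quadratic would be
#: (numerically) non-convex and the multiplier unbounded.
HARDNESS_FLOOR = 1e-6


@dataclass
class ChargeParams:
    """Per-atom electronegativity (energy/charge) and hardness (energy/charge^2)."""

    e: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=np.float64)
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.e.shape != self.s.shape:
            raise DimensionError(
                f"electronegativity ({self.e.shape}) and hardness ({self.s.shape}) "
                "must have equal length"
            )


@dataclass
class ChargeResult:
    """Partial charges for one molecule.

    q       per-atom charges (elementary charge units), summing to Q
    Q       the total molecular charge used as the constraint
    energy  charging energy E(q) at the optimum
    name    label carried through from the input record
    """

    q: np.ndarray
    Q: float
    energy: float
    name: str = ""


def charging_energy(e: np.ndarray, s: np.ndarray, q: np.ndarray) -> float:
    """E(q) = sum_i (e_i q_i + s_i q_i^2)."""
    e = np.asarray(e, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not (e.shape == s.shape == q.shape):
        raise DimensionError(
            f"charging_energy: shapes differ: e{e.shape} s{s.shape} q{q.shape}"
        )
    return float(np.sum(e * q + s * q * q))


def _check_hardness(s: np.ndarray) -> None:
    bad = np.nonzero(s <= HARDNESS_FLOOR)[0]
    if bad.size:
        raise HardnessError(
            f"hardness at atom(s) {bad.tolist()} is <= {HARDNESS_FLOOR}; "
            "the charging energy must be strictly convex"
        )


def qeq_solve(cp: ChargeParams, Q: float, name: str = "") -> ChargeResult:
    """Analytic constrained minimizer of the charging energy for one molecule."""
    e = cp.e
    s = cp.s
    if e.size == 0:
        raise EmptyMoleculeError("cannot equilibrate charges on an empty molecule")
    _check_hardness(s)
    b = 1.0 / (2.0 * s)
    lam = (Q + np.sum(e * b)) / np.sum(b)
    q = b * (lam - e)
    if not np.all(np.isfinite(q)):
        raise NumericalError("non-finite charges from charge equilibration")
    return ChargeResult(q=q, Q=float(Q), energy=charging_energy(e, s, q), name=name)


def qeq_solve_batch(
    e: np.ndarray,
    s: np.ndarray,
    total_charges: np.ndarray,
    segment_ids: np.ndarray,
) -> np.ndarray:
    """Equilibrate every molecule of a batch with its own Lagrange multiplier.

    ``segment_ids`` assigns each atom to its molecule; the two reductions run
    segment-wise, so a block-diagonal batch gives results identical to
    molecule-by-molecule solves. A single global constraint over the batch
    would be wrong — each molecule conserves its own Q.
    """
    e = np.asarray(e, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    seg = np.asarray(segment_ids)
    if e.size == 0:
        raise EmptyMoleculeError("empty batch")
    _check_hardness(s)
    n_mol = int(seg.max()) + 1
    if len(total_charges) != n_mol:
        raise DimensionError(
            f"{len(total_charges)} total charges for {n_mol} molecules in batch"
        )
    b = 1.0 / (2.0 * s)
    sum_b = np.bincount(seg, weights=b, minlength=n_mol)
    sum_eb = np.bincount(seg, weights=e * b, minlength=n_mol)
    lam = (np.asarray(total_charges, dtype=np.float64) + sum_eb) / sum_b
    q = b * (lam[seg] - e)
    if not np.all(np.isfinite(q)):
        raise NumericalError("non-finite charges from batched charge equilibration")
    return q


def qeq_backward_from_solution(
    e: np.ndarray,
    s: np.ndarray,
    q: np.ndarray,
    segment_ids: np.ndarray,
    grad_q: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint of the analytic solve, given the forward solution q.

    With b_i = 1/(2 s_i), B_m = sum b, and gB_m = sum g_i b_i over molecule m:
      dL/de_i = -g_i b_i + (gB_m / B_m) b_i
      dL/db_i = g_i (lam_m - e_i) - (gB_m / B_m)(lam_m - e_i)
      dL/ds_i = dL/db_i * (-2 b_i^2)
    where (lam_m - e_i) = q_i / b_i.
    """
    e = np.asarray(e, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    seg = np.asarray(segment_ids)
    g = np.asarray(grad_q, dtype=np.float64)
    n_mol = int(seg.max()) + 1
    b = 1.0 / (2.0 * s)
    sum_b = np.bincount(seg, weights=b, minlength=n_mol)
    g_b = np.bincount(seg, weights=g * b, minlength=n_mol)
    ratio = (g_b / sum_b)[seg]
    de = b * (ratio - g)
    lam_minus_e = q / b
    db = (g - ratio) * lam_minus_e
    ds = db * (-2.0 * b * b)
    return de, ds
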