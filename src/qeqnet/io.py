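"""Reading molecules and writing charge-annotated records.

Input formats: SMILES (one record per line, optional name), SDF (V2000) and
TRIPOS MOL2. RDKit does the SMILES/SDF heavy lifting; hydrogens are always
made explicit before graph construction because charges must be assigned to
every particle of a molecular-mechanics topology.

MOL2 is handled by a small reader/writer pair of our own (RDKit writes no
MOL2, and its reader expects SYBYL atom typing): the writer puts partial
charges in the standard per-atom charge column with the charge-type line set
to ``QEQNET_CHARGES``, elements as plain atom types, and nonzero formal
charges in a ``@<TRIPOS>UNITY_ATOM_ATTR`` section, which the reader consumes.
No 3D information is used anywhere — coordinates are written as zeros.

Written charges are rounded to six decimals with a sum-preserving repair:
any rounding residual is folded into the largest-|q| atom so the written
charges sum to the molecule's integer total charge exactly.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .chem import Atom, FeaturizationConfig, Molecule, total_formal_charge
from .errors import FormatError, ParseError, UnsupportedElementError
from .qeq import ChargeResult

RDLogger.DisableLog("rdApp.*")

FORMATS = ("smiles", "sdf", "mol2")
#: SDF property tag carrying per-atom partial charges, one value per line.
SDF_CHARGE_TAG = "PARTIAL_CHARGES"
#: charge-type label written on the MOL2 molecule record.
MOL2_CHARGE_TYPE = "QEQNET_CHARGES"
WRITER_DECIMALS = 6


# ----------------------------------------------------------------- conversion

def molecule_from_rdkit(rdmol: Chem.Mol, name: str = "") -> Molecule:
    """Convert an RDKit molecule (explicit H already added) to a Molecule."""
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()]
    if not name and rdmol.HasProp("_Name"):
        name = rdmol.GetProp("_Name")
    return Molecule(atoms=atoms, bonds=bonds, name=name, rdmol=rdmol)


def molecule_to_rdkit(mol: Molecule) -> Chem.Mol:
    """Best-effort RDKit molecule for writing.

    Uses the cached parse result when available (preserving bond orders);
    otherwise reconstructs with single bonds, which is exact for the
    synthetic tree molecules this package generates.
    """
    if mol.rdmol is not None:
        return mol.rdmol
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for i, j in mol.bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(
        out,
        Chem.SanitizeFlags.SANITIZE_SYMMRINGS
        | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION,
        catchErrors=True,
    )
    out.SetProp("_Name", mol.name)
    return out


def _validate_vocabulary(mol: Molecule, scheme: FeaturizationConfig) -> None:
    for a in mol.atoms:
        if a.element not in scheme.elements:
            raise UnsupportedElementError(
                f"molecule {mol.name!r}: element {a.element!r} is outside the "
                f"featurization vocabulary {scheme.elements}"
            )


# -------------------------------------------------------------------- parsing

def parse_molecule(
    source: str,
    fmt: str,
    scheme: FeaturizationConfig | None = None,
    name: str = "",
) -> Molecule:
    """Parse one record; explicit hydrogens are added when the format omits them.

    Raises :class:`ParseError` naming the offending record on syntax failure
    and :class:`UnsupportedElementError` for out-of-vocabulary elements.
    """
    scheme = scheme or FeaturizationConfig()
    if fmt not in FORMATS:
        raise FormatError(f"unsupported format {fmt!r}; expected one of {FORMATS}")
    label = name or source.strip().splitlines()[0][:60] if source.strip() else "<empty>"
    if fmt == "smiles":
        rd = Chem.MolFromSmiles(source.strip().split()[0]) if source.strip() else None
        if rd is None:
            raise ParseError(f"cannot parse SMILES record {label!r}")
        rd = Chem.AddHs(rd)
        parts = source.strip().split(None, 1)
        if not name and len(parts) > 1:
            name = parts[1].strip()
    elif fmt == "sdf":
        rd = Chem.MolFromMolBlock(source, removeHs=False, sanitize=True)
        if rd is None:
            raise ParseError(f"cannot parse SDF record {label!r}")
        rd = Chem.AddHs(rd)
    else:
        return _parse_mol2(source, scheme, name)
    mol = molecule_from_rdkit(rd, name)
    _validate_vocabulary(mol, scheme)
    return mol


@dataclass
class ParsedRecord:
    """Outcome of parsing one record from a multi-record file."""

    index: int
    name: str
    molecule: Optional[Molecule]
    error: Optional[str] = None


def read_molecules(
    text: str, fmt: str, scheme: FeaturizationConfig | None = None
) -> list[ParsedRecord]:
    """Parse a whole file's text; per-record failures become error entries."""
    scheme = scheme or FeaturizationConfig()
    if fmt not in FORMATS:
        raise FormatError(f"unsupported format {fmt!r}; expected one of {FORMATS}")
    records: list[ParsedRecord] = []

    def attempt(index: int, source: str, name: str = "") -> None:
        try:
            mol = parse_molecule(source, fmt, scheme, name)
            records.append(ParsedRecord(index, mol.name, mol))
        except Exception as exc:  # typed errors plus RDKit surprises
            records.append(
                ParsedRecord(index, name or f"record-{index}", None, str(exc))
            )

    if fmt == "smiles":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for i, line in enumerate(lines):
            attempt(i, line)
    elif fmt == "sdf":
        for i, block in enumerate(_split_sdf(text)):
            attempt(i, block)
    else:
        for i, block in enumerate(_split_mol2(text)):
            attempt(i, block)
    return records


def _split_sdf(text: str) -> list[str]:
    blocks = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append("\n".join(current) + "\n")
            current = []
        else:
            current.append(line)
    if any(ln.strip() for ln in current):
        blocks.append("\n".join(current) + "\n")
    return blocks


def _split_mol2(text: str) -> list[str]:
    blocks = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "@<TRIPOS>MOLECULE" and current:
            blocks.append("\n".join(current) + "\n")
            current = [line]
        else:
            current.append(line)
    if any(ln.strip() for ln in current):
        blocks.append("\n".join(current) + "\n")
    return blocks


def _normalize_element(token: str) -> str:
    sym = token.split(".")[0]
    return sym[:1].upper() + sym[1:].lower()


def _parse_mol2(
    source: str, scheme: FeaturizationConfig, name: str = ""
) -> Molecule:
    """Minimal TRIPOS MOL2 reader (the dialect the writer emits).

    Elements come from the atom-type column, aromatic flags from ``.ar``
    types or ``ar`` bonds, formal charges from ``@<TRIPOS>UNITY_ATOM_ATTR``
    (defaulting to zero when the section is absent). Hydrogens must already
    be explicit in the file.
    """
    lines = source.splitlines()
    section = None
    mol_header: list[str] = []
    atom_lines: list[str] = []
    bond_lines: list[str] = []
    attr_lines: list[str] = []
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[len("@<TRIPOS>"):].upper()
            continue
        if not stripped or stripped.startswith("#"):
            continue
        if section == "MOLECULE":
            mol_header.append(stripped)
        elif section == "ATOM":
            atom_lines.append(stripped)
        elif section == "BOND":
            bond_lines.append(stripped)
        elif section == "UNITY_ATOM_ATTR":
            attr_lines.append(stripped)
    if not atom_lines:
        raise ParseError(f"MOL2 record {name or '<unnamed>'!r} has no ATOM section")
    rec_name = name or (mol_header[0] if mol_header else "")

    elements: list[str] = []
    aromatic: list[bool] = []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 6:
            raise ParseError(f"malformed MOL2 atom line in {rec_name!r}: {ln!r}")
        typ = parts[5]
        elements.append(_normalize_element(typ))
        aromatic.append(typ.lower().endswith(".ar"))

    bonds: list[tuple[int, int]] = []
    for ln in bond_lines:
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"malformed MOL2 bond line in {rec_name!r}: {ln!r}")
        i, j = int(parts[1]) - 1, int(parts[2]) - 1
        bonds.append((i, j))
        if parts[3].lower() == "ar":
            aromatic[i] = True
            aromatic[j] = True

    formal = [0] * len(elements)
    k = 0
    while k < len(attr_lines):
        head = attr_lines[k].split()
        idx, n_attr = int(head[0]) - 1, int(head[1])
        for a in range(n_attr):
            k += 1
            key, value = attr_lines[k].split()[:2]
            if key.lower() == "charge":
                formal[idx] = int(round(float(value)))
        k += 1

    atoms = [
        Atom(element=el, formal_charge=fc, aromatic=ar)
        for el, fc, ar in zip(elements, formal, aromatic)
    ]
    mol = Molecule(atoms=atoms, bonds=bonds, name=rec_name)
    _validate_vocabulary(mol, scheme)
    return mol


# -------------------------------------------------------------------- writing

def round_preserving_sum(
    q: np.ndarray, total: float, decimals: int = WRITER_DECIMALS
) -> np.ndarray:
    """Round charges to fixed precision, repairing the sum.

    Naive rounding can break conservation by a few units in the last place;
    the residual is folded into the atom with the largest |q|, where it is
    relatively smallest.
    """
    q = np.asarray(q, dtype=np.float64)
    rounded = np.round(q, decimals)
    residual = round(float(total - rounded.sum()), decimals + 2)
    if residual != 0.0:
        k = int(np.argmax(np.abs(rounded)))
        rounded[k] = round(rounded[k] + residual, decimals)
    return rounded


def write_charges(mol: Molecule, charges: np.ndarray, fmt: str) -> str:
    """Serialize one charge-annotated record in SDF or MOL2.

    Atom order is preserved from the input; charges are rounded with the
    sum-preserving repair before writing.
    """
    charges = np.asarray(charges, dtype=np.float64)
    if charges.shape[0] != mol.num_atoms:
        raise FormatError(
            f"molecule {mol.name!r}: {charges.shape[0]} charges for "
            f"{mol.num_atoms} atoms"
        )
    q = round_preserving_sum(charges, float(total_formal_charge(mol)))
    if fmt == "sdf":
        return _write_sdf_record(mol, q)
    if fmt == "mol2":
        return _write_mol2_record(mol, q)
    raise FormatError(f"unsupported output format {fmt!r}; expected sdf or mol2")


def _write_sdf_record(mol: Molecule, q: np.ndarray) -> str:
    rd = molecule_to_rdkit(mol)
    block = Chem.MolToMolBlock(rd, kekulize=True)
    tag = "\n".join(f"{v:.{WRITER_DECIMALS}f}" for v in q)
    return f"{block}>  <{SDF_CHARGE_TAG}>\n{tag}\n\n$$$$\n"


def _write_mol2_record(mol: Molecule, q: np.ndarray) -> str:
    out = _io.StringIO()
    out.write("@<TRIPOS>MOLECULE\n")
    out.write(f"{mol.name or 'UNNAMED'}\n")
    out.write(f"{mol.num_atoms:>5d} {len(mol.bonds):>5d} 0 0 0\n")
    out.write("SMALL\n")
    out.write(f"{MOL2_CHARGE_TYPE}\n")
    out.write("@<TRIPOS>ATOM\n")
    counts: dict[str, int] = {}
    for i, (a, qi) in enumerate(zip(mol.atoms, q), start=1):
        counts[a.element] = counts.get(a.element, 0) + 1
        atom_name = f"{a.element}{counts[a.element]}"
        typ = f"{a.element}.ar" if a.aromatic else a.element
        out.write(
            f"{i:>7d} {atom_name:<6s} {0.0:>9.4f} {0.0:>9.4f} {0.0:>9.4f} "
            f"{typ:<6s} 1 MOL {qi:>10.{WRITER_DECIMALS}f}\n"
        )
    out.write("@<TRIPOS>BOND\n")
    rd = mol.rdmol
    for bi, (i, j) in enumerate(mol.bonds, start=1):
        order = "1"
        if rd is not None:
            b = rd.GetBondBetweenAtoms(i, j)
            if b is not None:
                order = {
                    Chem.BondType.SINGLE: "1",
                    Chem.BondType.DOUBLE: "2",
                    Chem.BondType.TRIPLE: "3",
                    Chem.BondType.AROMATIC: "ar",
                }.get(b.GetBondType(), "1")
        out.write(f"{bi:>6d} {i + 1:>5d} {j + 1:>5d} {order}\n")
    charged = [(i, a.formal_charge) for i, a in enumerate(mol.atoms) if a.formal_charge]
    if charged:
        out.write("@<TRIPOS>UNITY_ATOM_ATTR\n")
        for i, fc in charged:
            out.write(f"{i + 1} 1\ncharge {fc}\n")
    return out.getvalue()


def read_charges(text: str, fmt: str) -> list[tuple[Molecule, np.ndarray]]:
    """Read charge-annotated records back (SDF property tag or MOL2 column)."""
    out: list[tuple[Molecule, np.ndarray]] = []
    if fmt == "sdf":
        supplier = Chem.ForwardSDMolSupplier(
            _io.BytesIO(text.encode()), removeHs=False, sanitize=True
        )
        for rd in supplier:
            if rd is None:
                raise ParseError("unreadable SDF record while reading charges")
            if not rd.HasProp(SDF_CHARGE_TAG):
                raise ParseError(
                    f"SDF record {rd.GetProp('_Name') if rd.HasProp('_Name') else '?'!r} "
                    f"lacks the {SDF_CHARGE_TAG} tag"
                )
            q = np.array([float(v) for v in rd.GetProp(SDF_CHARGE_TAG).split()])
            out.append((molecule_from_rdkit(rd), q))
    elif fmt == "mol2":
        for block in _split_mol2(text):
            mol = _parse_mol2(block, FeaturizationConfig())
            q = []
            section = None
            for ln in block.splitlines():
                stripped = ln.strip()
                if stripped.startswith("@<TRIPOS>"):
                    section = stripped[len("@<TRIPOS>"):].upper()
                    continue
                if section == "ATOM" and stripped:
                    q.append(float(stripped.split()[8]))
            out.append((mol, np.array(q)))
    else:
        raise FormatError(f"unsupported charge format {fmt!r}; expected sdf or mol2")
    return out


def write_charge_file(
    records: Sequence[tuple[Molecule, np.ndarray]], path: str, fmt: str
) -> None:
    """Write all records to ``path`` atomically (temp file + rename)."""
    text = "".join(write_charges(mol, q, fmt) for mol, q in records)
    tmp = f"{path}.tmp.{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


# --------------------------------------------------------------- dataset (SDF)

def write_charge_dataset(
    records: Sequence[tuple[Molecule, np.ndarray]], path: str
) -> None:
    """Persist a labeled training set as SDF with the per-atom charge tag."""
    write_charge_file(records, path, "sdf")


def read_charge_dataset(path: str) -> list[tuple[Molecule, np.ndarray]]:
    with open(path) as fh:
        return read_charges(fh.read(), "sdf")
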