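"""Domain records and the on-disk dataset schema.

The package couples three record kinds per molecule:

* :class:`MoleculeRecord` — identity, topology and 3-D geometry (Å);
* :class:`ElectronicRecord` — the low-level (semiempirical, ZINDO-type)
  excited-state data: S1 energy in eV, oscillator strength, and per-atom
  Mulliken charges, atomic potentials, HOMO populations and particle/hole
  densities of the S0→S1 transition;
* :class:`TargetRecord` — the high-level (TDDFT-type) S1 energy and
  oscillator strength used as the regression target.

Geometry travels as SDF V2000 (with a ``precise_coords`` property holding
full double-precision coordinates, since the V2000 coordinate block is fixed
at four decimals) or as XYZ files plus an ``id,smiles`` CSV.  Electronic and
target records are versioned JSON with explicit per-atom arrays; this package
deliberately does not parse quantum-chemistry log files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

SCHEMA_VERSION = "1.0"

_PT = Chem.GetPeriodicTable()


def atomic_number(symbol: str) -> int:
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        z = 0
    if z <= 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return z


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass
class MoleculeRecord:
    """One molecule: atoms, nuclear charges, Cartesian coordinates (Å) and
    bond list.  ``hac`` is the heavy-atom (non-hydrogen) count."""

    id: str
    smiles: str
    elements: list[str]
    Z: np.ndarray
    coords: np.ndarray
    bonds: list[tuple[int, int, float, bool]]  # (i, j, order, aromatic)
    hac: int = field(default=-1)
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if not (len(self.Z) == n and self.coords.shape == (n, 3)):
            raise ValueError(f"molecule {self.id}: elements/Z/coords length mismatch")
        for sym, z in zip(self.elements, self.Z):
            if atomic_number(sym) != int(z):
                raise ValueError(f"molecule {self.id}: element {sym} does not match Z={z}")
        for i, j, *_ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id}: bond ({i},{j}) out of range")
        heavy = sum(1 for s in self.elements if s != "H")
        if self.hac < 0:
            self.hac = heavy
        elif self.hac != heavy:
            raise ValueError(f"molecule {self.id}: hac {self.hac} != non-H count {heavy}")
        if n > 1:
            d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 0:
                raise ValueError(f"molecule {self.id}: coincident atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str, smiles: str | None = None) -> "MoleculeRecord":
        if mol.GetNumConformers() == 0:
            raise ValueError(f"molecule {mol_id}: no conformer (3-D coordinates required)")
        conf = mol.GetConformer()
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        Z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=float)
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(), b.GetIsAromatic())
            for b in mol.GetBonds()
        ]
        if smiles is None:
            smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))
        return cls(mol_id, smiles, elements, Z, coords, bonds, _mol=mol)

    def to_rdkit(self) -> Chem.Mol:
        """RDKit molecule with atom order matching this record."""
        if self._mol is not None:
            return self._mol
        em = Chem.RWMol()
        for sym in self.elements:
            em.AddAtom(Chem.Atom(sym))
        order_map = {
            1.0: Chem.BondType.SINGLE,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
            1.5: Chem.BondType.AROMATIC,
        }
        for i, j, order, arom in self.bonds:
            bidx = em.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE)) - 1
            if arom:
                em.GetBondWithIdx(bidx).SetIsAromatic(True)
                em.GetAtomWithIdx(int(i)).SetIsAromatic(True)
                em.GetAtomWithIdx(int(j)).SetIsAromatic(True)
        mol = em.GetMol()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
        mol.AddConformer(conf)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            pass  # featurization falls back to the SMILES-derived graph
        self._mol = mol
        return mol


def _per_atom(name, arr, n, mol_id):
    a = np.asarray(arr, dtype=float)
    if a.shape != (n,):
        raise ValueError(
            f"molecule {mol_id}: per-atom array {name!r} has length {a.shape}, expected {n}"
        )
    return a


@dataclass
class ElectronicRecord:
    """Low-level electronic data for one molecule.

    ``n_elec``/``n_hole`` are per-atom populations of the S1 particle and
    hole natural transition orbitals (each summing to 1); ``w_homo`` is the
    per-atom HOMO population used to weight the MO-RDF.
    """

    molecule_id: str
    e_s1_low: float
    f_low: float | None
    mulliken: np.ndarray
    potential: np.ndarray
    n_elec: np.ndarray
    n_hole: np.ndarray
    w_homo: np.ndarray

    def validate(self, n_atoms: int, tol: float = 1e-6) -> None:
        for name in ("mulliken", "potential", "n_elec", "n_hole", "w_homo"):
            setattr(self, name, _per_atom(name, getattr(self, name), n_atoms, self.molecule_id))
        for name in ("n_elec", "n_hole", "w_homo"):
            v = getattr(self, name)
            if np.any(v < -tol):
                raise ValueError(f"molecule {self.molecule_id}: negative entries in {name}")
        for name in ("n_elec", "n_hole"):
            s = getattr(self, name).sum()
            if abs(s - 1.0) > tol:
                raise ValueError(
                    f"molecule {self.molecule_id}: {name} sums to {s:.8f}, expected 1"
                )
        if self.f_low is not None and self.f_low < 0:
            raise ValueError(f"molecule {self.molecule_id}: negative oscillator strength")


@dataclass
class TargetRecord:
    molecule_id: str
    e_s1_high: float
    f_high: float | None = None

    def validate(self) -> None:
        if not math.isfinite(self.e_s1_high) or self.e_s1_high <= 0:
            raise ValueError(f"molecule {self.molecule_id}: nonphysical target energy")


@dataclass
class PredictionRecord:
    molecule_id: str
    e_pred: float
    delta_pred: float
    per_fold_preds: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.per_fold_preds:
            m = float(np.mean(self.per_fold_preds))
            if abs(m - self.e_pred) > 1e-9:
                raise ValueError(
                    f"molecule {self.molecule_id}: e_pred {self.e_pred} != fold mean {m}"
                )


@dataclass
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]
    fold_assignments: dict[str, int]

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")
        if self.fold_assignments:
            if set(self.fold_assignments) != set(self.train_ids):
                raise ValueError("fold assignments must cover exactly the train ids")

    @property
    def k(self) -> int:
        return 1 + max(self.fold_assignments.values()) if self.fold_assignments else 0

    def fold_ids(self, fold: int) -> tuple[list[str], list[str]]:
        """(train-portion, validation-portion) ids for one fold."""
        val = [i for i in self.train_ids if self.fold_assignments[i] == fold]
        trn = [i for i in self.train_ids if self.fold_assignments[i] != fold]
        return trn, val


# ---------------------------------------------------------------------------
# joined dataset
# ---------------------------------------------------------------------------


class Dataset:
    """Joined molecule + electronic + target records, keyed by molecule id."""

    def __init__(
        self,
        molecules: list[MoleculeRecord],
        electronic: list[ElectronicRecord] | None = None,
        targets: list[TargetRecord] | None = None,
    ):
        self.molecules = {m.id: m for m in molecules}
        if len(self.molecules) != len(molecules):
            raise ValueError("duplicate molecule ids")
        self.electronic = {e.molecule_id: e for e in (electronic or [])}
        self.targets = {t.molecule_id: t for t in (targets or [])}
        for mid, e in self.electronic.items():
            if mid not in self.molecules:
                raise ValueError(f"electronic record references unknown molecule {mid!r}")
            e.validate(self.molecules[mid].n_atoms)
        for mid, t in self.targets.items():
            if mid not in self.molecules:
                raise ValueError(f"target record references unknown molecule {mid!r}")
            t.validate()

    @property
    def ids(self) -> list[str]:
        return list(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    def subset(self, ids) -> "Dataset":
        ids = list(ids)
        return Dataset(
            [self.molecules[i] for i in ids],
            [self.electronic[i] for i in ids if i in self.electronic],
            [self.targets[i] for i in ids if i in self.targets],
        )

    def complete_ids(self) -> tuple[list[str], dict[str, str]]:
        """Ids having all three records, plus a {dropped_id: reason} report."""
        kept, dropped = [], {}
        for mid in self.molecules:
            if mid not in self.electronic:
                dropped[mid] = "missing electronic record"
            elif mid not in self.targets:
                dropped[mid] = "missing target record"
            else:
                kept.append(mid)
        return kept, dropped

    def to_frame(self) -> pd.DataFrame:
        """Molecule-level scalar view (id, smiles, hac, energies, f)."""
        rows = []
        for mid, m in self.molecules.items():
            e = self.electronic.get(mid)
            t = self.targets.get(mid)
            rows.append(
                {
                    "id": mid,
                    "smiles": m.smiles,
                    "hac": m.hac,
                    "e_s1_low": e.e_s1_low if e else np.nan,
                    "f_low": (e.f_low if e and e.f_low is not None else np.nan),
                    "e_s1_high": t.e_s1_high if t else np.nan,
                    "f_high": (t.f_high if t and t.f_high is not None else np.nan),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def residual_delta(e_high, e_low):
    """Residual between the high-level and low-level S1 energies (eV),
    ΔE = E_high − E_low.  Accepts scalars or arrays; rejects non-finite
    input."""
    e_high = np.asarray(e_high, dtype=float)
    e_low = np.asarray(e_low, dtype=float)
    if not (np.all(np.isfinite(e_high)) and np.all(np.isfinite(e_low))):
        raise ValueError("residual_delta requires finite energies")
    out = e_high - e_low
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# on-disk schema
# ---------------------------------------------------------------------------


def _fmt(x: float) -> float:
    return float(x)  # json serialises python floats at full precision (repr)


def write_dataset(dataset: Dataset, out_dir: str) -> None:
    """Write molecules.sdf + molecules.csv + electronic.json + targets.json."""
    os.makedirs(out_dir, exist_ok=True)
    writer = Chem.SDWriter(os.path.join(out_dir, "molecules.sdf"))
    writer.SetForceV3000(False)
    for mid, m in dataset.molecules.items():
        mol = Chem.Mol(m.to_rdkit())
        mol.SetProp("_Name", mid)
        mol.SetProp("smiles", m.smiles)
        # V2000 coordinates are 4-decimal; carry full precision separately
        mol.SetProp(
            "precise_coords",
            "\n".join(" ".join(repr(float(v)) for v in row) for row in m.coords),
        )
        writer.write(mol)
    writer.close()
    pd.DataFrame(
        {"id": list(dataset.molecules), "smiles": [m.smiles for m in dataset.molecules.values()]}
    ).to_csv(os.path.join(out_dir, "molecules.csv"), index=False)
    elec = {
        "schema_version": SCHEMA_VERSION,
        "records": [
            {
                "molecule_id": e.molecule_id,
                "e_s1_low": _fmt(e.e_s1_low),
                "f_low": None if e.f_low is None else _fmt(e.f_low),
                "mulliken": [_fmt(v) for v in e.mulliken],
                "potential": [_fmt(v) for v in e.potential],
                "n_elec": [_fmt(v) for v in e.n_elec],
                "n_hole": [_fmt(v) for v in e.n_hole],
                "w_homo": [_fmt(v) for v in e.w_homo],
            }
            for e in dataset.electronic.values()
        ],
    }
    with open(os.path.join(out_dir, "electronic.json"), "w") as fh:
        json.dump(elec, fh)
    targ = {
        "schema_version": SCHEMA_VERSION,
        "records": [
            {
                "molecule_id": t.molecule_id,
                "e_s1_high": _fmt(t.e_s1_high),
                "f_high": None if t.f_high is None else _fmt(t.f_high),
            }
            for t in dataset.targets.values()
        ],
    }
    with open(os.path.join(out_dir, "targets.json"), "w") as fh:
        json.dump(targ, fh)


def _read_molecules_sdf(path: str) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
    out = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record at index {idx} in {path}")
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            pass
        mid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        smiles = mol.GetProp("smiles") if mol.HasProp("smiles") else Chem.MolToSmiles(mol)
        rec = MoleculeRecord.from_rdkit(mol, mid, smiles)
        if mol.HasProp("precise_coords"):
            rows = [
                [float(v) for v in line.split()]
                for line in mol.GetProp("precise_coords").strip().splitlines()
            ]
            coords = np.asarray(rows, dtype=float)
            if coords.shape != rec.coords.shape:
                raise ValueError(f"molecule {mid}: precise_coords atom-count mismatch")
            rec.coords = coords
            if rec._mol is not None:
                conf = rec._mol.GetConformer()
                for i, xyz in enumerate(coords):
                    conf.SetAtomPosition(i, [float(v) for v in xyz])
        out.append(rec)
    return out


def _read_xyz(path: str, mol_id: str, smiles: str) -> MoleculeRecord:
    with open(path) as fh:
        lines = fh.read().strip().splitlines()
    n = int(lines[0].strip())
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise ValueError(f"molecule {mol_id}: XYZ atom-count mismatch in {path}")
    elements, coords = [], []
    for line in body:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    Z = [atomic_number(s) for s in elements]
    graph = Chem.MolFromSmiles(smiles)
    bonds = []
    if graph is not None and graph.GetNumAtoms() == sum(1 for s in elements if s != "H"):
        # heavy-atom-only geometry whose order matches the canonical SMILES graph
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(), b.GetIsAromatic())
            for b in graph.GetBonds()
        ]
    return MoleculeRecord(mol_id, smiles, elements, np.array(Z, float), np.array(coords), bonds)


def _read_molecules_xyz(xyz_dir: str, csv_path: str) -> list[MoleculeRecord]:
    table = pd.read_csv(csv_path, dtype={"id": str})
    if not {"id", "smiles"} <= set(table.columns):
        raise ValueError("molecule CSV must have columns id,smiles")
    out = []
    for _, row in table.iterrows():
        path = os.path.join(xyz_dir, f"{row['id']}.xyz")
        if not os.path.exists(path):
            raise ValueError(f"molecule {row['id']}: missing XYZ file {path}")
        out.append(_read_xyz(path, str(row["id"]), row["smiles"]))
    return out


def _load_json_records(path: str, kind: str) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if "schema_version" not in doc:
        raise ValueError(f"{kind} file {path} lacks schema_version")
    return doc["records"]


def read_dataset(
    molecule_file: str,
    electronic_file: str | None = None,
    target_file: str | None = None,
    molecule_csv: str | None = None,
) -> tuple[Dataset, dict[str, str]]:
    """Read and join the dataset; returns (dataset, drop_report).

    ``molecule_file`` is an SDF path or a directory of ``<id>.xyz`` files
    (the latter requires ``molecule_csv`` with columns ``id,smiles``).
    Records missing from the electronic/target files are reported and
    dropped; structural inconsistencies (per-atom array length vs atom
    count, unknown elements) are hard errors naming the molecule.
    """
    if os.path.isdir(molecule_file):
        if molecule_csv is None:
            molecule_csv = os.path.join(os.path.dirname(molecule_file.rstrip("/")), "molecules.csv")
        molecules = _read_molecules_xyz(molecule_file, molecule_csv)
    else:
        molecules = _read_molecules_sdf(molecule_file)
    by_id = {m.id: m for m in molecules}

    electronic = []
    if electronic_file:
        for rec in _load_json_records(electronic_file, "electronic"):
            mid = rec["molecule_id"]
            if mid not in by_id:
                raise ValueError(f"electronic record references unknown molecule {mid!r}")
            e = ElectronicRecord(
                molecule_id=mid,
                e_s1_low=float(rec["e_s1_low"]),
                f_low=None if rec.get("f_low") is None else float(rec["f_low"]),
                mulliken=rec["mulliken"],
                potential=rec["potential"],
                n_elec=rec["n_elec"],
                n_hole=rec["n_hole"],
                w_homo=rec["w_homo"],
            )
            e.validate(by_id[mid].n_atoms)
            electronic.append(e)
    targets = []
    if target_file:
        for rec in _load_json_records(target_file, "target"):
            mid = rec["molecule_id"]
            if mid not in by_id:
                raise ValueError(f"target record references unknown molecule {mid!r}")
            t = TargetRecord(
                mid,
                float(rec["e_s1_high"]),
                None if rec.get("f_high") is None else float(rec["f_high"]),
            )
            t.validate()
            targets.append(t)

    ds = Dataset(molecules, electronic, targets)
    report: dict[str, str] = {}
    if electronic_file and target_file:
        kept, report = ds.complete_ids()
        ds = ds.subset(kept)
    return ds, report
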