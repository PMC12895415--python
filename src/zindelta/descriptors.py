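"""Electronic and structural molecular descriptors.

Implements the descriptor family used by the delta-learning models:

* ``atomic_potential`` — per-atom Coulomb-like potentials
  phi_i = sum_{j != i} Z_j / r_ij (e/Å), hydrogens included in the sum;
* ``population_from_orbital`` — Mulliken-style per-atom populations of an
  orbital in an orthogonalised basis, p_i = sum_{mu in i} c_mu^2 / sum c^2;
* ``particle_hole_densities`` — the same analysis applied to the dominant
  natural-transition-orbital pair of the S0→S1 excitation;
* ``mo_rdf`` — the molecular-orbital-weighted radial distribution function
  f(r) = sum_{i>j} w_i w_j g(r − d_ij) with a normalised Gaussian kernel
  (sigma = 0.05 Å) sampled on a fixed 0.5–15 Å grid of 726 points;
* ``morgan_fingerprint`` — 2048-bit radius-2 circular fingerprints;
* graph node/edge featurisation for the message-passing encoder: 41 default
  atom (DA) channels, extended to 45 with the four electronic atom (EA)
  scalars (Mulliken charge, atomic potential, particle and hole density),
  each z-scored with training-set statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .records import ElectronicRecord, MoleculeRecord

__all__ = [
    "MoRdfGrid",
    "DEFAULT_GRID",
    "atomic_potential",
    "population_from_orbital",
    "particle_hole_densities",
    "mo_rdf",
    "morgan_fingerprint",
    "atom_features",
    "bond_features",
    "build_node_features",
    "build_edge_features",
    "molecular_graph",
    "EaStandardizer",
    "N_DA_CHANNELS",
    "N_EA_CHANNELS",
    "N_EDGE_CHANNELS",
]


# ---------------------------------------------------------------------------
# MO-RDF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoRdfGrid:
    """Radial grid for the MO-RDF: inclusive endpoints, default
    0.5–15.0 Å at 0.02 Å spacing with a 0.05 Å Gaussian width, giving a
    726-point feature vector."""

    r_min: float = 0.5
    r_max: float = 15.0
    step: float = 0.02
    sigma: float = 0.05

    def __post_init__(self):
        if self.step <= 0 or self.sigma <= 0 or self.r_max <= self.r_min:
            raise ValueError("invalid MO-RDF grid")

    @property
    def n_points(self) -> int:
        return int(round((self.r_max - self.r_min) / self.step)) + 1

    @property
    def r(self) -> np.ndarray:
        return self.r_min + self.step * np.arange(self.n_points)


DEFAULT_GRID = MoRdfGrid()


def _pair_distances(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    return iu, ju, d


def atomic_potential(Z, coords, min_distance: float = 1e-6) -> np.ndarray:
    """Per-atom potentials phi_i = sum_{j != i} Z_j / r_ij in e/Å.

    All atoms contribute — hydrogens are not filtered.  A single atom has an
    empty sum (phi = 0).  Coincident atoms are a hard error naming the pair.
    """
    Z = np.asarray(Z, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(Z)
    if n == 0:
        raise ValueError("atomic_potential requires at least one atom")
    if coords.shape != (n, 3):
        raise ValueError("Z and coords length mismatch")
    if n == 1:
        return np.zeros(1)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    bad = np.argwhere((r < min_distance) & off)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"coincident atoms {i} and {j} (r = {r[i, j]:.2e} Å)")
    inv = np.where(off, 1.0 / np.where(off, r, 1.0), 0.0)
    return inv @ Z


def population_from_orbital(coeffs, basis_to_atom, n_atoms: int | None = None) -> np.ndarray:
    """Normalised per-atom populations of one orbital.

    In an orthogonalised (INDO-type) basis the Mulliken population of atom i
    reduces to the sum of squared coefficients of its basis functions:
    p_i = sum_{mu in i} c_mu^2 / sum_mu c_mu^2, so sum_i p_i = 1.
    """
    c = np.asarray(coeffs, dtype=float)
    idx = np.asarray(basis_to_atom, dtype=int)
    if c.shape != idx.shape:
        raise ValueError("coeffs and basis_to_atom length mismatch")
    norm = float(np.sum(c * c))
    if norm == 0.0:
        raise ValueError("all-zero orbital coefficients")
    if n_atoms is None:
        n_atoms = int(idx.max()) + 1
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise ValueError("basis_to_atom maps outside the atom range")
    return np.bincount(idx, weights=c * c, minlength=n_atoms) / norm


def particle_hole_densities(
    hole_coeffs,
    particle_coeffs,
    basis_to_atom,
    n_atoms: int | None = None,
    singular_values=None,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_hole, n_elec) per-atom densities from the dominant NTO pair.

    With ``singular_values``, ``hole_coeffs``/``particle_coeffs`` are lists
    of orbital vectors (one per NTO pair) and the per-pair populations are
    averaged with weights s_k^2 / sum s^2; both outputs still sum to 1.
    """
    if singular_values is None:
        n_hole = population_from_orbital(hole_coeffs, basis_to_atom, n_atoms)
        n_elec = population_from_orbital(particle_coeffs, basis_to_atom, n_atoms)
        return n_hole, n_elec
    sv = np.asarray(singular_values, dtype=float)
    if len(sv) != len(hole_coeffs) or len(sv) != len(particle_coeffs):
        raise ValueError("one singular value per NTO pair required")
    weights = sv**2 / np.sum(sv**2)
    n_hole = sum(
        w * population_from_orbital(h, basis_to_atom, n_atoms)
        for w, h in zip(weights, hole_coeffs)
    )
    n_elec = sum(
        w * population_from_orbital(p, basis_to_atom, n_atoms)
        for w, p in zip(weights, particle_coeffs)
    )
    return n_hole, n_elec


def mo_rdf(coords, w, grid: MoRdfGrid = DEFAULT_GRID) -> np.ndarray:
    """Orbital-weighted radial distribution function on ``grid``.

    f(r_k) = sum_{i>j} w_i w_j g(r_k − d_ij), with g a unit-mass Gaussian of
    width ``grid.sigma``; each unordered pair counts once and there are no
    self terms, so a single atom yields the zero vector.
    """
    coords = np.asarray(coords, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(w) != len(coords):
        raise ValueError("weights and coords length mismatch")
    if np.any(w < 0):
        warnings.warn("negative MO-RDF weights: populations are expected to be >= 0")
    out = np.zeros(grid.n_points)
    if len(w) < 2:
        return out
    iu, ju, d = _pair_distances(coords)
    wp = w[iu] * w[ju]
    r = grid.r
    pref = 1.0 / (grid.sigma * np.sqrt(2.0 * np.pi))
    # chunk over pairs to bound the (n_pairs x n_points) intermediate
    for start in range(0, len(d), 4096):
        sl = slice(start, start + 4096)
        x = r[None, :] - d[sl, None]
        out += wp[sl] @ (pref * np.exp(-0.5 * (x / grid.sigma) ** 2))
    return out


# ---------------------------------------------------------------------------
# Morgan fingerprint
# ---------------------------------------------------------------------------


def morgan_fingerprint(mol, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Binary circular fingerprint (default 2048 bits, radius 2 bonds)."""
    if isinstance(mol, MoleculeRecord):
        mol = Chem.MolFromSmiles(mol.smiles)
    elif isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    if mol is None:
        raise ValueError("unparseable molecule for fingerprinting")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


# ---------------------------------------------------------------------------
# graph featurisation
# ---------------------------------------------------------------------------

_ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "As", "Se", "Br", "Te", "I", "At"]
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_CHIRAL = [
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = [Chem.BondStereo.STEREONONE, Chem.BondStereo.STEREOANY,
           Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE]

# element(16) + degree(6) + formal charge + radicals + hybridisation(6)
# + aromatic + in-ring + numH(5) + chirality-possible + chiral tag(3)
N_DA_CHANNELS = 41
N_EA_CHANNELS = 45
N_EDGE_CHANNELS = 10  # bond type(4) + conjugated + in-ring + stereo(4)


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """41-channel default-atom (DA) feature vector."""
    feats = _one_hot(atom.GetSymbol(), _ELEMENTS)
    feats += _one_hot(atom.GetDegree(), [0, 1, 2, 3, 4])
    feats.append(float(atom.GetFormalCharge()))
    feats.append(float(atom.GetNumRadicalElectrons()))
    feats += _one_hot(atom.GetHybridization(), _HYBRID)
    feats.append(float(atom.GetIsAromatic()))
    feats.append(float(atom.IsInRing()))
    feats += _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3])
    feats.append(float(atom.HasProp("_ChiralityPossible")))
    feats += _one_hot(atom.GetChiralTag(), _CHIRAL)
    return np.array(feats)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    """10-channel bond feature vector; symmetric in the bond direction."""
    feats = _one_hot(bond.GetBondType(), _BOND_TYPES)[:-1]
    feats.append(float(bond.GetIsConjugated()))
    feats.append(float(bond.IsInRing()))
    stereo = _one_hot(bond.GetStereo(), _STEREO)[:-1]
    if sum(stereo) == 0:
        stereo[0] = 1.0  # unknown stereo folds into "none"
    feats += stereo
    return np.array(feats)


def _graph_mol(molecule) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES {molecule!r}")
        return mol
    if isinstance(molecule, MoleculeRecord):
        mol = molecule.to_rdkit()
        try:
            Chem.SanitizeMol(mol)
            return mol
        except Exception:
            parsed = Chem.MolFromSmiles(molecule.smiles)
            if parsed is None:
                raise ValueError(f"molecule {molecule.id}: unparseable structure")
            return parsed
    raise TypeError(f"cannot featurize {type(molecule)!r}")


@dataclass
class EaStandardizer:
    """Per-channel z-scoring of the four EA scalars, with statistics frozen
    from a training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, electronic_records) -> "EaStandardizer":
        cols = [
            np.concatenate([np.asarray(getattr(e, f), float) for e in electronic_records])
            for f in ("mulliken", "potential", "n_elec", "n_hole")
        ]
        mean = np.array([c.mean() for c in cols])
        std = np.array([c.std() for c in cols])
        std[std < 1e-12] = 1.0
        return cls(mean=mean, std=std)

    def transform(self, elec: ElectronicRecord) -> np.ndarray:
        raw = np.stack(
            [np.asarray(elec.mulliken), np.asarray(elec.potential),
             np.asarray(elec.n_elec), np.asarray(elec.n_hole)],
            axis=1,
        )
        return (raw - self.mean) / self.std


def build_node_features(
    molecule,
    elec: ElectronicRecord | None = None,
    mode: str = "DA",
    standardizer: EaStandardizer | None = None,
) -> np.ndarray:
    """Per-atom feature matrix: 41 channels in DA mode, 45 in DA+EA mode.

    DA+EA appends the z-scored (mulliken, potential, n_elec, n_hole) columns
    in that fixed order; requesting EA without electronic data is an error —
    missing electronics are never silently zero-filled.
    """
    if mode not in ("DA", "DA+EA"):
        raise ValueError(f"unknown featurization mode {mode!r}")
    mol = _graph_mol(molecule)
    da = np.stack([atom_features(a) for a in mol.GetAtoms()])
    if mode == "DA":
        return da
    if elec is None:
        raise ValueError("DA+EA mode requires an ElectronicRecord")
    if len(elec.mulliken) != mol.GetNumAtoms():
        raise ValueError(
            f"molecule {elec.molecule_id}: electronic arrays ({len(elec.mulliken)}) "
            f"do not match graph atom count ({mol.GetNumAtoms()})"
        )
    if standardizer is None:
        ea = np.stack(
            [np.asarray(elec.mulliken), np.asarray(elec.potential),
             np.asarray(elec.n_elec), np.asarray(elec.n_hole)],
            axis=1,
        )
    else:
        ea = standardizer.transform(elec)
    return np.concatenate([da, ea], axis=1)


def build_edge_features(molecule) -> tuple[np.ndarray, np.ndarray]:
    """(bond index array (n_bonds, 2), bond feature matrix (n_bonds, 10))."""
    mol = _graph_mol(molecule)
    idx, feats = [], []
    for b in mol.GetBonds():
        idx.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        feats.append(bond_features(b))
    if not idx:
        return np.zeros((0, 2), dtype=int), np.zeros((0, N_EDGE_CHANNELS))
    return np.asarray(idx, dtype=int), np.stack(feats)


def molecular_graph(
    molecule,
    elec: ElectronicRecord | None = None,
    mode: str = "DA",
    standardizer: EaStandardizer | None = None,
):
    """Directed-graph arrays for the encoder: node features plus both
    directions of every bond with shared symmetric edge features."""
    nodes = build_node_features(molecule, elec, mode, standardizer)
    bidx, bfeat = build_edge_features(molecule)
    if len(bidx):
        src = np.concatenate([bidx[:, 0], bidx[:, 1]])
        dst = np.concatenate([bidx[:, 1], bidx[:, 0]])
        efeat = np.concatenate([bfeat, bfeat], axis=0)
    else:
        src = dst = np.zeros(0, dtype=int)
        efeat = np.zeros((0, N_EDGE_CHANNELS))
    return nodes, src, dst, efeat
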