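"""Dataset-construction operators: conjugated-core extraction and
clustering, training-candidate filters, core-analogue test sampling, the
small-ring/alicyclic ("QCDGE-style") filter and the odd/even parity split.

The conjugated core of a molecule is the connected pi-system — aromatic
rings plus conjugated multiple-bond linkers — that dominates its low-lying
excited states.  Molecules sharing a core ("core-analogues", e.g.
naphthalene and 1-methyl-naphthalene) have near-identical S1 energies, so
clustering by core key maximises the *electronic* diversity of a training
set and supplies a principled train/test analogy split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .records import MoleculeRecord

__all__ = [
    "CoreCluster",
    "extract_conjugated_core",
    "cluster_unique_cores",
    "filter_training_candidates",
    "has_nitroso",
    "sample_core_analogues",
    "qcdge_style_filter",
    "parity_split",
    "ALLOWED_HEAVY_ELEMENTS",
]

ALLOWED_HEAVY_ELEMENTS = {"C", "N", "O", "S", "F"}


def _as_mol(molecule) -> Chem.Mol | None:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, MoleculeRecord):
        return Chem.MolFromSmiles(molecule.smiles)
    if isinstance(molecule, str):
        return Chem.MolFromSmiles(molecule)
    raise TypeError(f"cannot interpret {type(molecule)!r} as a molecule")


@dataclass
class CoreCluster:
    core_key: str
    member_ids: list[str] = field(default_factory=list)
    core_hac: int = 0

    @property
    def is_singleton(self) -> bool:
        return len(self.member_ids) == 1


# ---------------------------------------------------------------------------
# conjugated-core extraction
# ---------------------------------------------------------------------------


def _conjugated_atom_set(mol: Chem.Mol) -> set[int]:
    atoms: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            atoms.add(atom.GetIdx())
    for bond in mol.GetBonds():
        if bond.GetIsConjugated() or bond.GetBondType() in (
            Chem.BondType.DOUBLE,
            Chem.BondType.TRIPLE,
            Chem.BondType.AROMATIC,
        ):
            if bond.GetIsConjugated():
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
    return atoms


def _largest_component(mol: Chem.Mol, atoms: set[int]) -> set[int]:
    unvisited = set(atoms)
    best: set[int] = set()
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nb.GetIdx()
                if i in unvisited:
                    unvisited.remove(i)
                    comp.add(i)
                    frontier.append(i)
        if len(comp) > len(best):
            best = comp
    return best


def extract_conjugated_core(molecule) -> tuple[str, int]:
    """Canonical key and heavy-atom count of the molecule's conjugated core.

    The core is the largest connected set of aromatic/conjugated atoms after
    iteratively pruning sp3 terminal atoms; the key is the canonical SMILES
    of the induced subgraph (free valences hydrogen-capped).  Deterministic
    and independent of input atom order.  Molecules with no conjugation
    return an empty core with count 0.
    """
    mol = _as_mol(molecule)
    if mol is None:
        raise ValueError("unparseable molecule in core extraction")
    atoms = _conjugated_atom_set(mol)
    # prune saturated terminal atoms that sneak in via conjugated single bonds
    changed = True
    while changed and atoms:
        changed = False
        for i in sorted(atoms):
            atom = mol.GetAtomWithIdx(i)
            in_core_nbrs = sum(1 for nb in atom.GetNeighbors() if nb.GetIdx() in atoms)
            if atom.GetHybridization() == Chem.HybridizationType.SP3 and in_core_nbrs <= 1:
                atoms.remove(i)
                changed = True
    if not atoms:
        return "", 0
    core = _largest_component(mol, atoms)
    heavy = [i for i in core if mol.GetAtomWithIdx(i).GetAtomicNum() != 1]
    key = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(core), canonical=True)
    # re-canonicalise through a parse so chemically identical cores written
    # from different parents collapse to one key
    frag = Chem.MolFromSmiles(key, sanitize=False)
    if frag is not None:
        try:
            Chem.SanitizeMol(frag)
            key = Chem.MolToSmiles(frag)
        except Exception:
            pass
    return key, len(heavy)


def cluster_unique_cores(
    molecules: dict[str, object] | list[MoleculeRecord],
    min_core_hac: int = 6,
) -> tuple[dict[str, CoreCluster], dict[str, str]]:
    """Group molecules by conjugated-core key.

    Clusters whose core has fewer than ``min_core_hac`` heavy atoms are
    discarded (strict ``<``, so a benzene core of 6 heavy atoms survives).
    Returns (clusters keyed by core, {discarded_id: reason}).
    """
    if isinstance(molecules, list):
        molecules = {m.id: m for m in molecules}
    clusters: dict[str, CoreCluster] = {}
    discarded: dict[str, str] = {}
    for mid, mol in molecules.items():
        key, hac = extract_conjugated_core(mol)
        if hac < min_core_hac:
            discarded[mid] = f"core_hac {hac} < {min_core_hac}"
            continue
        cluster = clusters.setdefault(key, CoreCluster(core_key=key, core_hac=hac))
        cluster.member_ids.append(mid)
    return clusters, discarded


# ---------------------------------------------------------------------------
# candidate filters
# ---------------------------------------------------------------------------


def has_nitroso(molecule) -> bool:
    """True if the molecule carries a nitroso (−N=O) group: a two-connected
    nitrogen double-bonded to a terminal oxygen with no second oxygen
    neighbour (so nitro, nitrate and N-oxide groups do not match)."""
    mol = _as_mol(molecule)
    if mol is None:
        return False
    patt = Chem.MolFromSmarts("[NX2]=[OX1]")
    for n_idx, _o_idx in mol.GetSubstructMatches(patt):
        n = mol.GetAtomWithIdx(n_idx)
        o_neighbors = sum(1 for nb in n.GetNeighbors() if nb.GetAtomicNum() == 8)
        if o_neighbors == 1:
            return True
    return False


def filter_training_candidates(
    molecules: dict[str, object] | list[MoleculeRecord],
    hac_min: int = 10,
    hac_max: int = 25,
) -> tuple[list[str], dict[str, list[str]]]:
    """Keep molecules with 10–25 heavy atoms drawn from {C, N, O, S, F} and
    no nitroso group.  Returns (kept ids, {removed_id: [reasons]}); every
    violated rule is recorded."""
    if isinstance(molecules, list):
        molecules = {m.id: m for m in molecules}
    kept: list[str] = []
    removed: dict[str, list[str]] = {}
    for mid, molecule in molecules.items():
        try:
            mol = _as_mol(molecule)
        except TypeError:
            raise
        if mol is None:
            removed[mid] = ["parse"]
            continue
        reasons = []
        heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
        if any(a.GetSymbol() not in ALLOWED_HEAVY_ELEMENTS for a in heavy):
            reasons.append("element")
        if not hac_min <= len(heavy) <= hac_max:
            reasons.append("hac")
        if has_nitroso(mol):
            reasons.append("nitroso")
        if reasons:
            removed[mid] = reasons
        else:
            kept.append(mid)
    return kept, removed


def sample_core_analogues(
    clusters: dict[str, CoreCluster],
    train_ids,
    max_per_core: int = 3,
    seed: int = 0,
) -> list[str]:
    """Test-set sampling: for every cluster containing a training molecule,
    draw up to ``max_per_core`` non-training members uniformly without
    replacement.  Each sampled molecule therefore shares a conjugated core
    with a training molecule; output is disjoint from the training ids and
    deterministic for a fixed seed."""
    train = set(train_ids)
    rng = np.random.default_rng(seed)
    test: list[str] = []
    for key in sorted(clusters):
        cluster = clusters[key]
        members = set(cluster.member_ids)
        if not members & train:
            continue
        pool = sorted(members - train)
        if not pool:
            continue
        k = min(max_per_core, len(pool))
        test.extend(rng.choice(pool, size=k, replace=False).tolist())
    return test


def qcdge_style_filter(
    molecules: dict[str, object] | list[MoleculeRecord],
    exact_hac: int | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Retain molecules with 1 or 2 rings (SSSR) and no nonaromatic
    all-carbon ring; optionally require an exact heavy-atom count."""
    if isinstance(molecules, list):
        molecules = {m.id: m for m in molecules}
    kept: list[str] = []
    removed: dict[str, str] = {}
    for mid, molecule in molecules.items():
        mol = _as_mol(molecule)
        if mol is None:
            removed[mid] = "parse"
            continue
        ri = mol.GetRingInfo()
        n_rings = ri.NumRings()
        if n_rings not in (1, 2):
            removed[mid] = f"ring_count {n_rings}"
            continue
        alicyclic = False
        for ring in ri.AtomRings():
            ring_atoms = [mol.GetAtomWithIdx(i) for i in ring]
            if all(a.GetAtomicNum() == 6 for a in ring_atoms) and not all(
                a.GetIsAromatic() for a in ring_atoms
            ):
                alicyclic = True
                break
        if alicyclic:
            removed[mid] = "alicyclic_carbocycle"
            continue
        if exact_hac is not None:
            hac = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() != 1)
            if hac != exact_hac:
                removed[mid] = f"hac {hac} != {exact_hac}"
                continue
        kept.append(mid)
    return kept, removed


def parity_split(ids) -> tuple[list[str], list[str]]:
    """Sort ids ascending; odd positions (1st, 3rd, ...) go to the training
    set and even positions to the test set."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in parity split")
    try:  # database ids are usually numeric even when typed as strings
        ordered = sorted(ids, key=lambda x: (0, int(x)))
    except (TypeError, ValueError):
        ordered = sorted(ids)
    return ordered[0::2], ordered[1::2]
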