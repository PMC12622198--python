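"""Ligand / pocket domain types, standard-format I/O and featurization.

Ligands live in :class:`LigandState` — 3D coordinates plus categorical atom
types, formal charges, hybridizations and a symmetric bond-order matrix.
Protein context is a :class:`PocketState` extracted from a structure by a
radius cut around a reference ligand (whole residues are kept when any of
their atoms falls inside the cutoff).  SDF reading/writing goes through
RDKit; PDB reading through biotite.  All coordinates are Cartesian Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers conformer code)
from rdkit import RDLogger
from scipy.spatial.distance import cdist

RDLogger.DisableLog("rdApp.*")

ENDPOINTS = ("pIC50", "pKi", "pKd", "pEC50")


class ChemIOError(Exception):
    """Base class for I/O and validation failures."""


class FormatError(ChemIOError):
    """Unparseable SDF/PDB content."""


class VocabularyError(ChemIOError):
    """Out-of-vocabulary element, charge, hybridization or bond order."""


class InvariantError(ChemIOError):
    """A state object violates its structural invariants."""


class PocketSizeError(ChemIOError):
    """Pocket atom count outside the allowed [min_atoms, max_atoms] window."""


class EmptyStructureError(ChemIOError):
    """PDB file contains no protein ATOM records."""


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomVocabulary:
    """Ordered category sets for atom types, charges, hybridizations and bonds.

    Bond index 0 is always "none" (no bond).  Encoding then decoding any
    in-vocabulary label is the identity.
    """

    atom_types: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
    charge_values: tuple[int, ...] = (-2, -1, 0, 1, 2)
    hybridizations: tuple[str, ...] = ("sp", "sp2", "sp3", "other")
    bond_orders: tuple[str, ...] = ("none", "single", "double", "triple", "aromatic")

    def __post_init__(self):
        for name in ("atom_types", "charge_values", "hybridizations", "bond_orders"):
            vals = getattr(self, name)
            if len(vals) == 0 or len(set(vals)) != len(vals):
                raise InvariantError(f"vocabulary field {name} must be nonempty and duplicate-free")
        if self.bond_orders[0] != "none":
            raise InvariantError('bond order index 0 must be "none"')

    @property
    def n_atom_types(self) -> int:
        return len(self.atom_types)

    @property
    def n_charges(self) -> int:
        return len(self.charge_values)

    @property
    def n_hybridizations(self) -> int:
        return len(self.hybridizations)

    @property
    def n_bond_orders(self) -> int:
        return len(self.bond_orders)

    def atom_index(self, symbol: str) -> int:
        try:
            return self.atom_types.index(symbol)
        except ValueError:
            raise VocabularyError(f"element {symbol!r} not in vocabulary {self.atom_types}") from None

    def charge_index(self, charge: int) -> int:
        try:
            return self.charge_values.index(charge)
        except ValueError:
            raise VocabularyError(f"formal charge {charge} not in vocabulary {self.charge_values}") from None

    def hybridization_index(self, label: str) -> int:
        try:
            return self.hybridizations.index(label)
        except ValueError:
            raise VocabularyError(f"hybridization {label!r} not in vocabulary") from None

    def bond_index(self, label: str) -> int:
        try:
            return self.bond_orders.index(label)
        except ValueError:
            raise VocabularyError(f"bond order {label!r} not in vocabulary") from None

    def to_dict(self) -> dict:
        return {
            "atom_types": list(self.atom_types),
            "charge_values": [int(c) for c in self.charge_values],
            "hybridizations": list(self.hybridizations),
            "bond_orders": list(self.bond_orders),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AtomVocabulary":
        return cls(
            atom_types=tuple(d["atom_types"]),
            charge_values=tuple(int(c) for c in d["charge_values"]),
            hybridizations=tuple(d["hybridizations"]),
            bond_orders=tuple(d["bond_orders"]),
        )


DEFAULT_VOCABULARY = AtomVocabulary()

# max total bond order per element (aromatic bonds count 1.5)
MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "Br": 1, "I": 1}

_RD_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_RD_BOND_INV = {v: k for k, v in _RD_BOND.items()}
_RD_HYB = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

@dataclass
class LigandState:
    """A ligand: coordinates (N×3, Å) and per-atom / per-pair categories.

    ``bonds`` is a symmetric N×N integer matrix of bond-order indices with a
    zero ("none") diagonal.  ``atom_mask`` marks real atoms; padding rows
    carry index 0 and zero coordinates.
    """

    coords: np.ndarray
    atom_type: np.ndarray
    charge: np.ndarray
    hybridization: np.ndarray
    bonds: np.ndarray
    atom_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = self.coords.shape[0]
        self.atom_type = np.asarray(self.atom_type, dtype=np.int64)
        self.charge = np.asarray(self.charge, dtype=np.int64)
        self.hybridization = np.asarray(self.hybridization, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(n, n)
        if self.atom_mask is None:
            self.atom_mask = np.ones(n, dtype=bool)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_mask.sum())

    @property
    def n_slots(self) -> int:
        return self.coords.shape[0]

    def validate(self, vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> None:
        n = self.n_slots
        if not np.all(np.isfinite(self.coords)):
            raise InvariantError("non-finite ligand coordinates")
        if not np.array_equal(self.bonds, self.bonds.T):
            raise InvariantError("bond matrix is not symmetric")
        if np.any(np.diag(self.bonds) != 0):
            raise InvariantError("bond matrix diagonal must be 'none'")
        for arr, hi, what in (
            (self.atom_type, vocabulary.n_atom_types, "atom type"),
            (self.charge, vocabulary.n_charges, "charge"),
            (self.hybridization, vocabulary.n_hybridizations, "hybridization"),
            (self.bonds, vocabulary.n_bond_orders, "bond order"),
        ):
            if arr.min(initial=0) < 0 or arr.max(initial=0) >= hi:
                raise InvariantError(f"{what} index out of vocabulary range")
        pad = ~self.atom_mask
        if pad.any():
            if np.any(self.coords[pad] != 0.0):
                raise InvariantError("padding atoms must have zero coordinates")
            if np.any(self.atom_type[pad] != 0) or np.any(self.bonds[pad, :] != 0):
                raise InvariantError("padding atoms must carry index 0")
        _ = n

    def is_valid(self, vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> bool:
        try:
            self.validate(vocabulary)
            return True
        except InvariantError:
            return False

    def compact(self) -> "LigandState":
        """Drop padding slots."""
        m = self.atom_mask
        return LigandState(
            coords=self.coords[m],
            atom_type=self.atom_type[m],
            charge=self.charge[m],
            hybridization=self.hybridization[m],
            bonds=self.bonds[np.ix_(m, m)],
        )

    def translated(self, offset: np.ndarray) -> "LigandState":
        out = replace(self, coords=self.coords + np.asarray(offset, dtype=np.float64))
        out.coords[~self.atom_mask] = 0.0
        return out

    def copy(self) -> "LigandState":
        return LigandState(
            coords=self.coords.copy(),
            atom_type=self.atom_type.copy(),
            charge=self.charge.copy(),
            hybridization=self.hybridization.copy(),
            bonds=self.bonds.copy(),
            atom_mask=self.atom_mask.copy(),
        )


@dataclass
class PocketState:
    """Pocket atoms (M×3, Å) with element indices and residue bookkeeping."""

    coords: np.ndarray
    atom_type: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    atom_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        m = self.coords.shape[0]
        self.atom_type = np.asarray(self.atom_type, dtype=np.int64)
        self.residue_id = np.asarray(self.residue_id, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        if self.atom_mask is None:
            self.atom_mask = np.ones(m, dtype=bool)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_mask.sum())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise InvariantError("non-finite pocket coordinates")

    def centroid(self) -> np.ndarray:
        return self.coords[self.atom_mask].mean(axis=0)

    def translated(self, offset: np.ndarray) -> "PocketState":
        out = replace(self, coords=self.coords + np.asarray(offset, dtype=np.float64))
        out.coords[~self.atom_mask] = 0.0
        return out

    def copy(self) -> "PocketState":
        return PocketState(
            coords=self.coords.copy(),
            atom_type=self.atom_type.copy(),
            residue_id=self.residue_id.copy(),
            residue_name=self.residue_name.copy(),
            chain_id=self.chain_id.copy(),
            atom_mask=self.atom_mask.copy(),
        )


@dataclass
class ComplexRecord:
    """One ligand-pocket pair, optionally annotated with log-unit affinities."""

    ligand: LigandState
    pocket: PocketState
    affinity: dict[str, float] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self):
        for k, v in self.affinity.items():
            if k not in ENDPOINTS:
                raise InvariantError(f"unknown affinity endpoint {k!r}")
            if v < 0:
                raise InvariantError(f"affinity {k}={v} must be >= 0 (log units)")

    def centered_on_pocket(self) -> "ComplexRecord":
        """Shift ligand and pocket so the pocket centroid sits at the origin."""
        offset = -self.pocket.centroid()
        return ComplexRecord(
            ligand=self.ligand.translated(offset),
            pocket=self.pocket.translated(offset),
            affinity=dict(self.affinity),
            source_id=self.source_id,
        )


@dataclass
class ProteinAtoms:
    """Flat table of protein ATOM records (HETATM ligand atoms kept separately)."""

    coords: np.ndarray
    element: np.ndarray
    atom_name: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray

    def __len__(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# SDF I/O (RDKit)
# ---------------------------------------------------------------------------

def _mol_to_state(mol: Chem.Mol, vocabulary: AtomVocabulary) -> LigandState:
    n = mol.GetNumAtoms()
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=np.float64)
    atom_type = np.zeros(n, dtype=np.int64)
    charge = np.zeros(n, dtype=np.int64)
    hyb = np.zeros(n, dtype=np.int64)
    for i, atom in enumerate(mol.GetAtoms()):
        atom_type[i] = vocabulary.atom_index(atom.GetSymbol())
        charge[i] = vocabulary.charge_index(atom.GetFormalCharge())
        hyb[i] = vocabulary.hybridization_index(_RD_HYB.get(atom.GetHybridization(), "other"))
    bonds = np.zeros((n, n), dtype=np.int64)
    for bond in mol.GetBonds():
        label = _RD_BOND_INV.get(bond.GetBondType())
        if label is None:
            raise VocabularyError(f"bond type {bond.GetBondType()} not in vocabulary")
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        k = vocabulary.bond_index(label)
        bonds[i, j] = k
        bonds[j, i] = k
    return LigandState(coords=coords, atom_type=atom_type, charge=charge,
                       hybridization=hyb, bonds=bonds)


def read_ligand_sdf(path, vocabulary: AtomVocabulary = DEFAULT_VOCABULARY,
                    explicit_hydrogens: bool = False) -> list[LigandState]:
    """Read a V2000/V3000 SDF into a list of :class:`LigandState`.

    Heavy-atom representation by default (hydrogens stripped); pass
    ``explicit_hydrogens=True`` to keep them (requires "H" in the vocabulary).
    Out-of-vocabulary elements raise :class:`VocabularyError` rather than
    being dropped silently.
    """
    import os

    if os.path.getsize(path) == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    states: list[LigandState] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"SDF record {idx} in {path} could not be parsed")
        try:
            Chem.SanitizeMol(mol)
            if not explicit_hydrogens:
                mol = Chem.RemoveHs(mol)
        except Exception:
            # model-generated molecules may violate valence rules; fall back
            # to an unsanitized read (hybridization then decodes as "other")
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
            if not explicit_hydrogens:
                mol = Chem.RemoveHs(mol, sanitize=False)
        if mol.GetNumConformers() == 0:
            raise FormatError(f"SDF record {idx} in {path} has no 3D coordinates")
        states.append(_mol_to_state(mol, vocabulary))
    return states


def state_to_mol(state: LigandState, vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> Chem.Mol:
    """Build an RDKit molecule (no sanitization) from a ligand state."""
    compact = state.compact()
    mol = Chem.RWMol()
    for i in range(compact.n_slots):
        atom = Chem.Atom(vocabulary.atom_types[compact.atom_type[i]])
        atom.SetFormalCharge(int(vocabulary.charge_values[compact.charge[i]]))
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i in range(compact.n_slots):
        for j in range(i + 1, compact.n_slots):
            k = compact.bonds[i, j]
            if k != 0:
                mol.AddBond(i, j, _RD_BOND[vocabulary.bond_orders[k]])
    conf = Chem.Conformer(compact.n_slots)
    for i in range(compact.n_slots):
        conf.SetAtomPosition(i, [float(x) for x in compact.coords[i]])
    out = mol.GetMol()
    out.AddConformer(conf)
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out


def write_ligand_sdf(ligands: list[LigandState], path,
                     vocabulary: AtomVocabulary = DEFAULT_VOCABULARY,
                     properties: list[dict] | None = None):
    """Write ligand states to an SDF file (V2000, coordinates at 4 decimals).

    Padding atoms are omitted.  Optional per-ligand ``properties`` dicts are
    emitted as SD tags.
    """
    for state in ligands:
        state.validate(vocabulary)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for i, state in enumerate(ligands):
        mol = state_to_mol(state, vocabulary)
        if properties is not None:
            for key, val in properties[i].items():
                mol.SetProp(str(key), str(val))
        writer.write(mol)
    writer.close()
    return path


# ---------------------------------------------------------------------------
# PDB I/O (biotite)
# ---------------------------------------------------------------------------

def _check_pdb_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise FormatError(
                            f"{path}: malformed coordinate column on line {lineno}: {line.rstrip()!r}"
                        ) from None


def read_pocket_pdb(path) -> tuple[ProteinAtoms, ProteinAtoms]:
    """Read a PDB file; return (protein ATOM records, HETATM records).

    Altloc duplicates keep the highest-occupancy variant, ties broken by
    altloc letter order.  Raises :class:`EmptyStructureError` when the file
    holds no protein ATOM records, and :class:`FormatError` (with a line
    number) on malformed coordinates.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="all",
                                  extra_fields=["occupancy", "atom_id"])
    except Exception as exc:
        _check_pdb_lines(path)
        raise FormatError(f"failed to parse PDB {path}: {exc}") from exc

    # altloc filter: per (chain, res_id, res_name, atom_name) keep best variant
    altloc = atoms.get_annotation("altloc_id") if "altloc_id" in atoms.get_annotation_categories() else np.full(len(atoms), " ")
    occupancy = atoms.occupancy if hasattr(atoms, "occupancy") else np.ones(len(atoms))
    keep = np.ones(len(atoms), dtype=bool)
    groups: dict[tuple, list[int]] = {}
    for i in range(len(atoms)):
        key = (atoms.chain_id[i], int(atoms.res_id[i]), atoms.res_name[i], atoms.atom_name[i])
        groups.setdefault(key, []).append(i)
    for members in groups.values():
        if len(members) > 1:
            best = min(members, key=lambda i: (-float(occupancy[i]), str(altloc[i]), i))
            for i in members:
                keep[i] = i == best
    atoms = atoms[keep]

    def table(sel: np.ndarray) -> ProteinAtoms:
        sub = atoms[sel]
        element = np.array([e.capitalize() for e in sub.element], dtype=object)
        return ProteinAtoms(
            coords=np.asarray(sub.coord, dtype=np.float64),
            element=element,
            atom_name=np.asarray(sub.atom_name, dtype=object),
            residue_id=np.asarray(sub.res_id, dtype=np.int64),
            residue_name=np.asarray(sub.res_name, dtype=object),
            chain_id=np.asarray(sub.chain_id, dtype=object),
        )

    protein = table(~atoms.hetero)
    hetero = table(atoms.hetero)
    if len(protein) == 0:
        raise EmptyStructureError(f"{path} contains no protein ATOM records")
    return protein, hetero


def write_pocket_pdb(pocket: PocketState, path,
                     vocabulary: AtomVocabulary = DEFAULT_VOCABULARY):
    """Write a pocket as a minimal PDB file of ATOM records."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    m = int(pocket.atom_mask.sum())
    arr = struc.AtomArray(m)
    idx = np.where(pocket.atom_mask)[0]
    arr.coord = pocket.coords[idx]
    arr.chain_id = np.array([str(c) for c in pocket.chain_id[idx]])
    arr.res_id = pocket.residue_id[idx]
    arr.res_name = np.array([str(r) for r in pocket.residue_name[idx]])
    elements = [vocabulary.atom_types[t] for t in pocket.atom_type[idx]]
    arr.element = np.array([e.upper() for e in elements])
    # unique atom names within a residue (element + per-residue counter)
    names = []
    counters: dict[tuple, int] = {}
    for i, e in zip(idx, elements):
        key = (pocket.chain_id[i], int(pocket.residue_id[i]))
        counters[key] = counters.get(key, 0) + 1
        names.append(f"{e.upper()}{counters[key]}")
    arr.atom_name = np.array(names)
    arr.hetero = np.zeros(m, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# pocket extraction
# ---------------------------------------------------------------------------

def extract_pocket(protein_atoms: ProteinAtoms, ligand: LigandState,
                   radius_A: float = 7.0, min_atoms: int = 10, max_atoms: int = 800,
                   vocabulary: AtomVocabulary = DEFAULT_VOCABULARY,
                   residue_level: bool = True) -> PocketState:
    """Cut the binding pocket around a reference ligand.

    A residue belongs to the pocket when any of its atoms lies within
    ``radius_A`` of any ligand atom; all atoms of such residues are kept
    (set ``residue_level=False`` for atom-level cutting).  Complexes whose
    pocket falls outside ``[min_atoms, max_atoms]`` are rejected with
    :class:`PocketSizeError`, mirroring dataset-level filtering.
    """
    if ligand.n_atoms < 1:
        raise InvariantError("reference ligand has no atoms")
    if radius_A <= 0:
        raise InvariantError("radius must be positive")
    lig_xyz = ligand.coords[ligand.atom_mask]
    dmin = cdist(protein_atoms.coords, lig_xyz).min(axis=1)
    within = dmin < radius_A
    if residue_level:
        keys = list(zip(protein_atoms.chain_id, protein_atoms.residue_id))
        hit_residues = {k for k, w in zip(keys, within) if w}
        sel = np.array([k in hit_residues for k in keys], dtype=bool)
    else:
        sel = within
    count = int(sel.sum())
    if count < min_atoms:
        raise PocketSizeError(f"pocket has {count} atoms (< min {min_atoms})")
    if count > max_atoms:
        raise PocketSizeError(f"pocket has {count} atoms (> max {max_atoms})")
    atom_type = np.array([vocabulary.atom_index(e) for e in protein_atoms.element[sel]],
                         dtype=np.int64)
    return PocketState(
        coords=protein_atoms.coords[sel],
        atom_type=atom_type,
        residue_id=protein_atoms.residue_id[sel],
        residue_name=protein_atoms.residue_name[sel],
        chain_id=protein_atoms.chain_id[sel],
    )


def load_complex(sdf_path, pdb_path, vocabulary: AtomVocabulary = DEFAULT_VOCABULARY,
                 radius_A: float = 7.0, min_atoms: int = 10, max_atoms: int = 800,
                 source_id: str = "", center: bool = True) -> ComplexRecord:
    """Read ligand + protein, extract the pocket and (by default) re-center
    the complex on the pocket centroid."""
    ligand = read_ligand_sdf(sdf_path, vocabulary)[0]
    protein, _ = read_pocket_pdb(pdb_path)
    pocket = extract_pocket(protein, ligand, radius_A, min_atoms, max_atoms, vocabulary)
    record = ComplexRecord(ligand=ligand, pocket=pocket,
                           source_id=source_id or str(sdf_path))
    return record.centered_on_pocket() if center else record


# ---------------------------------------------------------------------------
# affinity sidecar
# ---------------------------------------------------------------------------

def read_affinity_csv(path) -> dict[str, dict[str, float]]:
    """Read a long-format affinity table: columns source_id, endpoint, value."""
    df = pd.read_csv(path)
    required = {"source_id", "endpoint", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"affinity CSV must have columns {sorted(required)}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        ep = str(row["endpoint"])
        if ep not in ENDPOINTS:
            raise FormatError(f"unknown endpoint {ep!r} in affinity CSV")
        out.setdefault(str(row["source_id"]), {})[ep] = float(row["value"])
    return out


def write_affinity_csv(affinities: dict[str, dict[str, float]], path):
    rows = [
        {"source_id": sid, "endpoint": ep, "value": val}
        for sid, eps in affinities.items()
        for ep, val in eps.items()
    ]
    pd.DataFrame(rows, columns=["source_id", "endpoint", "value"]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _one_hot(indices: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros(indices.shape + (k,), dtype=np.float64)
    np.put_along_axis(out, indices[..., None], 1.0, axis=-1)
    return out


def encode_ligand_features(ligand: LigandState,
                           vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> dict[str, np.ndarray]:
    """One-hot encode a ligand: per-atom type/charge/hybridization blocks and
    a per-pair bond block.  ``decode_ligand_features`` inverts this exactly."""
    ligand.validate(vocabulary)
    return {
        "atom_type": _one_hot(ligand.atom_type, vocabulary.n_atom_types),
        "charge": _one_hot(ligand.charge, vocabulary.n_charges),
        "hybridization": _one_hot(ligand.hybridization, vocabulary.n_hybridizations),
        "bonds": _one_hot(ligand.bonds, vocabulary.n_bond_orders),
        "coords": ligand.coords.copy(),
        "atom_mask": ligand.atom_mask.copy(),
    }


def decode_ligand_features(features: dict[str, np.ndarray],
                           vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> LigandState:
    bonds = np.argmax(features["bonds"], axis=-1)
    bonds = np.where(bonds == bonds.T, bonds, 0)  # argmax ties cannot break symmetry
    np.fill_diagonal(bonds, 0)
    return LigandState(
        coords=features["coords"],
        atom_type=np.argmax(features["atom_type"], axis=-1),
        charge=np.argmax(features["charge"], axis=-1),
        hybridization=np.argmax(features["hybridization"], axis=-1),
        bonds=bonds,
        atom_mask=features.get("atom_mask"),
    )
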