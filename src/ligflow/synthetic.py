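"""Procedural toy ligand-pocket complexes with a known affinity ground truth.

The generator emulates the shape of real training data — drug-like heavy-atom
graphs with near-canonical bond geometry sitting inside a shell of protein
atoms — while staying fully analytic: the "experimental" affinity is a linear
function of the ligand-pocket contact count and the ligand heavy-atom count,
so every number the model is asked to recover can be recomputed exactly by an
independent oracle.  Ligand geometry is template-based (aromatic rings,
sp3 chains, branch points) rather than force-field embedded.

All randomness flows through ``numpy.random.Generator`` streams; datasets
split one master seed into counter-based per-record substreams, so record i
never depends on how many records precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .chem_io import (
    DEFAULT_VOCABULARY,
    AtomVocabulary,
    ComplexRecord,
    LigandState,
    PocketState,
    ProteinAtoms,
    write_affinity_csv,
    write_ligand_sdf,
    write_pocket_pdb,
)

# bond lengths (Å) used by the templates
BOND_LENGTHS = {"single": 1.54, "double": 1.34, "aromatic": 1.39}

# endpoint = scale * latent + offset (+ independent noise), clipped to [0, 12]
ENDPOINT_TRANSFORMS = {
    "pIC50": (1.0, 0.0),
    "pKi": (1.0, 0.3),
    "pKd": (0.9, 0.5),
    "pEC50": (1.05, -0.2),
}

CONTACT_CUTOFF_A = 4.0


class PlacementError(RuntimeError):
    """Geometric placement failed after bounded retries."""


@dataclass
class FixtureConfig:
    """Configuration of one synthetic dataset.

    ``noise_sd`` jitters atom coordinates (Å); ``affinity_coefficients`` are
    (intercept, per-contact, per-heavy-atom) for the latent affinity;
    ``affinity_noise_sd`` is the per-endpoint observation noise in log units.
    """

    n_complexes: int = 500
    ligand_size_range: tuple[int, int] = (8, 16)
    pocket_size_range: tuple[int, int] = (24, 42)
    seed: int = 0
    noise_sd: float = 0.05
    affinity_coefficients: tuple[float, ...] = (2.0, 0.08, 0.0)
    affinity_noise_sd: float = 0.2

    def __post_init__(self):
        for name in ("ligand_size_range", "pocket_size_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")
        if self.noise_sd < 0 or self.affinity_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_complexes": self.n_complexes,
            "ligand_size_range": list(self.ligand_size_range),
            "pocket_size_range": list(self.pocket_size_range),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "affinity_coefficients": list(self.affinity_coefficients),
            "affinity_noise_sd": self.affinity_noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureConfig":
        d = dict(d)
        d["ligand_size_range"] = tuple(d["ligand_size_range"])
        d["pocket_size_range"] = tuple(d["pocket_size_range"])
        d["affinity_coefficients"] = tuple(d["affinity_coefficients"])
        return cls(**d)


# ---------------------------------------------------------------------------
# ligand templates
# ---------------------------------------------------------------------------

def _chain_positions(n: int, origin: np.ndarray, direction: np.ndarray,
                     bond: float = BOND_LENGTHS["single"]) -> np.ndarray:
    """Zigzag sp3 chain with tetrahedral angles, growing along ``direction``."""
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame around the growth axis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    perp = np.cross(direction, helper)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(109.47) / 2.0
    dx, dy = bond * np.sin(half), bond * np.cos(half)
    pos = np.zeros((n, 3))
    cur = origin.astype(float).copy()
    for i in range(n):
        cur = cur + dx * direction + dy * perp * (1 if i % 2 == 0 else -1)
        pos[i] = cur
    return pos


_ORDER_VALENCE = {0: 0.0, 1: 1.0, 2: 2.0, 3: 3.0, 4: 1.5}


def _bond_order_sums(bonds: np.ndarray) -> np.ndarray:
    """Total bond order per atom (aromatic counts 1.5)."""
    lut = np.array([_ORDER_VALENCE[k] for k in range(5)])
    return lut[bonds].sum(axis=1)


def _assign_elements(n: int, bonds: np.ndarray, aromatic: np.ndarray,
                     rng: np.random.Generator, vocab: AtomVocabulary) -> np.ndarray:
    """Element indices respecting valence caps, based on per-atom bond-order
    sums (O needs <= 2, N <= 3, halogens only on order-1 terminals)."""
    val = _bond_order_sums(bonds)
    symbols = np.full(n, "C", dtype=object)
    for i in range(n):
        v = val[i]
        if aromatic[i]:
            if v <= 3.0 and rng.random() < 0.15:
                symbols[i] = "N"
        elif v <= 1.0:
            r = rng.random()
            if r < 0.15:
                symbols[i] = "O"
            elif r < 0.25:
                symbols[i] = "N"
            elif r < 0.32:
                symbols[i] = rng.choice(["F", "Cl"])
        elif v <= 2.0:
            r = rng.random()
            if r < 0.10:
                symbols[i] = "O"
            elif r < 0.18:
                symbols[i] = "N"
        elif v <= 3.0 and rng.random() < 0.08:
            symbols[i] = "N"
    return np.array([vocab.atom_index(s) for s in symbols], dtype=np.int64)


def generate_toy_ligand(size: int, rng: np.random.Generator,
                        noise_sd: float = 0.02, template: str = "auto",
                        vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> LigandState:
    """Generate one connected toy ligand with near-canonical bond geometry.

    ``template`` is "ring" (aromatic 6-ring plus sp3 substituent chains),
    "chain" (pure zigzag), or "auto" (random choice; rings require size>=6).
    Deterministic given the ``rng`` state.
    """
    if not (3 <= size <= 32):
        raise ValueError(f"ligand size {size} outside [3, 32]")
    if template == "auto":
        template = "ring" if (size >= 6 and rng.random() < 0.6) else "chain"

    coords = np.zeros((size, 3))
    bonds = np.zeros((size, size), dtype=np.int64)
    aromatic = np.zeros(size, dtype=bool)
    b_arom = vocabulary.bond_index("aromatic")
    b_single = vocabulary.bond_index("single")
    b_double = vocabulary.bond_index("double")

    if template == "ring":
        if size < 6:
            raise ValueError("ring template needs size >= 6")
        r = BOND_LENGTHS["aromatic"]  # circumradius of a regular hexagon = edge
        ang = np.arange(6) * np.pi / 3.0
        coords[:6, 0] = r * np.cos(ang)
        coords[:6, 1] = r * np.sin(ang)
        for i in range(6):
            j = (i + 1) % 6
            bonds[i, j] = bonds[j, i] = b_arom
        aromatic[:6] = True
        # distribute remaining atoms as chains, at most one per ring anchor
        # (keeps anchor carbons at two aromatic + one single bond)
        extra = size - 6
        anchors = rng.permutation(6)
        n_chains = min(6, extra) if extra else 0
        lengths = np.zeros(n_chains, dtype=int)
        for c in range(extra):
            lengths[c % n_chains] += 1
        k = 6
        for a in range(n_chains):
            anchor = int(anchors[a])
            chain_len = int(lengths[a])
            direction = coords[anchor] / max(np.linalg.norm(coords[anchor]), 1e-9)
            tilt = rng.normal(scale=0.25, size=3)
            pos = _chain_positions(chain_len, coords[anchor], direction + tilt)
            prev = anchor
            for c in range(chain_len):
                coords[k] = pos[c]
                bonds[prev, k] = bonds[k, prev] = b_single
                prev = k
                k += 1
    elif template == "chain":
        coords[:] = _chain_positions(size, np.zeros(3), np.array([1.0, 0.0, 0.0]))
        coords -= coords.mean(axis=0)
        for i in range(size - 1):
            bonds[i, i + 1] = bonds[i + 1, i] = b_single
    else:
        raise ValueError(f"unknown template {template!r}")

    degrees = (bonds > 0).sum(axis=1)
    # occasionally promote one terminal single bond to a carbonyl-like double
    terminals = [i for i in range(size) if degrees[i] == 1 and not aromatic[i]]
    sp2 = np.zeros(size, dtype=bool)
    if terminals and rng.random() < 0.4:
        t = int(rng.choice(terminals))
        nb = int(np.nonzero(bonds[t])[0][0])
        if not aromatic[nb] and _bond_order_sums(bonds)[nb] <= 3.0:
            bonds[t, nb] = bonds[nb, t] = b_double
            # shorten the bond to the double-bond length
            vec = coords[t] - coords[nb]
            coords[t] = coords[nb] + vec / np.linalg.norm(vec) * BOND_LENGTHS["double"]
            sp2[[t, nb]] = True

    atom_type = _assign_elements(size, bonds, aromatic, rng, vocabulary)
    # double-bonded terminals read best as O (carbonyl); keep element consistent
    if sp2.any():
        for i in np.nonzero(sp2 & (degrees == 1))[0]:
            atom_type[i] = vocabulary.atom_index("O")

    hyb = np.where(aromatic | sp2,
                   vocabulary.hybridization_index("sp2"),
                   vocabulary.hybridization_index("sp3"))
    if noise_sd > 0:
        coords = coords + rng.normal(scale=noise_sd, size=coords.shape)
    return LigandState(
        coords=coords,
        atom_type=atom_type,
        charge=np.full(size, vocabulary.charge_index(0), dtype=np.int64),
        hybridization=hyb.astype(np.int64),
        bonds=bonds,
    )


# ---------------------------------------------------------------------------
# pockets
# ---------------------------------------------------------------------------

POCKET_ELEMENTS = ("C", "C", "C", "N", "O", "S")
RESIDUE_NAMES = ("ALA", "GLY", "SER", "VAL", "LEU", "THR")


def generate_toy_pocket(ligand: LigandState, size: int, rng: np.random.Generator,
                        vocabulary: AtomVocabulary = DEFAULT_VOCABULARY,
                        max_retries: int = 500) -> PocketState:
    """Place ``size`` pocket atoms on a partial shell 3-7 Å from the ligand.

    No pocket atom comes within 2.5 Å of any ligand atom or 1.8 Å of another
    pocket atom; residue ids are assigned in triples of consecutive atoms.
    """
    if size < 10:
        raise ValueError("pocket size must be >= 10")
    lig = ligand.coords[ligand.atom_mask]
    placed = np.zeros((size, 3))
    n_placed = 0
    tries = 0
    while n_placed < size:
        tries += 1
        if tries > max_retries * size:
            raise PlacementError(f"could not place pocket atom {n_placed} after {tries} tries")
        anchor = lig[rng.integers(len(lig))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(3.2, 6.5)
        pos = anchor + radius * direction
        if cdist(pos[None], lig).min() < 2.5:
            continue
        if n_placed and cdist(pos[None], placed[:n_placed]).min() < 1.8:
            continue
        placed[n_placed] = pos
        n_placed += 1
    atom_type = np.array(
        [vocabulary.atom_index(rng.choice(POCKET_ELEMENTS)) for _ in range(size)],
        dtype=np.int64,
    )
    residue_id = np.arange(size) // 3 + 1
    residue_name = np.array([RESIDUE_NAMES[(r - 1) % len(RESIDUE_NAMES)] for r in residue_id],
                            dtype=object)
    return PocketState(
        coords=placed,
        atom_type=atom_type,
        residue_id=residue_id,
        residue_name=residue_name,
        chain_id=np.full(size, "A", dtype=object),
    )


def pocket_to_protein_atoms(pocket: PocketState,
                            vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> ProteinAtoms:
    """View a pocket as a protein-atom table (for re-extraction round trips)."""
    idx = np.where(pocket.atom_mask)[0]
    return ProteinAtoms(
        coords=pocket.coords[idx].copy(),
        element=np.array([vocabulary.atom_types[t] for t in pocket.atom_type[idx]], dtype=object),
        atom_name=np.array([f"X{i}" for i in range(len(idx))], dtype=object),
        residue_id=pocket.residue_id[idx].copy(),
        residue_name=pocket.residue_name[idx].copy(),
        chain_id=pocket.chain_id[idx].copy(),
    )


# ---------------------------------------------------------------------------
# ground-truth affinity
# ---------------------------------------------------------------------------

def contact_count(ligand: LigandState, pocket: PocketState,
                  cutoff_A: float = CONTACT_CUTOFF_A) -> int:
    """Number of ligand-pocket atom pairs closer than ``cutoff_A``."""
    d = cdist(ligand.coords[ligand.atom_mask], pocket.coords[pocket.atom_mask])
    return int((d < cutoff_A).sum())


def synthetic_affinity(record: ComplexRecord,
                       coefficients: tuple[float, ...] = (2.0, 0.08, 0.0),
                       noise_sd: float = 0.2,
                       rng: np.random.Generator | None = None) -> dict[str, float]:
    """Ground-truth endpoint map for a toy complex.

    latent = c0 + c1 * contacts(<4 Å) + c2 * heavy atoms; pIC50 is the latent
    plus Gaussian noise, the other endpoints are fixed affine transforms of
    the same latent with independent noise.  All values clipped to [0, 12].
    """
    if rng is None:
        rng = np.random.default_rng(0)
    c0, c1, c2 = coefficients
    latent = c0 + c1 * contact_count(record.ligand, record.pocket) + c2 * record.ligand.n_atoms
    out = {}
    for endpoint, (scale, offset) in ENDPOINT_TRANSFORMS.items():
        value = scale * latent + offset
        if noise_sd > 0:
            value += rng.normal(scale=noise_sd)
        out[endpoint] = float(np.clip(value, 0.0, 12.0))
    return out


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def build_complex(config: FixtureConfig, index: int,
                  vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> ComplexRecord:
    """Build complex ``index`` of the dataset from its own counter substream."""
    rng = np.random.default_rng([config.seed, index])
    lo, hi = config.ligand_size_range
    ligand = generate_toy_ligand(int(rng.integers(lo, hi + 1)), rng,
                                 noise_sd=config.noise_sd, vocabulary=vocabulary)
    plo, phi = config.pocket_size_range
    pocket = generate_toy_pocket(ligand, int(rng.integers(plo, phi + 1)), rng,
                                 vocabulary=vocabulary)
    record = ComplexRecord(ligand=ligand, pocket=pocket, source_id=f"cplx-{index:04d}")
    record.affinity = synthetic_affinity(record, config.affinity_coefficients,
                                         config.affinity_noise_sd, rng)
    return record.centered_on_pocket()


def build_fixture_dataset(config: FixtureConfig, out_dir=None,
                          vocabulary: AtomVocabulary = DEFAULT_VOCABULARY) -> list[ComplexRecord]:
    """Generate the dataset; optionally write SDF + per-complex PDB + affinity
    CSV + a YAML manifest of the config under ``out_dir``."""
    records = [build_complex(config, i, vocabulary) for i in range(config.n_complexes)]
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ligand_sdf([r.ligand for r in records], out / "ligands.sdf", vocabulary,
                         properties=[{"source_id": r.source_id} for r in records])
        for r in records:
            write_pocket_pdb(r.pocket, out / f"{r.source_id}.pdb", vocabulary)
        write_affinity_csv({r.source_id: r.affinity for r in records}, out / "affinities.csv")
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"fixture_config": config.to_dict()}, fh)
    return records
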