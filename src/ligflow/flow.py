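"""Mixed continuous/discrete flow matching over ligands in a pocket.

Coordinates follow conditional flow matching on the linear path
x_t = (1-t) x0 + t x1 with the l1-prediction parameterization: the network
predicts the clean endpoint X_hat and the sampler integrates the induced
velocity v = (X_hat - x_t) / (1 - t).  Categorical attributes (atom type,
charge, hybridization, bond order) follow a uniform-prior discrete flow:
z_t equals the data category with probability t and a uniform draw
otherwise, and sampling runs the corresponding jump process that resamples
each variable from the predicted clean posterior with probability
dt / (1 - t).  Time runs noise -> data as t: 0 -> 1.

The module also houses the joint model container (:class:`LigandFlowModel`)
and its multi-task training loop (structure + affinity + confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn
from .nn import Adam, Linear, Module, Tensor
from .chem_io import ENDPOINTS, AtomVocabulary, ComplexRecord, LigandState, PocketState
from .equivariant import (
    BackboneConfig,
    DecoderOutput,
    FeatureState,
    LigandDecoder,
    PocketEncoder,
    collate_ligands,
    collate_pockets,
    load_checkpoint,
    pocket_centroid,
    save_checkpoint,
)
from .heads import AffinityHead, LddtConfig, confidence_loss, huber_affinity_loss, lddt_per_atom


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossWeights:
    """Weights of the multi-task objective (all >= 0)."""

    lambda_c: float = 1.0
    lambda_t: float = 0.5
    lambda_ch: float = 0.5
    lambda_h: float = 0.5
    lambda_b: float = 0.5
    lambda_affinity: float = 0.1
    lambda_confidence: float = 0.1

    def __post_init__(self):
        if any(getattr(self, f) < 0 for f in self.__dataclass_fields__):
            raise ValueError("loss weights must be nonnegative")


@dataclass
class SamplerConfig:
    """Generation settings: Euler/jump steps, prior width, mode and seed."""

    steps: int = 100
    noise_sd: float = 2.0
    time_distribution: str = "uniform"
    seed: int = 0
    mode: str = "denovo"
    polish_steps: int = 1  # final denoising decodes at t=1 (structure snap)

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.polish_steps < 0:
            raise ValueError("polish_steps must be >= 0")
        if self.mode not in ("denovo", "fragment", "interaction"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")


@dataclass
class ConditioningMask:
    """Fragment-inpainting mask: fixed atoms/bonds are clamped to a reference
    at every sampler step; interaction flags label pocket atoms."""

    fixed_atoms: np.ndarray
    fixed_bonds: np.ndarray | None = None
    interaction_flags: np.ndarray | None = None

    def __post_init__(self):
        self.fixed_atoms = np.asarray(self.fixed_atoms, dtype=bool)
        n = self.fixed_atoms.shape[0]
        if self.fixed_bonds is None:
            self.fixed_bonds = np.outer(self.fixed_atoms, self.fixed_atoms)
        self.fixed_bonds = np.asarray(self.fixed_bonds, dtype=bool).reshape(n, n)
        if np.any(self.fixed_bonds & ~np.outer(self.fixed_atoms, self.fixed_atoms)):
            raise ValueError("fixed bonds may only connect fixed atoms")


# ---------------------------------------------------------------------------
# prior, interpolation, corruption
# ---------------------------------------------------------------------------

def pocket_frame(pocket_coords: np.ndarray, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sign-fixed principal-axis frame of a pocket: (centroid, 3x3 rotation).

    Prior noise is drawn in this frame, so a rigid motion of the pocket moves
    the drawn prior (and hence the generated ligand) by the same motion for a
    fixed seed.  Axes are covariance eigenvectors ordered by eigenvalue,
    signs fixed by third-moment skewness, handedness fixed to det = +1.
    """
    xyz = pocket_coords if mask is None else pocket_coords[mask]
    center = xyz.mean(axis=0)
    r = xyz - center
    cov = r.T @ r / len(r)
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1].copy()  # descending variance
    for k in range(3):
        s = float(((r @ vecs[:, k]) ** 3).sum())
        if abs(s) < 1e-9:
            s = vecs[np.argmax(np.abs(vecs[:, k])), k]
        if s < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return center, vecs


def sample_prior(n_atoms: int, pocket: PocketState, config: SamplerConfig,
                 rng: np.random.Generator,
                 vocabulary: AtomVocabulary) -> LigandState:
    """Draw the noise endpoint l0: isotropic Gaussian coordinates centered on
    the pocket centroid (drawn in the pocket's principal frame) and uniform
    categorical attributes."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    center, frame = pocket_frame(pocket.coords, pocket.atom_mask)
    z = rng.normal(scale=config.noise_sd, size=(n_atoms, 3)) if config.noise_sd > 0 \
        else np.zeros((n_atoms, 3))
    coords = center + z @ frame.T
    bonds = rng.integers(0, vocabulary.n_bond_orders, size=(n_atoms, n_atoms))
    bonds = np.triu(bonds, 1)
    bonds = bonds + bonds.T
    return LigandState(
        coords=coords,
        atom_type=rng.integers(0, vocabulary.n_atom_types, size=n_atoms),
        charge=rng.integers(0, vocabulary.n_charges, size=n_atoms),
        hybridization=rng.integers(0, vocabulary.n_hybridizations, size=n_atoms),
        bonds=bonds,
    )


def interpolate_coords(x0: np.ndarray, x1: np.ndarray, t) -> np.ndarray:
    """Linear conditional path x_t = (1-t) x0 + t x1."""
    x0, x1 = np.asarray(x0, dtype=np.float64), np.asarray(x1, dtype=np.float64)
    if x0.shape != x1.shape:
        raise ValueError("shape mismatch between prior and data coordinates")
    t = np.asarray(t, dtype=np.float64)
    while t.ndim < x0.ndim:
        t = t[..., None]
    return (1.0 - t) * x0 + t * x1


def corrupt_categorical(z1: np.ndarray, t, n_categories: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Uniform-prior discrete corruption: keep the data category with
    probability t, else draw uniformly over the vocabulary.  Hence
    P(z_t = z1) = t + (1-t)/K."""
    z1 = np.asarray(z1)
    t = np.broadcast_to(np.asarray(t, dtype=np.float64).reshape((-1,) + (1,) * (z1.ndim - 1)),
                        z1.shape) if np.ndim(t) > 0 else np.full(z1.shape, float(t))
    keep = rng.random(z1.shape) < t
    uniform = rng.integers(0, n_categories, size=z1.shape)
    return np.where(keep, z1, uniform)


def corrupt_bonds(b1: np.ndarray, t, n_categories: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Symmetric bond corruption: corrupt the upper triangle, mirror down."""
    bt = corrupt_categorical(b1, t, n_categories, rng)
    upper = np.triu(bt, 1) if bt.ndim == 2 else np.triu(bt.swapaxes(0, 0), 1)
    if bt.ndim == 3:
        upper = np.stack([np.triu(m, 1) for m in bt])
        return upper + upper.swapaxes(-1, -2)
    return upper + upper.T


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _masked_ce(logits: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean cross-entropy over entries where mask is True."""
    k = logits.shape[-1]
    lsm = nn.log_softmax(logits, axis=-1).reshape(-1, k)
    picked = lsm[np.arange(lsm.shape[0]), target.reshape(-1)]
    m = mask.astype(np.float64).reshape(-1)
    return -(picked * m).sum() * (1.0 / max(m.sum(), 1.0))


def total_loss(prediction: DecoderOutput, target: dict[str, np.ndarray],
               weights: LossWeights) -> tuple[Tensor, dict[str, float]]:
    """Weighted structure loss: coordinate MSE plus cross-entropies for atom
    type, charge, hybridization and bond order.

    MSE averages over unmasked atoms and the 3 coordinates; categorical terms
    average over unmasked atoms (bonds: unmasked pairs i < j).  Returns the
    weighted sum and the per-term unweighted values.
    """
    mask = target["mask"]
    m3 = mask.astype(np.float64)[..., None]
    n_atoms = max(mask.sum(), 1)
    diff = (prediction.coords - Tensor(target["coords"])) * m3
    mse = (diff * diff).sum() * (1.0 / (3.0 * n_atoms))

    ce_t = _masked_ce(prediction.type_logits, target["atom_type"], mask)
    ce_q = _masked_ce(prediction.charge_logits, target["charge"], mask)
    ce_h = _masked_ce(prediction.hyb_logits, target["hybridization"], mask)

    n = mask.shape[1]
    pair_mask = mask[:, :, None] & mask[:, None, :] & np.triu(np.ones((n, n), dtype=bool), 1)
    ce_b = _masked_ce(prediction.bond_logits, target["bonds"], pair_mask)

    terms = {"coord_mse": mse, "type_ce": ce_t, "charge_ce": ce_q,
             "hyb_ce": ce_h, "bond_ce": ce_b}
    total = (weights.lambda_c * mse + weights.lambda_t * ce_t
             + weights.lambda_ch * ce_q + weights.lambda_h * ce_h
             + weights.lambda_b * ce_b)
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite structure loss")
    return total, {k: float(v.data) for k, v in terms.items()}


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_posterior(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw category indices from softmax(logits) along the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    cum = np.cumsum(p, axis=-1)
    u = rng.random(cum.shape[:-1] + (1,))
    return (u > cum).sum(axis=-1)


def integrate_step(batch: dict[str, np.ndarray], prediction: DecoderOutput,
                   t: float, dt: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One Euler/jump step from time t to t+dt on a collated ligand batch.

    Coordinates move along the l1-parameterized velocity
    v = (X_hat - x_t)/(1-t); each categorical variable jumps to a draw from
    the predicted clean posterior with probability dt/(1-t) (clamped at 1).
    At t+dt >= 1 coordinates equal X_hat and categoricals the argmax.
    """
    if not (0.0 <= t < 1.0) or not (0.0 < dt <= 1.0 - t + 1e-12):
        raise ValueError(f"invalid step t={t}, dt={dt}")
    out = {k: v.copy() for k, v in batch.items()}
    mask = batch["mask"]
    m3 = mask[..., None]
    x_hat = prediction.coords.data
    final = t + dt >= 1.0 - 1e-12
    if final:
        out["coords"] = np.where(m3, x_hat, 0.0)
    else:
        v = (x_hat - batch["coords"]) / (1.0 - t)
        out["coords"] = np.where(m3, batch["coords"] + dt * v, 0.0)

    p_jump = min(dt / (1.0 - t), 1.0)
    for key, logits in (("atom_type", prediction.type_logits.data),
                        ("charge", prediction.charge_logits.data),
                        ("hybridization", prediction.hyb_logits.data)):
        if final:
            new = np.argmax(logits, axis=-1)
        else:
            draw = _sample_posterior(logits, rng)
            jump = rng.random(batch[key].shape) < p_jump
            new = np.where(jump, draw, batch[key])
        out[key] = np.where(mask, new, 0)

    bond_logits = prediction.bond_logits.data
    if final:
        new_b = np.argmax(bond_logits, axis=-1)
    else:
        draw = _sample_posterior(bond_logits, rng)
        jump = rng.random(batch["bonds"].shape) < p_jump
        new_b = np.where(jump, draw, batch["bonds"])
    upper = np.stack([np.triu(m_, 1) for m_ in new_b])
    new_b = upper + upper.swapaxes(-1, -2)
    pair_mask = mask[:, :, None] & mask[:, None, :]
    out["bonds"] = np.where(pair_mask, new_b, 0)
    return out


def apply_conditioning(batch: dict[str, np.ndarray], mask: ConditioningMask,
                       reference: LigandState) -> dict[str, np.ndarray]:
    """Clamp fixed atoms/bonds of a collated batch to the reference ligand."""
    fixed = mask.fixed_atoms
    n_ref = reference.n_slots
    if fixed.shape[0] != n_ref:
        raise ValueError("conditioning mask does not match the reference ligand")
    out = {k: v.copy() for k, v in batch.items()}
    idx = np.where(fixed)[0]
    out["coords"][:, idx] = reference.coords[idx]
    out["atom_type"][:, idx] = reference.atom_type[idx]
    out["charge"][:, idx] = reference.charge[idx]
    out["hybridization"][:, idx] = reference.hybridization[idx]
    bi, bj = np.where(mask.fixed_bonds)
    out["bonds"][:, bi, bj] = reference.bonds[bi, bj]
    return out


# ---------------------------------------------------------------------------
# the joint model
# ---------------------------------------------------------------------------

class LigandFlowModel(Module):
    """Pocket encoder + ligand decoder + affinity and confidence heads."""

    def __init__(self, vocab: AtomVocabulary, config: BackboneConfig,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.config = config
        self.encoder = PocketEncoder(vocab, config, rng)
        self.decoder = LigandDecoder(vocab, config, rng)
        self.affinity_head = AffinityHead(config, rng)
        self.confidence_proj = Linear(config.d_inv_dec, 50, rng)

    # -- forward pieces ----------------------------------------------------
    def encode_pocket(self, pockets: list[PocketState],
                      interaction_flags: list[np.ndarray] | None = None):
        batch = collate_pockets(pockets, interaction_flags=interaction_flags)
        state, center = self.encoder(batch)
        coords_centered = (batch["coords"] - center) * batch["mask"][..., None]
        return state, center, coords_centered

    def decode(self, lig_batch: dict[str, np.ndarray], t: np.ndarray,
               pocket_state: FeatureState, pocket_coords_centered: np.ndarray,
               center: np.ndarray, n_layers: int | None = None) -> DecoderOutput:
        return self.decoder(lig_batch, t, pocket_state, pocket_coords_centered,
                            center, n_layers=n_layers)

    def confidence_logits(self, pred: DecoderOutput, pocket_state: FeatureState,
                          pocket_coords_centered: np.ndarray, center: np.ndarray) -> Tensor:
        """Reduced-depth pass over the predicted clean structure l1_hat."""
        hard = {
            "coords": pred.coords.data,
            "atom_type": np.argmax(pred.type_logits.data, axis=-1),
            "charge": np.argmax(pred.charge_logits.data, axis=-1),
            "hybridization": np.argmax(pred.hyb_logits.data, axis=-1),
            "bonds": _sym_argmax(pred.bond_logits.data),
            "mask": pred.mask,
        }
        for key in ("atom_type", "charge", "hybridization"):
            hard[key] = np.where(pred.mask, hard[key], 0)
        out = self.decoder(hard, np.ones(pred.mask.shape[0]), pocket_state,
                           pocket_coords_centered, center,
                           n_layers=self.config.confidence_depth)
        return self.confidence_proj(out.ligand_state.inv)

    # -- persistence ---------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        save_checkpoint(path, {"model": self}, self.config, self.vocab, extra)

    @classmethod
    def load(cls, path) -> tuple["LigandFlowModel", dict]:
        states, config, vocab, extra = load_checkpoint(path)
        model = cls(vocab, config, seed=0)
        model.load_state_dict(states["model"])
        return model, extra


def _sym_argmax(bond_logits: np.ndarray) -> np.ndarray:
    b = np.argmax(bond_logits, axis=-1)
    upper = np.stack([np.triu(m, 1) for m in b])
    return upper + upper.swapaxes(-1, -2)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def draw_sizes(reference_size: int, n: int, rng: np.random.Generator,
               margin: float = 0.10) -> np.ndarray:
    """Ligand sizes uniform within +/- margin of a reference size."""
    lo = max(3, int(np.floor(reference_size * (1 - margin))))
    hi = max(lo, int(np.ceil(reference_size * (1 + margin))))
    return rng.integers(lo, hi + 1, size=n)


def generate(model: LigandFlowModel, pocket: PocketState, n_ligands: int,
             sizes: np.ndarray | int, config: SamplerConfig,
             conditioning: ConditioningMask | None = None,
             reference: LigandState | None = None,
             return_prediction: bool = False):
    """Sample ``n_ligands`` ligands for one pocket by iterative refinement of
    a noisy prior.  ``sizes`` is an int (shared) or per-ligand array.
    Fragment mode clamps the conditioning reference at every step.
    Seed-deterministic through ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "fragment" and (conditioning is None or reference is None):
        raise ValueError("fragment mode needs a conditioning mask and reference")
    sizes = np.full(n_ligands, sizes, dtype=np.int64) if np.isscalar(sizes) \
        else np.asarray(sizes, dtype=np.int64)
    if sizes.shape[0] != n_ligands or np.any(sizes < 1):
        raise ValueError("invalid size specification")

    flags = None
    if config.mode == "interaction" and conditioning is not None \
            and conditioning.interaction_flags is not None:
        flags = [conditioning.interaction_flags]
    pocket_state, center, pocket_xyz = model.encode_pocket([pocket], flags)
    n_slots = int(sizes.max())
    priors = [sample_prior(int(s), pocket, config, rng, model.vocab) for s in sizes]
    batch = collate_ligands(priors, model.vocab, n_slots)
    B = n_ligands
    pstate = _tile_pocket(pocket_state, B)
    pxyz = np.repeat(pocket_xyz, B, axis=0)
    pcenter = np.repeat(center, B, axis=0)

    dt = 1.0 / config.steps
    pred = None
    for step in range(config.steps):
        t = step * dt
        if conditioning is not None and reference is not None:
            batch = apply_conditioning(batch, conditioning, reference)
        pred = model.decode(batch, np.full(B, t), pstate, pxyz, pcenter)
        batch = integrate_step(batch, pred, t, dt, rng)
    for _ in range(config.polish_steps):
        # denoising snap: one decode of the finished structure at t=1
        if conditioning is not None and reference is not None:
            batch = apply_conditioning(batch, conditioning, reference)
        pred = model.decode(batch, np.ones(B), pstate, pxyz, pcenter)
        batch = _hard_assign(batch, pred)
    if conditioning is not None and reference is not None:
        batch = apply_conditioning(batch, conditioning, reference)

    ligands = []
    for b in range(B):
        n = int(sizes[b])
        ligands.append(LigandState(
            coords=batch["coords"][b, :n],
            atom_type=batch["atom_type"][b, :n],
            charge=batch["charge"][b, :n],
            hybridization=batch["hybridization"][b, :n],
            bonds=batch["bonds"][b, :n, :n],
        ))
    return (ligands, batch, pred) if return_prediction else ligands


def _hard_assign(batch: dict[str, np.ndarray], pred: DecoderOutput) -> dict[str, np.ndarray]:
    """Replace a batch with the prediction's clean state (argmax categories)."""
    mask = batch["mask"]
    out = dict(batch)
    out["coords"] = np.where(mask[..., None], pred.coords.data, 0.0)
    for key, logits in (("atom_type", pred.type_logits.data),
                        ("charge", pred.charge_logits.data),
                        ("hybridization", pred.hyb_logits.data)):
        out[key] = np.where(mask, np.argmax(logits, axis=-1), 0)
    b = _sym_argmax(pred.bond_logits.data)
    out["bonds"] = np.where(mask[:, :, None] & mask[:, None, :], b, 0)
    return out


def _tile_pocket(state: FeatureState, B: int) -> FeatureState:
    def rep(x: Tensor) -> Tensor:
        reps = (B,) + (1,) * (x.ndim - 1)
        return Tensor(np.tile(x.data, reps))

    return FeatureState(inv=rep(state.inv), equi=rep(state.equi),
                        edges=None if state.edges is None else rep(state.edges),
                        mask=np.repeat(state.mask, B, axis=0))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings for the joint multi-task objective."""

    n_steps: int = 600
    batch_size: int = 8
    lr: float = 2e-3
    lr_min_factor: float = 0.05   # cosine decay floor as a fraction of lr
    seed: int = 0
    log_every: int = 25
    confidence_every: int = 3  # confidence pass on every k-th step
    coord_input_noise_sd: float = 0.2  # robustness jitter on x_t (A); see methods
    affinity_t_min: float = 0.7  # affinity loss only where latents see near-clean input
    t_one_fraction: float = 0.0  # fraction of samples pinned to t=1 (clean input)
    lddt: LddtConfig = field(default_factory=LddtConfig)


def _collate_dataset(records: list[ComplexRecord], vocab: AtomVocabulary):
    lig = collate_ligands([r.ligand for r in records], vocab)
    pock = collate_pockets([r.pocket for r in records])
    aff = np.zeros((len(records), len(ENDPOINTS)))
    aff_mask = np.zeros((len(records), len(ENDPOINTS)), dtype=bool)
    for i, r in enumerate(records):
        for j, ep in enumerate(ENDPOINTS):
            if ep in r.affinity:
                aff[i, j] = r.affinity[ep]
                aff_mask[i, j] = True
    return lig, pock, aff, aff_mask


def _take(batch: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[idx] for k, v in batch.items()}


def train(records: list[ComplexRecord], model: LigandFlowModel,
          weights: LossWeights = LossWeights(),
          config: TrainConfig = TrainConfig(),
          callback=None) -> list[dict[str, float]]:
    """Joint training: structure flow matching + masked Huber affinity +
    binned-lDDT confidence.  Returns the per-step loss trace.

    Each step draws a batch, a flow time t ~ U(0,1) per sample, corrupts the
    clean ligands toward pocket-frame noise, decodes, and minimizes
    L_total + lambda_affinity * L_affinity + lambda_confidence * L_confidence.
    Raises on divergence (non-finite loss).
    """
    if not records:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    lig_all, pock_all, aff_all, aff_mask_all = _collate_dataset(records, model.vocab)
    vocab = model.vocab
    prior_sd = SamplerConfig().noise_sd
    centroids = pocket_centroid(pock_all["coords"], pock_all["mask"])

    optim = Adam(model.parameters(), lr=config.lr)
    trace: list[dict[str, float]] = []
    n = len(records)
    for step in range(config.n_steps):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        lig = _take(lig_all, idx)
        pock = {k: pock_all[k][idx] for k in pock_all}
        t = rng.uniform(0.0, 1.0, size=len(idx))
        if config.t_one_fraction > 0:
            # pin a slice of each batch to t=1: the affinity and confidence
            # heads consume clean-structure latents at prediction time
            n_one = int(round(config.t_one_fraction * len(idx)))
            if n_one:
                t[:n_one] = 1.0

        noisy = dict(lig)
        # fresh prior endpoint each step: isotropic Gaussian at the pocket centroid
        x0 = centroids[idx] + rng.normal(scale=prior_sd, size=lig["coords"].shape)
        # optimal-transport pairing of prior and data atoms: without it the
        # conditional mean at low t collapses every atom onto the centroid
        # (atoms are exchangeable), and sampled trajectories contract
        for b in range(x0.shape[0]):
            m = lig["mask"][b]
            if m.sum() > 1:
                valid = np.where(m)[0]
                sub = x0[b][valid].copy()
                cost = ((sub[:, None] - lig["coords"][b][valid][None]) ** 2).sum(-1)
                rows, cols = linear_sum_assignment(cost)
                x0[b, valid[cols]] = sub[rows]
        x_t = interpolate_coords(x0, lig["coords"], t)
        if config.coord_input_noise_sd > 0:
            # small jitter keeps the decoder contractive on the imperfect
            # structures it sees when integrating its own predictions
            x_t = x_t + rng.normal(scale=config.coord_input_noise_sd, size=x_t.shape)
        noisy["coords"] = np.where(lig["mask"][..., None], x_t, 0.0)
        noisy["atom_type"] = np.where(lig["mask"], corrupt_categorical(
            lig["atom_type"], t, vocab.n_atom_types, rng), 0)
        noisy["charge"] = np.where(lig["mask"], corrupt_categorical(
            lig["charge"], t, vocab.n_charges, rng), 0)
        noisy["hybridization"] = np.where(lig["mask"], corrupt_categorical(
            lig["hybridization"], t, vocab.n_hybridizations, rng), 0)
        bt = corrupt_bonds(lig["bonds"], t, vocab.n_bond_orders, rng)
        pair_mask = lig["mask"][:, :, None] & lig["mask"][:, None, :]
        noisy["bonds"] = np.where(pair_mask, bt, 0)

        pocket_state, center = model.encoder(pock)
        pock_xyz = (pock["coords"] - center) * pock["mask"][..., None]
        pred = model.decode(noisy, t, pocket_state, pock_xyz, center)
        loss, terms = total_loss(pred, lig, weights)

        t_ok = t >= config.affinity_t_min
        if weights.lambda_affinity > 0 and t_ok.any():
            aff_pred = model.affinity_head.forward_raw(pred.ligand_state, pocket_state,
                                                       pred.cross_edges)
            # only samples whose latents saw near-clean structure carry an
            # affinity signal; prediction runs at t = 1
            aff_mask = aff_mask_all[idx] & t_ok[:, None]
            l_aff = huber_affinity_loss(aff_pred, aff_all[idx], aff_mask)
            loss = loss + weights.lambda_affinity * l_aff
            terms["affinity_huber"] = float(l_aff.data)

        if weights.lambda_confidence > 0 and step % config.confidence_every == 0:
            logits = model.confidence_logits(pred, pocket_state, pock_xyz, center)
            true_scores = _true_lddt_batch(lig, pock, pred.coords.data, config.lddt)
            l_conf = confidence_loss(logits, true_scores, mask=lig["mask"],
                                     k=config.lddt.bins)
            loss = loss + weights.lambda_confidence * l_conf
            terms["confidence_ce"] = float(l_conf.data)

        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at step {step}: loss={loss.data}, terms={terms}")
        model.zero_grad()
        loss.backward()
        # cosine learning-rate decay: late training needs small steps to pin
        # down sub-Angstrom geometry
        frac = step / max(config.n_steps - 1, 1)
        floor = config.lr_min_factor
        optim.lr = config.lr * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac)))
        optim.step()
        terms["total"] = float(loss.data)
        terms["step"] = step
        trace.append(terms)
        if callback is not None and step % config.log_every == 0:
            callback(step, terms)
    return trace


def _true_lddt_batch(lig: dict[str, np.ndarray], pock: dict[str, np.ndarray],
                     pred_coords: np.ndarray, cfg: LddtConfig) -> np.ndarray:
    """Per-atom lDDT of the predicted vs true ligand-pocket distances,
    computed per batch element over valid pocket atoms (padding rows 0)."""
    B, N = lig["mask"].shape
    out = np.zeros((B, N))
    for b in range(B):
        lm, pm = lig["mask"][b], pock["mask"][b]
        if not lm.any() or not pm.any():
            continue
        d_true = np.linalg.norm(lig["coords"][b][lm][:, None] - pock["coords"][b][pm][None],
                                axis=-1)
        d_pred = np.linalg.norm(pred_coords[b][lm][:, None] - pock["coords"][b][pm][None],
                                axis=-1)
        out[b, lm] = lddt_per_atom(d_true, d_pred, cfg)
    return out


def finetune_affinity_head(records: list[ComplexRecord], model: LigandFlowModel,
                           n_steps: int = 1200, batch_size: int = 32,
                           lr: float = 1e-3, seed: int = 0,
                           delta: float = 1.0,
                           stop_at_loss: float | None = 0.02) -> list[float]:
    """Stage-two affinity training: freeze the backbone, cache clean-complex
    (t=1) decoder latents once, and train only the affinity head on them.

    The backbone learns its representation jointly; this stage lets the small
    endpoint head converge fully on the fixed representation at negligible
    cost (one decode per complex, then head-only gradient steps).  Returns
    the loss trace.
    """
    rng = np.random.default_rng(seed)
    caches = []
    aff = np.zeros((len(records), len(ENDPOINTS)))
    aff_mask = np.zeros((len(records), len(ENDPOINTS)), dtype=bool)
    with nn.no_grad():
        for i, rec in enumerate(records):
            r = rec.centered_on_pocket()
            lig = collate_ligands([r.ligand], model.vocab)
            pocket_state, center, pock_xyz = model.encode_pocket([r.pocket])
            pred = model.decode(lig, np.ones(1), pocket_state, pock_xyz, center)
            caches.append({
                "lig_inv": pred.ligand_state.inv.data[0],
                "lig_equi": pred.ligand_state.equi.data[0],
                "lig_mask": lig["mask"][0],
                "p_inv": pocket_state.inv.data[0],
                "p_equi": pocket_state.equi.data[0],
                "p_mask": pocket_state.mask[0],
                "cross": pred.cross_edges.data[0],
            })
            for j, ep in enumerate(ENDPOINTS):
                if ep in rec.affinity:
                    aff[i, j] = rec.affinity[ep]
                    aff_mask[i, j] = True

    head = model.affinity_head
    optim = Adam(head.parameters(), lr=lr)
    trace = []
    n = len(records)
    nl = max(c["lig_inv"].shape[0] for c in caches)
    npk = max(c["p_inv"].shape[0] for c in caches)

    def pad(arr, rows):
        out = np.zeros((rows,) + arr.shape[1:])
        out[: arr.shape[0]] = arr
        return out

    for step in range(n_steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        lig_state = FeatureState(
            inv=Tensor(np.stack([pad(caches[i]["lig_inv"], nl) for i in idx])),
            equi=Tensor(np.stack([pad(caches[i]["lig_equi"], nl) for i in idx])),
            edges=None,
            mask=np.stack([pad(caches[i]["lig_mask"][:, None], nl)[:, 0].astype(bool)
                           for i in idx]),
        )
        pocket_state = FeatureState(
            inv=Tensor(np.stack([pad(caches[i]["p_inv"], npk) for i in idx])),
            equi=Tensor(np.stack([pad(caches[i]["p_equi"], npk) for i in idx])),
            edges=None,
            mask=np.stack([pad(caches[i]["p_mask"][:, None], npk)[:, 0].astype(bool)
                           for i in idx]),
        )
        cross = Tensor(np.stack([
            pad(pad(caches[i]["cross"], nl).swapaxes(0, 1), npk).swapaxes(0, 1)
            for i in idx]))
        pred = head.forward_raw(lig_state, pocket_state, cross)
        loss = huber_affinity_loss(pred, aff[idx], aff_mask[idx], delta=delta)
        for p in head.parameters():
            p.grad = None
        loss.backward()
        frac = step / max(n_steps - 1, 1)
        optim.lr = lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))
        optim.step()
        trace.append(float(loss.data))
        # fitting below the observation-noise floor of the labels only
        # memorizes noise; stop once the running loss reaches it
        if stop_at_loss is not None and len(trace) >= 20 \
                and float(np.mean(trace[-20:])) < stop_at_loss:
            break
    return trace


# ---------------------------------------------------------------------------
# prediction convenience
# ---------------------------------------------------------------------------

def predict_affinity_batch(model: LigandFlowModel, ligands: list[LigandState],
                           pocket: PocketState) -> np.ndarray:
    """Predict (n, 4) endpoint affinities for many ligands in one pocket.

    One batched decode at t = 1; equivalent to per-ligand
    :func:`predict_affinity` up to padding-invariant arithmetic.
    """
    offset = -pocket.centroid()
    pocket_c = pocket.translated(offset)
    ligs_c = [lig.translated(offset) for lig in ligands]
    batch = collate_ligands(ligs_c, model.vocab)
    pocket_state, center, pock_xyz = model.encode_pocket([pocket_c])
    B = len(ligands)
    pstate = _tile_pocket(pocket_state, B)
    pred = model.decode(batch, np.ones(B), pstate,
                        np.repeat(pock_xyz, B, axis=0), np.repeat(center, B, axis=0))
    aff = model.affinity_head(pred.ligand_state, pstate, pred.cross_edges)
    return aff.data.copy()


def predict_affinity(model: LigandFlowModel, record: ComplexRecord):
    """Predict four-endpoint affinity and pLDDT for a clean complex (t=1)."""
    from .heads import AffinityPrediction, ConfidenceOutput

    rec = record.centered_on_pocket()
    lig = collate_ligands([rec.ligand], model.vocab)
    pocket_state, center, pock_xyz = model.encode_pocket([rec.pocket])
    pred = model.decode(lig, np.ones(1), pocket_state, pock_xyz, center)
    aff = model.affinity_head(pred.ligand_state, pocket_state, pred.cross_edges)
    logits = model.confidence_logits(pred, pocket_state, pock_xyz, center)
    conf = ConfidenceOutput.from_logits(logits.data[0][lig["mask"][0]])
    return AffinityPrediction.from_array(aff.data[0]), conf
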