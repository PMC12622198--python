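"""Inference-time steering via sequential Monte Carlo importance sampling.

An ensemble of B generation trajectories ("particles") is advanced by the
unguided sampler; at scheduled times inside a steering window the current
denoised estimates l1_hat are scored by a reward built from the model's own
affinity head (single- or dual-objective, e.g. maximize on-target while
minimizing off-target affinity), converted to importance weights by a
temperature-scaled softmax, and the ensemble is resampled from
Multinomial(B, w).  This biases the final samples toward the target
distribution proportional to reward x model probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import no_grad
from .chem_io import ENDPOINTS, LigandState, PocketState
from .equivariant import FeatureState, collate_ligands
from .flow import (
    ConditioningMask,
    LigandFlowModel,
    SamplerConfig,
    _hard_assign,
    _tile_pocket,
    apply_conditioning,
    integrate_step,
    sample_prior,
)


@dataclass(frozen=True)
class Objective:
    """One reward term: an endpoint on a named pocket, with direction/weight."""

    pocket: str
    endpoint: str = "pIC50"
    direction: str = "maximize"
    weight: float = 1.0

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be maximize or minimize")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "maximize" else -1.0


@dataclass(frozen=True)
class RewardSpec:
    """A weighted list of objectives with a softmax temperature lambda."""

    objectives: tuple[Objective, ...]
    temperature: float = 1.0

    def __post_init__(self):
        if len(self.objectives) == 0:
            raise ValueError("reward needs at least one objective")
        if not np.isfinite([o.weight for o in self.objectives]).all():
            raise ValueError("objective weights must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ParticleEnsemble:
    """B concurrent trajectories with scores and normalized weights."""

    batch: dict[str, np.ndarray]     # collated ligand states at time tau
    scores: np.ndarray               # (B,) reward scores y_hat
    weights: np.ndarray              # (B,) importance weights, sum 1

    def __post_init__(self):
        B = self.batch["mask"].shape[0]
        if B < 2:
            raise ValueError("ensemble needs B >= 2 particles")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def n_particles(self) -> int:
        return self.batch["mask"].shape[0]


@dataclass
class _PocketContext:
    state: FeatureState
    center: np.ndarray
    coords_centered: np.ndarray
    pocket: PocketState


def _encode_pockets(model: LigandFlowModel, pockets: dict[str, PocketState],
                    B: int) -> dict[str, _PocketContext]:
    out = {}
    for name, pocket in pockets.items():
        state, center, xyz = model.encode_pocket([pocket])
        out[name] = _PocketContext(
            state=_tile_pocket(state, B),
            center=np.repeat(center, B, axis=0),
            coords_centered=np.repeat(xyz, B, axis=0),
            pocket=pocket,
        )
    return out


def evaluate_reward(model: LigandFlowModel, l1_batch: dict[str, np.ndarray],
                    contexts: dict[str, _PocketContext], spec: RewardSpec) -> np.ndarray:
    """Score denoised estimates: signed weighted sum of endpoint predictions.

    Each objective decodes l1_hat at t=1 against its own pocket and reads the
    requested endpoint from the affinity head.
    """
    B = l1_batch["mask"].shape[0]
    scores = np.zeros(B)
    with no_grad():
        for obj in spec.objectives:
            if obj.pocket not in contexts:
                raise KeyError(f"pocket {obj.pocket!r} not available for reward")
            ctx = contexts[obj.pocket]
            pred = model.decode(l1_batch, np.ones(B), ctx.state,
                                ctx.coords_centered, ctx.center)
            aff = model.affinity_head(pred.ligand_state, ctx.state, pred.cross_edges)
            scores += obj.weight * obj.sign * aff.data[:, ENDPOINTS.index(obj.endpoint)]
    return scores


def resampling_weights(scores: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Softmax importance weights w_i = softmax(lambda * y_hat)_i.

    Shift-invariant and numerically stabilized by max subtraction.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite reward scores")
    z = temperature * scores
    e = np.exp(z - z.max())
    return e / e.sum()


def resample(ensemble: ParticleEnsemble, rng: np.random.Generator) -> ParticleEnsemble:
    """Multinomial resampling with replacement proportional to the weights;
    weights reset to uniform afterwards."""
    w = ensemble.weights
    if w.sum() <= 0:
        raise ValueError("degenerate all-zero weights")
    B = ensemble.n_particles
    idx = rng.choice(B, size=B, replace=True, p=w / w.sum())
    batch = {k: v[idx] for k, v in ensemble.batch.items()}
    return ParticleEnsemble(batch=batch, scores=ensemble.scores[idx],
                            weights=np.full(B, 1.0 / B))


@dataclass
class SteeringSchedule:
    """Resampling window [start, stop] (fractions of the trajectory) and
    cadence in integration steps."""

    start: float = 0.0
    stop: float = 0.5
    every: int = 10

    def __post_init__(self):
        if not (0.0 <= self.start <= self.stop <= 1.0):
            raise ValueError("need 0 <= start <= stop <= 1")
        if self.every < 1:
            raise ValueError("cadence must be >= 1 step")


def steered_generate(model: LigandFlowModel, pockets: dict[str, PocketState],
                     generation_pocket: str, spec: RewardSpec, B: int,
                     schedule: SteeringSchedule, sampler: SamplerConfig,
                     sizes: np.ndarray | int,
                     conditioning: ConditioningMask | None = None,
                     reference: LigandState | None = None
                     ) -> tuple[list[LigandState], np.ndarray]:
    """Run B parallel trajectories on ``generation_pocket``; inside the
    steering window, evaluate rewards on the current denoised estimates every
    ``schedule.every`` steps, softmax-weight and multinomially resample.
    Outside the window the sampler is unguided.  Returns the final B ligands
    and their last reward scores."""
    if B < 2:
        raise ValueError("steering needs B >= 2 particles")
    rng = np.random.default_rng(sampler.seed)
    contexts = _encode_pockets(model, pockets, B)
    gen = contexts[generation_pocket]

    sizes_arr = np.full(B, sizes, dtype=np.int64) if np.isscalar(sizes) \
        else np.asarray(sizes, dtype=np.int64)
    priors = [sample_prior(int(s), gen.pocket, sampler, rng, model.vocab)
              for s in sizes_arr]
    batch = collate_ligands(priors, model.vocab, int(sizes_arr.max()))

    scores = np.zeros(B)
    dt = 1.0 / sampler.steps
    window = schedule.stop > schedule.start
    with no_grad():
        for step in range(sampler.steps):
            t = step * dt
            if conditioning is not None and reference is not None:
                batch = apply_conditioning(batch, conditioning, reference)
            pred = model.decode(batch, np.full(B, t), gen.state,
                                gen.coords_centered, gen.center)
            steer_now = (window and schedule.start <= t <= schedule.stop
                         and step % schedule.every == 0)
            if steer_now:
                l1 = {
                    "coords": pred.coords.data,
                    "atom_type": np.argmax(pred.type_logits.data, axis=-1),
                    "charge": np.argmax(pred.charge_logits.data, axis=-1),
                    "hybridization": np.argmax(pred.hyb_logits.data, axis=-1),
                    "bonds": _sym_bond_argmax(pred.bond_logits.data),
                    "mask": batch["mask"],
                }
                for key in ("atom_type", "charge", "hybridization"):
                    l1[key] = np.where(batch["mask"], l1[key], 0)
                scores = evaluate_reward(model, l1, contexts, spec)
                weights = resampling_weights(scores, spec.temperature)
                ens = ParticleEnsemble(batch=batch, scores=scores, weights=weights)
                ens = resample(ens, rng)
                batch, scores = ens.batch, ens.scores
                pred = model.decode(batch, np.full(B, t), gen.state,
                                    gen.coords_centered, gen.center)
            batch = integrate_step(batch, pred, t, dt, rng)
        for _ in range(sampler.polish_steps):
            if conditioning is not None and reference is not None:
                batch = apply_conditioning(batch, conditioning, reference)
            pred = model.decode(batch, np.full(B, 1.0), gen.state,
                                gen.coords_centered, gen.center)
            batch = _hard_assign(batch, pred)
        if conditioning is not None and reference is not None:
            batch = apply_conditioning(batch, conditioning, reference)

    ligands = []
    for b in range(B):
        m = batch["mask"][b]
        n = int(m.sum())
        ligands.append(LigandState(
            coords=batch["coords"][b, :n],
            atom_type=batch["atom_type"][b, :n],
            charge=batch["charge"][b, :n],
            hybridization=batch["hybridization"][b, :n],
            bonds=batch["bonds"][b, :n, :n],
        ))
    return ligands, scores


def _sym_bond_argmax(bond_logits: np.ndarray) -> np.ndarray:
    b = np.argmax(bond_logits, axis=-1)
    upper = np.stack([np.triu(m, 1) for m in b])
    return upper + upper.swapaxes(-1, -2)
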