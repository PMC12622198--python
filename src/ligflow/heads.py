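"""Prediction heads: four-endpoint binding affinity, lDDT/pLDDT confidence,
free-energy conversion, endpoint aggregation and the regression metric stack.

Affinity values are log-unit potencies (pIC50/pKi/pKd/pEC50, nonnegative by
the ReLU output contract).  Confidence is a per-atom local distance
difference test (lDDT) against the pocket, binned into k classes for
cross-entropy training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import nn
from .nn import MLP, Linear, Module, Tensor
from .chem_io import ENDPOINTS
from .equivariant import BackboneConfig, FeatureState, GatedEquivariantBlock

R_KCAL_PER_K_MOL = 1.987e-3  # universal gas constant, kcal K^-1 mol^-1
T_KELVIN = 298.0             # absolute temperature used for dG conversion
LIGAND_POOL_C = 100.0        # fixed normalizer of the ligand sum-pool branch


class EmptyLigandError(ValueError):
    """Affinity pooling over an all-masked ligand or pocket."""


# ---------------------------------------------------------------------------
# affinity
# ---------------------------------------------------------------------------

@dataclass
class AffinityPrediction:
    """Four nonnegative log-unit endpoint values plus a validity mask."""

    pIC50: float
    pKi: float
    pKd: float
    pEC50: float
    endpoint_mask: tuple[bool, bool, bool, bool] = (True, True, True, True)

    def __post_init__(self):
        for ep in ENDPOINTS:
            if getattr(self, ep) < 0:
                raise ValueError(f"{ep} must be >= 0 (ReLU output contract)")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, ep) for ep in ENDPOINTS])

    @classmethod
    def from_array(cls, values: np.ndarray, mask=None) -> "AffinityPrediction":
        mask = tuple(bool(b) for b in (mask if mask is not None else (True,) * 4))
        return cls(*[float(v) for v in values], endpoint_mask=mask)


class AffinityHead(Module):
    """Pool decoder latents into four endpoint predictions.

    Ligand and pocket node features are fused by gated equivariant blocks
    (rotation invariant); the ligand branch concatenates a 1/C sum pool
    (C=100, carries molecule size) with a mean pool, the pocket branch mean
    pools, and the interaction branch takes the mask-weighted mean of the
    ligand-pocket cross-edge features.  Endpoint-specific MLPs with a final
    ReLU map the concatenated representation to nonnegative log-unit values.
    """

    def __init__(self, config: BackboneConfig, rng):
        d_lig, d_pock = config.d_inv_dec, config.d_inv_enc
        d_z = config.d_inv_dec
        self.gate_lig = GatedEquivariantBlock(d_lig, config.d_equi, d_lig, rng)
        self.gate_pocket = GatedEquivariantBlock(d_pock, config.d_equi, d_pock, rng)
        self.mlp_lig = MLP(2 * d_lig, d_z, d_z, rng)
        self.mlp_pocket = MLP(d_pock, d_z, d_z, rng)
        self.mlp_int = MLP(config.d_edge, d_z, d_z, rng)
        self.endpoint_mlps = [MLP(3 * d_z, d_z, 1, rng) for _ in ENDPOINTS]
        for mlp in self.endpoint_mlps:
            # start in the middle of the log-affinity range: a ReLU output
            # head that initializes negative everywhere never recovers
            mlp.layers[-1].bias.data[...] = 5.0

    def forward(self, ligand_feats: FeatureState, pocket_feats: FeatureState,
                cross_edges: Tensor) -> Tensor:
        """Return (B, 4) nonnegative predictions ordered as ENDPOINTS."""
        return self.forward_raw(ligand_feats, pocket_feats, cross_edges).relu()

    def forward_raw(self, ligand_feats: FeatureState, pocket_feats: FeatureState,
                    cross_edges: Tensor) -> Tensor:
        """Pre-ReLU endpoint activations.

        Training regresses these against the (nonnegative) targets so the
        output ReLU can never silence gradients; at convergence the ReLU is
        the identity on in-distribution inputs.
        """
        lm = ligand_feats.mask.astype(np.float64)
        pm = pocket_feats.mask.astype(np.float64)
        if np.any(lm.sum(axis=1) == 0):
            raise EmptyLigandError("affinity head received an empty ligand")
        if np.any(pm.sum(axis=1) == 0):
            raise EmptyLigandError("affinity head received an empty pocket")

        f_lig = self.gate_lig(ligand_feats.inv, ligand_feats.equi, ligand_feats.mask)
        lig_sum = f_lig.sum(axis=1)
        n_lig = lm.sum(axis=1, keepdims=True)
        z_lig = self.mlp_lig(nn.concatenate(
            [lig_sum * (1.0 / LIGAND_POOL_C), lig_sum * Tensor(1.0 / n_lig)], axis=-1))

        f_pocket = self.gate_pocket(pocket_feats.inv, pocket_feats.equi, pocket_feats.mask)
        n_pocket = pm.sum(axis=1, keepdims=True)
        z_pocket = self.mlp_pocket(f_pocket.sum(axis=1) * Tensor(1.0 / n_pocket))

        pair_mask = (lm[:, :, None] * pm[:, None, :])[..., None]
        e_sum = (cross_edges * pair_mask).sum(axis=(1, 2))
        z_int = self.mlp_int(e_sum * Tensor(1.0 / pair_mask.sum(axis=(1, 2))))

        z = nn.concatenate([z_lig, z_pocket, z_int], axis=-1)
        return nn.concatenate([mlp(z) for mlp in self.endpoint_mlps], axis=-1)


def affinity_forward(head: AffinityHead, ligand_feats: FeatureState,
                     pocket_feats: FeatureState, cross_edges: Tensor) -> Tensor:
    """Functional wrapper over :class:`AffinityHead`."""
    return head(ligand_feats, pocket_feats, cross_edges)


def huber(residual: Tensor, delta: float = 1.0) -> Tensor:
    """Elementwise Huber: quadratic inside |e|<=delta, linear outside."""
    abs_e = nn.where(residual.data >= 0, residual, -residual)
    quad = residual * residual * 0.5
    lin = abs_e * delta - 0.5 * delta * delta
    return nn.where(abs_e.data <= delta, quad, lin)


def huber_affinity_loss(pred: Tensor, target: np.ndarray,
                        endpoint_mask: np.ndarray | None = None,
                        delta: float = 1.0) -> Tensor:
    """Mean Huber loss over labeled (pred, target) endpoint entries.

    ``pred`` is (B, 4); ``endpoint_mask`` marks labeled entries.  With zero
    labeled entries the loss is defined as 0 and a warning is emitted.
    """
    target = np.asarray(target, dtype=np.float64)
    if endpoint_mask is None:
        endpoint_mask = np.ones(target.shape, dtype=bool)
    n_valid = int(endpoint_mask.sum())
    if n_valid == 0:
        warnings.warn("huber_affinity_loss: no labeled endpoints; loss defined as 0")
        return Tensor(0.0)
    m = endpoint_mask.astype(np.float64)
    per_entry = huber(pred - Tensor(target), delta)
    return (per_entry * m).sum() * (1.0 / n_valid)


# ---------------------------------------------------------------------------
# lDDT / pLDDT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LddtConfig:
    """Inclusion radius, error thresholds and bin count for the lDDT score.

    The default thresholds are the canonical 0.5/1/2/4 Å set; the inclusion
    rule is strict (`D < inclusion_radius`), as are the threshold tests
    (`|D - D_hat| < c`).
    """

    inclusion_radius: float = 12.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    bins: int = 50

    def __post_init__(self):
        if any(t <= 0 for t in self.thresholds) or list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be positive ascending")


@dataclass
class ConfidenceOutput:
    """Per-atom confidence logits, expected lDDT and the 0-100 pLDDT scalar."""

    per_atom_logits: np.ndarray       # (|L|, k)
    per_atom_lddt: np.ndarray         # (|L|,) in (0, 1)
    plddt_scalar: float               # 100 x mean expected bin center

    @classmethod
    def from_logits(cls, logits: np.ndarray, k: int | None = None) -> "ConfidenceOutput":
        logits = np.asarray(logits, dtype=np.float64)
        k = k or logits.shape[-1]
        p = np.exp(logits - logits.max(axis=-1, keepdims=True))
        p /= p.sum(axis=-1, keepdims=True)
        centers = (np.arange(k) + 0.5) / k
        expected = p @ centers
        return cls(per_atom_logits=logits, per_atom_lddt=expected,
                   plddt_scalar=float(100.0 * expected.mean()))


def lddt_per_atom(d_true: np.ndarray, d_pred: np.ndarray,
                  config: LddtConfig = LddtConfig()) -> np.ndarray:
    """Per-ligand-atom lDDT of predicted vs true ligand-pocket distances.

    Neighbors are pocket atoms with true distance strictly below the
    inclusion radius; the neighbor count is clamped to >= 1 so atoms without
    neighbors score 0.  Scores lie in [0, 1].
    """
    d_true = np.asarray(d_true, dtype=np.float64)
    d_pred = np.asarray(d_pred, dtype=np.float64)
    if d_true.shape != d_pred.shape:
        raise ValueError("distance matrices must share a shape")
    include = d_true < config.inclusion_radius
    b = np.maximum(include.sum(axis=1), 1)
    err = np.abs(d_true - d_pred)
    passes = np.zeros(d_true.shape)
    for c in config.thresholds:
        passes += (err < c)
    passes *= include
    return passes.sum(axis=1) / (b * len(config.thresholds))


def lddt_bin(score, k: int = 50):
    """Bin an lDDT score in [0, 1] into floor(score*k), with 1 mapping to k-1."""
    arr = np.asarray(score, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("lDDT score out of [0, 1]")
    bins = np.minimum(np.floor(arr * k).astype(np.int64), k - 1)
    return int(bins) if np.isscalar(score) or arr.ndim == 0 else bins


def confidence_loss(logits: Tensor, true_lddt: np.ndarray,
                    mask: np.ndarray | None = None, k: int = 50) -> Tensor:
    """Mean cross-entropy of confidence logits against binned true scores."""
    bins = lddt_bin(np.asarray(true_lddt, dtype=np.float64), k)
    lsm = nn.log_softmax(logits, axis=-1)
    flat = lsm.reshape(-1, k)
    idx = np.arange(flat.shape[0])
    picked = flat[idx, np.asarray(bins).reshape(-1)]
    if mask is None:
        return -picked.mean()
    m = np.asarray(mask, dtype=np.float64).reshape(-1)
    return -(picked * m).sum() * (1.0 / max(m.sum(), 1.0))


# ---------------------------------------------------------------------------
# units, aggregation, metrics
# ---------------------------------------------------------------------------

def delta_g_from_pk(pk: float, R: float = R_KCAL_PER_K_MOL, T: float = T_KELVIN) -> float:
    """Binding free energy in kcal/mol: dG = -R T ln(10) * pK."""
    return float(-R * T * np.log(10.0) * pk)


def aggregate_endpoints(pred: AffinityPrediction, mode: str = "median") -> float:
    """Robust single-number potency: median (default) or mean over the
    unmasked endpoints."""
    values = pred.as_array()[np.asarray(pred.endpoint_mask, dtype=bool)]
    if values.size == 0:
        raise ValueError("all endpoints are masked")
    if mode == "median":
        return float(np.median(values))
    if mode == "mean":
        return float(values.mean())
    raise ValueError(f"unknown aggregation mode {mode!r}")


def regression_metrics(pred: np.ndarray, true: np.ndarray) -> dict[str, float]:
    """RAE, RMSE, R^2, Kendall tau-b and Pearson r between two vectors.

    RAE is the relative absolute error against the mean predictor:
    sum|y_hat - y| / sum|y - mean(y)|.
    """
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred/true must be equal-length 1-D vectors of length >= 2")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(true))):
        raise ValueError("non-finite values in metric inputs")
    sst = float(((true - true.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("true values have zero variance; R2/Pearson undefined")
    sae = float(np.abs(true - true.mean()).sum())
    rae = float(np.abs(pred - true).sum()) / sae
    rmse = float(np.sqrt(((pred - true) ** 2).mean()))
    r2 = 1.0 - float(((pred - true) ** 2).sum()) / sst
    tau = float(stats.kendalltau(pred, true, variant="b").statistic)
    pearson = float(stats.pearsonr(pred, true).statistic)
    return {"RAE": rae, "RMSE": rmse, "R2": r2, "kendall_tau": tau, "pearson": pearson}
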