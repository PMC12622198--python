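# Methods

`ligflow` implements a pocket-conditioned generative model of 3D drug-like
ligands based on SE(3)-equivariant joint continuous/discrete flow matching,
with three auxiliary capabilities trained jointly with generation: a
four-endpoint binding-affinity head (pIC50, pKi, pKd, pEC50), a binned-lDDT
confidence head, and inference-time steering of the sampler by sequential
Monte Carlo (SMC) importance resampling.  This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Generative model

A ligand is a tuple l = (X, T, Q, H, B): coordinates X ∈ ℝ^{N×3} (Å),
per-atom categorical atom types T, formal charges Q, hybridizations H, and a
symmetric bond-order matrix B with a "none" diagonal.  The protein pocket
P — all residues with an atom within 7 Å of a reference ligand, bounded to
10–800 atoms — is the fixed conditioning context.

Time runs noise → data as t: 0 → 1.

**Coordinates** follow conditional flow matching on the linear path
x_t = (1−t)·x0 + t·x1 with prior x0 ~ N(pocket centroid, σ²I), σ = 2 Å.
The network is l1-parameterized: it predicts the clean endpoint X̂ and the
sampler integrates the induced velocity v_t = (X̂ − x_t)/(1 − t) with an
Euler scheme (default 100 steps).

**Categorical attributes** follow a uniform-prior discrete flow: z_t equals
the data category with probability t, otherwise a uniform draw, so
P(z_t = z1) = t + (1−t)/K.  Sampling runs the corresponding jump process:
each variable is resampled from the predicted clean posterior with
probability dt/(1−t) (clamped at 1); at t = 1 categoricals take the argmax.
Bond entries are corrupted and resampled on the upper triangle and
mirrored, so the matrix stays symmetric throughout.  The uniform-prior
variant (rather than a masking prior) matches de novo sampling, where prior
atom types are drawn, not masked.  Training times are drawn t ~ U(0, 1).

Training-protocol details matter a great deal at this scale.  First,
prior and data atoms are paired by optimal transport (a linear assignment
on squared distances per complex) before interpolating: atoms are
exchangeable, so under arbitrary pairing the conditional mean E[x1 | x_t]
at low t collapses every atom onto the pocket centroid, and sampled
trajectories inherit the contraction (we measured mean nearest-neighbor
distances shrinking from 1.98 Å in the prior to ~1.0 Å in samples, against
1.45 Å in data).  OT pairing makes early endpoint predictions structured
and the flow nearly straight.  Second, a small Gaussian jitter (0.2 Å) is
added to the interpolated coordinates during training: the sampler feeds
the decoder its own imperfect intermediate structures, which the clean
interpolants of the conditional path never cover, and the jitter turns the
decoder into a contraction toward the data manifold on exactly that input
class.  Third, a configurable fraction of each batch (default protocol:
25%) is pinned to t = 1, so the decoder sees clean structures exactly as
the affinity, confidence and polish pathways consume them at prediction
time; the remaining samples keep t ~ U(0, 1).  All three are exposed in
`TrainConfig`; the conditional path itself is unchanged.

Affinity training is staged, mirroring the multi-stage character of the
method: during joint training the Huber term is applied only to batch
samples with t above `affinity_t_min` (default 0.6) — latents from heavily
corrupted inputs cannot carry contact information — and after joint
training a short head-only stage (`finetune_affinity_head`) freezes the
backbone, caches one clean-complex (t = 1) decode per training complex and
trains the endpoint MLPs on the cached latents with early stopping at the
label-noise floor (Huber ≈ 0.5·σ², σ = 0.2 log units; fitting below that
floor memorizes observation noise).  This stage costs under a minute and
is what closes the gap between the latents' information content and the
head's use of it.

The sampler ends with a polish pass (`SamplerConfig.polish_steps`, default
1): one extra decode of the finished structure at t = 1 whose prediction
replaces the state.  The input-jitter training makes the decoder a
denoiser on exactly this input class, so the pass snaps bond geometry
toward the data manifold without touching the integration scheme.

Three generative modes share one backbone: de novo generation; fragment
elaboration (inpainting: fixed atoms and bonds are clamped to the anchor
reference at every sampler step, so anchor coordinates are preserved
exactly); and interaction-guided generation, realized as categorical
interaction flags appended to the invariant pocket-atom features.

## Equivariant backbone

A pocket encoder (self-attention only, coordinates fixed) produces
invariant features p_inv, equivariant features p_equi and pocket edge
features; a ligand decoder alternates ligand self-attention and
ligand→pocket cross-attention per layer, with residual coordinate updates,
and ends in a structure head (coordinates + categorical logits, bond logits
symmetrized from symmetrized edge features).

Each attention block computes, from latent down-projections of the
equivariant node features (latent size L with multi-head invariant
attention), the pairwise squared-distance tensor S_ij = |q_i − k_j|² and
cross-product tensor C_ij = q_i × k_j; S is stacked into the pairwise
messages and C enters the equivariant aggregation.  The cross-product
message Σ_j w_ij (q_i × k_j) is evaluated as q_i × (Σ_j w_ij k_j), which is
algebraically identical (bilinearity) and avoids materializing N×N×3×L
tensors.  Edges are updated from Gaussian radial-basis expansions of the
*updated* interatomic distances (32 centers uniform on [0, 10] Å, width
equal to the spacing).  Flow time is injected as a 16-dimensional
sinusoidal embedding concatenated to the initial invariant features.

Equivariance is exact by construction, not approximate: invariant channels
touch geometry only through norms, distances and dot products; equivariant
channels (stacks of 3-vectors) are combined linearly over channels, via
cross products, and along coordinate differences; translations are absorbed
by centering each forward pass on the pocket centroid and restoring it at
the output.  The test suite verifies the full contract (coordinates
equivariant, every logit/affinity/pLDDT invariant) to 1e-4/1e-5 under random
rigid motions; in float64 the observed deviations are ~1e-13.

Numerical stabilization: invariant streams are layer-normalized, edge
features are layer-normalized before entering pair messages, equivariant
stacks are RMS-normalized (a rotation-invariant scalar scale) before
projection, per-pair coordinate-update gates are tanh-bounded, and
coordinates enter the network in units of 5 Å.  Training uses Adam with
global-norm gradient clipping and cosine learning-rate decay; the decay is
what pins down sub-Ångström geometry late in training.

Two configurations exist: the full-scale one (4-layer encoder at d_inv=256,
12-layer decoder at d_inv=384, d_equi=128, latent 64, 32 heads, confidence
depth 8), built and checked shape-only; and the desk-scale default used by
every test and example (2-layer encoder at 64, 4-layer decoder at 96,
d_equi=16, latent 16, 4 heads, confidence depth 2, ~0.75M parameters),
chosen so the complete train/sample/steer/predict loop runs on one CPU in
minutes.

## Affinity head

Potency measures (IC50, Ki, Kd, EC50) are not interchangeable, so each is
predicted separately in log units.  From the decoder's final latents:
f_i = Gate(h_inv, h_equi) per ligand atom (a gated equivariant block whose
output is rotation invariant); z_lig = MLP([(1/C)·Σ f_i, (1/|L|)·Σ f_i])
with fixed C = 100, so the first branch carries molecule size while the
second is size-invariant; z_pocket mean-pools gated pocket features; z_int
= MLP(Σ_ij e_ij m_i m_j / Σ_ij m_i m_j), the validity-mask-weighted mean of
ligand–pocket cross-edge features.  Endpoint-specific MLPs over
[z_lig, z_pocket, z_int] with a final ReLU give nonnegative log-unit
predictions.  The loss is the mean Huber loss (δ = 1, i.e. one log unit =
one order of magnitude in potency) over labeled endpoints only; unlabeled
endpoints contribute zero gradient.  Log affinities convert to free
energies as ΔG = −RT·ln10·pK with R = 1.987×10⁻³ kcal K⁻¹ mol⁻¹ and
T = 298 K.  Multi-endpoint predictions are aggregated by the median by
default.

## Confidence (pLDDT)

For each ligand atom, the local distance difference test compares true and
predicted ligand–pocket distance matrices: neighbors are pocket atoms with
true distance strictly below 12.0 Å (count clamped to ≥ 1), and the score
is the fraction of error thresholds passed, |D − D̂| < c for c ∈ {0.5, 1,
2, 4} Å.  The canonical 0.5/1/2/4 threshold set is the default; a variant
including a 12 Å threshold is available via `LddtConfig(thresholds=...)`.
Scores are binned into k = 50 classes (bin = floor(score·50), score 1 →
bin 49) and the confidence head — the first `confidence_depth` decoder
layers re-run on the predicted structure l̂1 at t = 1, plus a linear
projection to 50 logits — is trained by cross-entropy.  The scalar pLDDT
is 100 × the mean expected bin center under the predicted distribution.
The l̂1 input to the confidence pass is detached: argmax categories are
non-differentiable anyway, and detaching keeps the structure gradients
unpolluted.

## SMC steering

To sample from a reward-tilted distribution p(l | y, P) ∝ r(y | l, P) ·
p_θ(l | P), B particles are advanced in parallel by the unguided sampler;
at scheduled times inside a window [start, stop] (cadence: every 10
integration steps by default) the current denoised estimates l̂1 — not the
noisy l_τ, because the affinity head is trained on clean-structure features
— are scored, weights w_i = softmax(λ·ŷ_i) computed (max-subtraction
stabilized; λ = 1 by default), and the ensemble resampled from
Multinomial(B, w) with weights reset to uniform.  Rewards are signed
weighted sums of endpoint predictions per named pocket, which expresses
dual-objective selectivity directly: maximize predicted affinity on the
on-target pocket while minimizing it on the off-target pocket.

## Synthetic study systems

The fixture generator emulates the *shape* of real training data while
staying analytically checkable.  Ligands (8–16 heavy atoms by default) are
template-built — aromatic six-rings (bond 1.39 Å, planar), sp³ zigzag
chains (1.54 Å, tetrahedral angles), occasional terminal carbonyl-like
doubles (1.34 Å) — with elements assigned under per-element valence caps
and 0.05 Å coordinate jitter.  Pockets (24–42 atoms by default, residues
in triples) sit on a partial shell 3–7 Å from the ligand with no atom
closer than 2.5 Å.  The ground-truth affinity is a contact-count linear
model: latent = c0 + c1·#{ligand–pocket pairs < 4 Å} + c2·#heavy atoms
with (c0, c1, c2) = (2.0, 0.08, 0.0) — the pure contact-count model, so that
shuffling pockets across complexes genuinely destroys the correlation —
and pIC50 = latent + noise (σ = 0.2 log
units, clipped to [0, 12]) and the other endpoints fixed affine transforms
of the same latent with independent noise.  This target is deliberately
pocket-dependent: predicting it requires the interaction pooling z_int, and
shuffling pockets across complexes destroys the correlation — which the
acceptance suite checks.  One master seed is split into counter-based
per-record substreams, so record i is independent of dataset size.

What the fixtures do *not* model: real medicinal chemistry (rings beyond
benzene, stereochemistry, protonation states), rotamer flexibility, water,
and experimental assay noise structure.  Passing the recovery tests shows
the architecture can learn pocket-dependent structure–activity signal from
3D complexes end to end; it says nothing about accuracy on real proteins.

## Problem sizes and numerics

Tests and the acceptance script train the desk-scale model on 500 fixture
complexes (440 train / 60 held out) for 900 Adam steps at batch 12 (lr
2.5e-3, cosine decay) plus the head-only affinity stage, then sample with
30 Euler steps (plus one polish pass), steer with 64 particles over 20
steps with resampling every 2 steps, and evaluate affinity recovery on the
held-out complexes — about 16 minutes on one CPU in float64.  Pockets
default to 24-42 atoms and ligands to 8-16 heavy atoms: toy scale chosen
so the complete loop runs on a single desktop core.  Degenerate inputs are
defined explicitly: empty ligands raise in the affinity pooling; an
all-masked Huber loss is 0 with a warning; ties in the bond argmax are
resolved upper-triangle-first and mirrored; lDDT atoms without neighbors
score 0 via the b ≥ 1 clamp.

## Known limitations

The desk-scale model trained on toy fixtures generates template-like
geometry, not strain-free chemistry; generated bond graphs are valid by
construction of the state invariants but not checked for chemical sanity
(valence caps hold in the training data, approximately in samples).
Generated bond-length distributions reach a Wasserstein-1 distance of
roughly 0.15-0.25 Å from the training distribution under the default
schedule; closing the remaining gap to crystallographic sharpness would
need a larger backbone or substantially longer training than a desktop
budget allows.  The
sampler is a plain Euler/jump scheme — no SDE variants, no EMA weights, no
preference alignment.  Checkpoints store raw float64 weights; no
quantization or mixed precision.
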