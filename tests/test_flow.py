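"""Flow-matching engine: prior, conditional paths, corruption marginals,
loss arithmetic, integration, conditioning and the training loop."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligflow.nn import Tensor
from ligflow.chem_io import DEFAULT_VOCABULARY
from ligflow.equivariant import collate_ligands
from ligflow.flow import (
    ConditioningMask,
    LigandFlowModel,
    LossWeights,
    SamplerConfig,
    TrainConfig,
    apply_conditioning,
    corrupt_bonds,
    corrupt_categorical,
    generate,
    integrate_step,
    interpolate_coords,
    pocket_frame,
    sample_prior,
    total_loss,
    train,
)
from ligflow.synthetic import FixtureConfig, build_complex, generate_toy_ligand


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def test_prior_zero_noise_collapses_to_centroid(vocab):
    rec = build_complex(FixtureConfig(seed=1), 0)
    cfg = SamplerConfig(noise_sd=0.0)
    prior = sample_prior(6, rec.pocket, cfg, np.random.default_rng(0), vocab)
    np.testing.assert_allclose(prior.coords, rec.pocket.centroid()[None, :].repeat(6, 0),
                               atol=1e-12)


def test_prior_seed_determinism(vocab):
    rec = build_complex(FixtureConfig(seed=1), 0)
    cfg = SamplerConfig(noise_sd=2.0)
    a = sample_prior(8, rec.pocket, cfg, np.random.default_rng(5), vocab)
    b = sample_prior(8, rec.pocket, cfg, np.random.default_rng(5), vocab)
    np.testing.assert_array_equal(a.coords, b.coords)
    assert np.array_equal(a.bonds, b.bonds)
    a.validate(vocab)


def test_prior_mean_near_centroid(vocab):
    rec = build_complex(FixtureConfig(seed=2), 0)
    cfg = SamplerConfig(noise_sd=1.5)
    rng = np.random.default_rng(3)
    draws = np.concatenate([
        sample_prior(10, rec.pocket, cfg, rng, vocab).coords for _ in range(1000)])
    centroid = rec.pocket.centroid()
    tol = 3 * 1.5 / np.sqrt(len(draws))
    assert np.abs(draws.mean(axis=0) - centroid).max() < 3 * tol + 0.05


def test_pocket_frame_rotates_with_pocket(vocab):
    rec = build_complex(FixtureConfig(seed=4), 1)
    c1, f1 = pocket_frame(rec.pocket.coords)
    R = Rotation.random(random_state=2).as_matrix()
    u = np.array([1.0, 2.0, 3.0])
    c2, f2 = pocket_frame(rec.pocket.coords @ R.T + u)
    np.testing.assert_allclose(c1 @ R.T + u, c2, atol=1e-9)
    np.testing.assert_allclose(R @ f1, f2, atol=1e-9)
    np.testing.assert_allclose(np.linalg.det(f1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# paths and corruption
# ---------------------------------------------------------------------------

def test_interpolation_closed_forms():
    x0 = np.zeros((2, 3))
    x1 = np.array([[2.0, 4.0, 6.0], [1.0, 1.0, 1.0]])
    np.testing.assert_array_equal(interpolate_coords(x0, x1, 0.0), x0)
    np.testing.assert_array_equal(interpolate_coords(x0, x1, 1.0), x1)
    np.testing.assert_allclose(interpolate_coords(x0[:1], x1[:1], 0.5), [[1.0, 2.0, 3.0]])


def test_corruption_boundary_times(rng):
    z1 = rng.integers(0, 5, size=1000)
    np.testing.assert_array_equal(corrupt_categorical(z1, 1.0, 5, rng), z1)
    z0 = corrupt_categorical(z1, 0.0, 5, rng)
    counts = np.bincount(z0, minlength=5) / len(z0)
    sigma = np.sqrt(0.2 * 0.8 / len(z0))
    assert np.abs(counts - 0.2).max() < 4 * sigma


def test_corruption_marginal_matches_theory(rng):
    """P(z_t = z1) = t + (1-t)/K for the uniform-prior discrete path."""
    K, n = 5, 20000
    z1 = rng.integers(0, K, size=n)
    for t in (0.25, 0.75):
        zt = corrupt_categorical(z1, t, K, rng)
        p = (zt == z1).mean()
        expected = t + (1 - t) / K
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(p - expected) < 4 * sigma


def test_bond_corruption_stays_symmetric(rng):
    lig = generate_toy_ligand(10, rng)
    bt = corrupt_bonds(lig.bonds, 0.3, 5, rng)
    assert np.array_equal(bt, bt.T)
    assert (np.diag(bt) == 0).all()


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _fake_prediction(target, vocab, logits_scale=30.0, coords=None):
    """DecoderOutput-like object with one-hot-scaled logits at the target."""
    from ligflow.equivariant import DecoderOutput, FeatureState

    def onehot(idx, k):
        out = np.full(idx.shape + (k,), 0.0)
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return Tensor(out * logits_scale)

    return DecoderOutput(
        coords=Tensor(coords if coords is not None else target["coords"]),
        type_logits=onehot(target["atom_type"], vocab.n_atom_types),
        charge_logits=onehot(target["charge"], vocab.n_charges),
        hyb_logits=onehot(target["hybridization"], vocab.n_hybridizations),
        bond_logits=onehot(target["bonds"], vocab.n_bond_orders),
        ligand_state=None, cross_edges=None, mask=target["mask"])


def test_perfect_prediction_gives_vanishing_loss(vocab, rng):
    lig = generate_toy_ligand(7, rng)
    target = collate_ligands([lig], vocab)
    pred = _fake_prediction(target, vocab, logits_scale=200.0)
    loss, terms = total_loss(pred, target, LossWeights())
    assert terms["coord_mse"] == 0.0
    assert loss.data < 1e-6


def test_zero_weights_zero_loss(vocab, rng):
    lig = generate_toy_ligand(5, rng)
    target = collate_ligands([lig], vocab)
    pred = _fake_prediction(target, vocab)
    w = LossWeights(lambda_c=0, lambda_t=0, lambda_ch=0, lambda_h=0, lambda_b=0,
                    lambda_affinity=0, lambda_confidence=0)
    loss, _ = total_loss(pred, target, w)
    assert loss.data == 0.0


def test_two_atom_hand_loss(vocab):
    """Calculator-level recomputation of every term on a 2-atom system."""
    lig = np.zeros((1, 2, 3))
    lig[0, 1, 0] = 1.5
    target = {
        "coords": lig,
        "atom_type": np.array([[0, 1]]),
        "charge": np.array([[2, 2]]),
        "hybridization": np.array([[2, 2]]),
        "bonds": np.array([[[0, 1], [1, 0]]]),
        "mask": np.ones((1, 2), bool),
    }
    pred_coords = lig + 0.1
    pred = _fake_prediction(target, vocab, logits_scale=1.0, coords=pred_coords)
    loss, terms = total_loss(pred, target, LossWeights(lambda_c=1.0, lambda_t=1.0,
                                                       lambda_ch=1.0, lambda_h=1.0,
                                                       lambda_b=1.0))
    np.testing.assert_allclose(terms["coord_mse"], 0.01, atol=1e-12)
    # CE of a one-hot logit vector with scale 1: -log softmax at the hot index
    k_t = vocab.n_atom_types
    ce_t = -np.log(np.e / (np.e + (k_t - 1)))
    np.testing.assert_allclose(terms["type_ce"], ce_t, atol=1e-9)
    k_b = vocab.n_bond_orders
    ce_b = -np.log(np.e / (np.e + (k_b - 1)))
    np.testing.assert_allclose(terms["bond_ce"], ce_b, atol=1e-9)
    ce = lambda k: -np.log(np.e / (np.e + (k - 1)))
    expected_total = 0.01 + ce_t + ce_b + ce(vocab.n_charges) + ce(vocab.n_hybridizations)
    np.testing.assert_allclose(loss.data, expected_total, atol=1e-9)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_integrate_fixed_point(vocab, rng):
    lig = generate_toy_ligand(6, rng)
    batch = collate_ligands([lig], vocab)
    pred = _fake_prediction(batch, vocab, logits_scale=500.0)
    out = integrate_step(batch, pred, 0.4, 0.1, np.random.default_rng(0))
    np.testing.assert_allclose(out["coords"], batch["coords"], atol=1e-12)


def test_integrate_single_full_step_reaches_prediction(vocab, rng):
    lig = generate_toy_ligand(6, rng)
    batch = collate_ligands([lig], vocab)
    start = dict(batch)
    start["coords"] = batch["coords"] + rng.normal(size=batch["coords"].shape)
    pred = _fake_prediction(batch, vocab, logits_scale=500.0)
    out = integrate_step(start, pred, 0.0, 1.0, np.random.default_rng(0))
    np.testing.assert_allclose(out["coords"], batch["coords"], atol=1e-12)
    assert np.array_equal(out["atom_type"], batch["atom_type"])
    assert np.array_equal(out["bonds"], batch["bonds"])


def test_integration_absorbs_to_frozen_prediction(vocab, rng):
    """With a frozen oracle prediction, full integration lands exactly on it."""
    lig = generate_toy_ligand(8, rng)
    target = collate_ligands([lig], vocab)
    pred = _fake_prediction(target, vocab, logits_scale=500.0)
    state = dict(target)
    state["coords"] = target["coords"] + rng.normal(scale=2.0, size=target["coords"].shape)
    state["atom_type"] = rng.integers(0, vocab.n_atom_types, size=state["atom_type"].shape)
    steps = 20
    r = np.random.default_rng(1)
    for k in range(steps):
        state = integrate_step(state, pred, k / steps, 1 / steps, r)
    np.testing.assert_allclose(state["coords"], target["coords"], atol=1e-9)
    assert np.array_equal(state["atom_type"], target["atom_type"])
    assert np.array_equal(state["bonds"], target["bonds"])


def test_integrate_rejects_bad_times(vocab, rng):
    lig = generate_toy_ligand(4, rng)
    batch = collate_ligands([lig], vocab)
    pred = _fake_prediction(batch, vocab)
    with pytest.raises(ValueError):
        integrate_step(batch, pred, 1.0, 0.1, rng)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def test_conditioning_all_true_copies_reference(vocab, rng):
    lig = generate_toy_ligand(6, rng)
    other = generate_toy_ligand(6, np.random.default_rng(99))
    batch = collate_ligands([other], vocab)
    mask = ConditioningMask(fixed_atoms=np.ones(6, bool))
    out = apply_conditioning(batch, mask, lig)
    np.testing.assert_array_equal(out["coords"][0], lig.coords)
    assert np.array_equal(out["bonds"][0], lig.bonds)


def test_conditioning_all_false_is_identity(vocab, rng):
    lig = generate_toy_ligand(6, rng)
    other = generate_toy_ligand(6, np.random.default_rng(98))
    batch = collate_ligands([other], vocab)
    mask = ConditioningMask(fixed_atoms=np.zeros(6, bool))
    out = apply_conditioning(batch, mask, lig)
    np.testing.assert_array_equal(out["coords"], batch["coords"])


def test_fixed_bonds_must_connect_fixed_atoms():
    fixed = np.array([True, True, False])
    bad = np.zeros((3, 3), bool)
    bad[0, 2] = True
    with pytest.raises(ValueError):
        ConditioningMask(fixed_atoms=fixed, fixed_bonds=bad)


# ---------------------------------------------------------------------------
# generation + training (smoke level; accuracy in acceptance tests)
# ---------------------------------------------------------------------------

def test_generate_contract(trained_model, small_records):
    ligs = generate(trained_model, small_records[0].pocket, 4, 7,
                    SamplerConfig(steps=10, seed=4))
    assert len(ligs) == 4
    for lig in ligs:
        assert lig.n_atoms == 7
        lig.validate(trained_model.vocab)


def test_generate_seed_determinism(trained_model, small_records):
    a = generate(trained_model, small_records[0].pocket, 2, 8, SamplerConfig(steps=8, seed=9))
    b = generate(trained_model, small_records[0].pocket, 2, 8, SamplerConfig(steps=8, seed=9))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.coords, y.coords)
        assert np.array_equal(x.bonds, y.bonds)


def test_generate_rigid_motion_equivariance(trained_model, small_records):
    rec = small_records[1]
    R = Rotation.random(random_state=8).as_matrix()
    u = np.array([4.0, -2.0, 1.0])
    moved = rec.pocket.copy()
    moved.coords = moved.coords @ R.T + u
    g1 = generate(trained_model, rec.pocket, 2, 8, SamplerConfig(steps=8, seed=2))
    g2 = generate(trained_model, moved, 2, 8, SamplerConfig(steps=8, seed=2))
    for a, b in zip(g1, g2):
        np.testing.assert_allclose(a.coords @ R.T + u, b.coords, atol=1e-3)
        assert np.array_equal(a.atom_type, b.atom_type)


def test_fragment_mode_keeps_fragment_exactly(trained_model, small_records):
    rec = small_records[2]
    ref = rec.ligand
    n = ref.n_slots
    fixed = np.zeros(n, bool)
    fixed[:4] = True
    mask = ConditioningMask(fixed_atoms=fixed)
    ligs = generate(trained_model, rec.pocket, 3, n,
                    SamplerConfig(steps=10, seed=5, mode="fragment"),
                    conditioning=mask, reference=ref)
    for lig in ligs:
        np.testing.assert_allclose(lig.coords[:4], ref.coords[:4], atol=1e-6)
        assert np.array_equal(lig.atom_type[:4], ref.atom_type[:4])


def test_train_decreases_loss_and_is_deterministic(vocab, desk_config, small_records):
    m1 = LigandFlowModel(vocab, desk_config, seed=7)
    cfg = TrainConfig(n_steps=30, batch_size=4, seed=11)
    w = LossWeights(lambda_affinity=0.1, lambda_confidence=0.0)
    t1 = train(small_records[:4], m1, w, cfg)
    first = np.mean([r["total"] for r in t1[:5]])
    last = np.mean([r["total"] for r in t1[-5:]])
    assert last < first
    m2 = LigandFlowModel(vocab, desk_config, seed=7)
    t2 = train(small_records[:4], m2, w, cfg)
    np.testing.assert_allclose([r["total"] for r in t1], [r["total"] for r in t2])


def test_train_empty_dataset_raises(vocab, desk_config):
    with pytest.raises(ValueError):
        train([], LigandFlowModel(vocab, desk_config, seed=0))
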