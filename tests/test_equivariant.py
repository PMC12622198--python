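"""SE(3)/permutation contracts of the backbone, pairwise geometric
features, gated fusion, masking behaviour and checkpointing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligflow import nn
from ligflow.nn import Tensor
from ligflow.chem_io import ComplexRecord
from ligflow.equivariant import (
    BackboneConfig,
    EquivariantUpdateBlock,
    FeatureState,
    GatedEquivariantBlock,
    LigandDecoder,
    PocketEncoder,
    collate_ligands,
    collate_pockets,
    gated_fuse,
    load_checkpoint,
    pairwise_geometric_features,
    save_checkpoint,
    time_embedding,
)
from ligflow.flow import LigandFlowModel
from ligflow.synthetic import FixtureConfig, build_complex


def random_rotation(seed):
    return Rotation.random(random_state=seed).as_matrix()


def rotate_equi(equi, R):
    return np.einsum("ab,...bd->...ad", R, equi)


# ---------------------------------------------------------------------------
# pairwise geometric features
# ---------------------------------------------------------------------------

def test_pairwise_features_identity_case():
    q = Tensor(np.random.default_rng(0).normal(size=(2, 4, 3, 5)))
    s, c = pairwise_geometric_features(q, q)
    diag = np.arange(4)
    np.testing.assert_allclose(s.data[:, diag, diag], 0.0, atol=1e-12)
    np.testing.assert_allclose(c.data[:, diag, diag], 0.0, atol=1e-12)


def test_pairwise_features_hand_computation():
    q = Tensor(np.array([1.0, 0.0, 0.0]).reshape(1, 1, 3, 1))
    k = Tensor(np.array([0.0, 1.0, 0.0]).reshape(1, 1, 3, 1))
    s, c = pairwise_geometric_features(q, k)
    np.testing.assert_allclose(s.data, [[[[2.0]]]])
    np.testing.assert_allclose(c.data[0, 0, 0, :, 0], [0.0, 0.0, 1.0])


def test_pairwise_features_symmetry(rng):
    q = rng.normal(size=(1, 5, 3, 4))
    k = rng.normal(size=(1, 7, 3, 4))
    s1, c1 = pairwise_geometric_features(Tensor(q), Tensor(k))
    R = random_rotation(1)
    s2, c2 = pairwise_geometric_features(Tensor(rotate_equi(q, R)), Tensor(rotate_equi(k, R)))
    np.testing.assert_allclose(s1.data, s2.data, atol=1e-10)
    np.testing.assert_allclose(rotate_equi(c1.data, R), c2.data, atol=1e-10)


def test_pairwise_features_dimension_mismatch():
    with pytest.raises(ValueError):
        pairwise_geometric_features(Tensor(np.zeros((1, 2, 3, 4))),
                                    Tensor(np.zeros((1, 2, 3, 5))))


# ---------------------------------------------------------------------------
# gated fusion
# ---------------------------------------------------------------------------

def test_gated_fuse_is_rotation_invariant(rng):
    block = GatedEquivariantBlock(8, 6, 10, np.random.default_rng(0))
    inv = Tensor(rng.normal(size=(2, 5, 8)))
    equi = rng.normal(size=(2, 5, 3, 6))
    out1 = gated_fuse(block, inv, Tensor(equi))
    out2 = gated_fuse(block, inv, Tensor(rotate_equi(equi, random_rotation(2))))
    np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)


def test_gated_fuse_zero_equi_depends_on_inv_alone(rng):
    block = GatedEquivariantBlock(8, 6, 10, np.random.default_rng(1))
    inv = Tensor(rng.normal(size=(1, 4, 8)))
    zero = Tensor(np.zeros((1, 4, 3, 6)))
    out1 = gated_fuse(block, inv, zero)
    rotated = Tensor(rotate_equi(np.zeros((1, 4, 3, 6)), random_rotation(3)))
    np.testing.assert_allclose(out1.data, gated_fuse(block, inv, rotated).data)


def test_gated_fuse_masked_rows_zero(rng):
    block = GatedEquivariantBlock(8, 6, 10, np.random.default_rng(2))
    mask = np.array([[True, True, False]])
    out = gated_fuse(block, Tensor(rng.normal(size=(1, 3, 8))),
                     Tensor(rng.normal(size=(1, 3, 3, 6))), mask)
    np.testing.assert_allclose(out.data[0, 2], 0.0)


# ---------------------------------------------------------------------------
# update block
# ---------------------------------------------------------------------------

def _random_block_inputs(rng, cfg, B=1, n=6):
    inv = Tensor(rng.normal(size=(B, n, cfg.d_inv_dec)))
    equi = Tensor(rng.normal(size=(B, n, 3, cfg.d_equi)))
    edges = Tensor(rng.normal(size=(B, n, n, cfg.d_edge)))
    coords = Tensor(rng.normal(scale=2.0, size=(B, n, 3)))
    mask = np.ones((B, n), dtype=bool)
    return FeatureState(inv=inv, equi=equi, edges=None, mask=mask), edges, coords


def test_update_block_equivariance(rng):
    cfg = BackboneConfig.desk_scale()
    block = EquivariantUpdateBlock(cfg.d_inv_dec, cfg.d_inv_dec, cfg,
                                   np.random.default_rng(0), update_coords=True)
    state, edges, coords = _random_block_inputs(rng, cfg)
    out1, e1, x1 = block(state, state, edges, coords, coords)

    R = random_rotation(5)
    state2 = FeatureState(inv=state.inv, equi=Tensor(rotate_equi(state.equi.data, R)),
                          edges=None, mask=state.mask)
    coords2 = Tensor(state.mask[..., None] * (coords.data @ R.T))
    out2, e2, x2 = block(state2, state2, edges, coords2, coords2)

    np.testing.assert_allclose(out1.inv.data, out2.inv.data, atol=1e-9)
    np.testing.assert_allclose(e1.data, e2.data, atol=1e-9)
    np.testing.assert_allclose(rotate_equi(out1.equi.data, R), out2.equi.data, atol=1e-9)
    np.testing.assert_allclose(x1.data @ R.T, x2.data, atol=1e-9)


def test_update_block_permutation_equivariance(rng):
    cfg = BackboneConfig.desk_scale()
    block = EquivariantUpdateBlock(cfg.d_inv_dec, cfg.d_inv_dec, cfg,
                                   np.random.default_rng(1), update_coords=True)
    state, edges, coords = _random_block_inputs(rng, cfg, n=5)
    out1, e1, x1 = block(state, state, edges, coords, coords)
    perm = np.random.default_rng(2).permutation(5)
    statep = FeatureState(inv=Tensor(state.inv.data[:, perm]),
                          equi=Tensor(state.equi.data[:, perm]),
                          edges=None, mask=state.mask[:, perm])
    edgesp = Tensor(e1.data * 0 + edges.data[:, perm][:, :, perm])
    out2, e2, x2 = block(statep, statep, edgesp, Tensor(coords.data[:, perm]),
                         Tensor(coords.data[:, perm]))
    np.testing.assert_allclose(out1.inv.data[:, perm], out2.inv.data, atol=1e-9)
    np.testing.assert_allclose(x1.data[:, perm], x2.data, atol=1e-9)
    np.testing.assert_allclose(e1.data[:, perm][:, :, perm], e2.data, atol=1e-9)


def test_update_block_padding_growth(rng):
    """Growing the padding never changes the unmasked outputs."""
    cfg = BackboneConfig.desk_scale()
    block = EquivariantUpdateBlock(cfg.d_inv_dec, cfg.d_inv_dec, cfg,
                                   np.random.default_rng(3), update_coords=True)
    state, edges, coords = _random_block_inputs(rng, cfg, n=4)
    out1, e1, x1 = block(state, state, edges, coords, coords)

    def pad(arr, axes, extra=3):
        for ax in axes:
            shape = list(arr.shape)
            shape[ax] = extra
            arr = np.concatenate([arr, np.zeros(shape)], axis=ax)
        return arr

    mask = np.concatenate([state.mask, np.zeros((1, 3), bool)], axis=1)
    statep = FeatureState(inv=Tensor(pad(state.inv.data, [1])),
                          equi=Tensor(pad(state.equi.data, [1])), edges=None, mask=mask)
    out2, e2, x2 = block(statep, statep, Tensor(pad(edges.data, [1, 2])),
                         Tensor(pad(coords.data, [1])), Tensor(pad(coords.data, [1])))
    np.testing.assert_allclose(out1.inv.data, out2.inv.data[:, :4], atol=1e-9)
    np.testing.assert_allclose(out1.equi.data, out2.equi.data[:, :4], atol=1e-9)
    np.testing.assert_allclose(x1.data, x2.data[:, :4], atol=1e-9)
    np.testing.assert_allclose(out2.inv.data[:, 4:], 0.0)


# ---------------------------------------------------------------------------
# encoder / decoder
# ---------------------------------------------------------------------------

def _toy_record(seed=5, index=0):
    return build_complex(FixtureConfig(seed=seed), index)


def test_pocket_encoder_rigid_motion(vocab):
    cfg = BackboneConfig.desk_scale()
    enc = PocketEncoder(vocab, cfg, np.random.default_rng(0))
    rec = _toy_record()
    batch = collate_pockets([rec.pocket])
    s1, _ = enc(batch)
    R, u = random_rotation(7), np.array([3.0, -1.0, 2.0])
    moved = rec.pocket.copy()
    moved.coords = moved.coords @ R.T + u
    s2, _ = enc(collate_pockets([moved]))
    np.testing.assert_allclose(s1.inv.data, s2.inv.data, atol=1e-9)
    np.testing.assert_allclose(rotate_equi(s1.equi.data, R), s2.equi.data, atol=1e-9)
    np.testing.assert_allclose(s1.edges.data, s2.edges.data, atol=1e-9)


def test_pocket_encoder_determinism_and_empty(vocab):
    cfg = BackboneConfig.desk_scale()
    enc = PocketEncoder(vocab, cfg, np.random.default_rng(1))
    rec = _toy_record()
    b = collate_pockets([rec.pocket])
    s1, _ = enc(b)
    s2, _ = enc(collate_pockets([rec.pocket]))
    np.testing.assert_array_equal(s1.inv.data, s2.inv.data)
    empty = {k: v[:, :0] if v.ndim > 1 else v for k, v in b.items()}
    empty = {k: v[:, :0] for k, v in b.items()}
    with pytest.raises(ValueError):
        enc(empty)


def test_decoder_full_se3_contract(vocab, untrained_model):
    """Joint rigid motion of pocket+ligand moves predicted coordinates
    identically and leaves every logit, affinity input feature and edge
    feature unchanged."""
    model = untrained_model
    rec = _toy_record(seed=11)
    lig = collate_ligands([rec.ligand], vocab)
    ps, c, px = model.encode_pocket([rec.pocket])
    out1 = model.decode(lig, np.array([0.7]), ps, px, c)

    R, u = random_rotation(13), np.array([-4.0, 2.0, 9.0])
    lig2 = {**lig, "coords": lig["coords"] @ R.T + u}
    moved = rec.pocket.copy()
    moved.coords = moved.coords @ R.T + u
    ps2, c2, px2 = model.encode_pocket([moved])
    out2 = model.decode(lig2, np.array([0.7]), ps2, px2, c2)

    np.testing.assert_allclose(out1.coords.data @ R.T + u, out2.coords.data, atol=1e-4)
    for field in ("type_logits", "charge_logits", "hyb_logits", "bond_logits"):
        np.testing.assert_allclose(getattr(out1, field).data,
                                   getattr(out2, field).data, atol=1e-5)
    np.testing.assert_allclose(out1.cross_edges.data, out2.cross_edges.data, atol=1e-5)
    np.testing.assert_allclose(out1.ligand_state.inv.data,
                               out2.ligand_state.inv.data, atol=1e-5)


def test_decoder_ligand_permutation(vocab, untrained_model):
    rec = _toy_record(seed=17)
    lig = collate_ligands([rec.ligand], vocab)
    ps, c, px = model_ctx = untrained_model.encode_pocket([rec.pocket])
    out1 = untrained_model.decode(lig, np.array([0.5]), ps, px, c)
    n = rec.ligand.n_slots
    perm = np.random.default_rng(3).permutation(n)
    ligp = {
        "coords": lig["coords"][:, perm],
        "atom_type": lig["atom_type"][:, perm],
        "charge": lig["charge"][:, perm],
        "hybridization": lig["hybridization"][:, perm],
        "bonds": lig["bonds"][:, perm][:, :, perm],
        "mask": lig["mask"][:, perm],
    }
    out2 = untrained_model.decode(ligp, np.array([0.5]), ps, px, c)
    np.testing.assert_allclose(out1.coords.data[:, perm], out2.coords.data, atol=1e-9)
    np.testing.assert_allclose(out1.type_logits.data[:, perm], out2.type_logits.data,
                               atol=1e-9)
    np.testing.assert_allclose(out1.bond_logits.data[:, perm][:, :, perm],
                               out2.bond_logits.data, atol=1e-9)


def test_decoder_bond_logits_symmetric(vocab, untrained_model):
    rec = _toy_record(seed=19)
    lig = collate_ligands([rec.ligand], vocab)
    ps, c, px = untrained_model.encode_pocket([rec.pocket])
    out = untrained_model.decode(lig, np.array([0.3]), ps, px, c)
    np.testing.assert_allclose(out.bond_logits.data,
                               out.bond_logits.data.swapaxes(1, 2), atol=1e-12)


def test_paper_scale_config_shapes(vocab):
    """The full-size configuration builds and produces correctly shaped
    outputs on a minimal input (shape-only check)."""
    cfg = BackboneConfig()  # published sizes
    assert cfg.enc_layers == 4 and cfg.d_inv_enc == 256
    assert cfg.dec_layers == 12 and cfg.d_inv_dec == 384
    assert cfg.d_equi == 128 and cfg.latent_size == 64
    assert cfg.attention_heads == 32 and cfg.confidence_depth == 8
    with pytest.raises(ValueError):
        BackboneConfig(confidence_depth=20, dec_layers=12)
    with pytest.raises(ValueError):
        BackboneConfig(enc_layers=0)


def test_time_embedding_shape_and_range():
    emb = time_embedding(np.array([0.0, 0.5, 1.0]), 16)
    assert emb.shape == (3, 16)
    assert np.abs(emb).max() <= 1.0


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def test_checkpoint_roundtrip(tmp_path, vocab, untrained_model):
    path = tmp_path / "model.npz"
    untrained_model.save(path, extra={"note": "test"})
    model2, extra = LigandFlowModel.load(path)
    assert extra["note"] == "test"
    for (n1, p1), (n2, p2) in zip(untrained_model.named_parameters(),
                                  model2.named_parameters()):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)
    rec = _toy_record(seed=23)
    a1, _ = __import__("ligflow.flow", fromlist=["predict_affinity"]).predict_affinity(
        untrained_model, rec)
    a2, _ = __import__("ligflow.flow", fromlist=["predict_affinity"]).predict_affinity(
        model2, rec)
    np.testing.assert_allclose(a1.as_array(), a2.as_array(), atol=1e-12)


def test_checkpoint_version_check(tmp_path, vocab, desk_config, untrained_model):
    path = tmp_path / "model.npz"
    save_checkpoint(path, {"model": untrained_model}, desk_config, vocab)
    import json

    import numpy as np_

    with np_.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    header = json.loads(bytes(arrays["__header__"]).decode())
    header["version"] = 99
    arrays["__header__"] = np_.frombuffer(json.dumps(header).encode(), dtype=np_.uint8)
    np_.savez(path, **arrays)
    with pytest.raises(ValueError, match="version"):
        load_checkpoint(path)
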