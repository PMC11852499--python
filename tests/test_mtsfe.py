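"""Backbone: pooling semantics, attention, shape contract, freezing,
checkpointing."""

import numpy as np
import pytest

from gdtil import MTSFE, MTSFEConfig, block_digest, var_pool
from gdtil import nn
from gdtil.mtsfe import BACKBONE_BLOCKS, load_checkpoint, save_checkpoint


@pytest.fixture(scope="module")
def tiny_cfg():
    return MTSFEConfig(fs=128.0, n_channels=4, n_scales=2, temporal_filters_per_scale=4,
                       spatial_depth_multiplier=2, pool_kernel=4, pool_stride=8,
                       mhsa_depth=1, n_heads=2, encoder_filters=4, seed=1)


@pytest.fixture(scope="module")
def tiny_model(tiny_cfg):
    return MTSFE(tiny_cfg)


class TestVarPool:
    def test_constant_window_has_zero_variance(self):
        assert var_pool([3.0, 3.0, 3.0]) == 0.0

    def test_population_variance_formula(self):
        assert var_pool([1.0, 2.0, 3.0, 4.0]) == pytest.approx(1.25)

    def test_quadratic_homogeneity(self, rng):
        w = rng.normal(size=6)
        assert var_pool(3.0 * w) == pytest.approx(9.0 * var_pool(w))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            var_pool([])


class TestMHSA:
    def test_output_shape_equals_input_shape(self, rng):
        blk = nn.MHSABlock(8, 2, rng)
        x = nn.Tensor(rng.normal(size=(3, 5, 8)))
        assert blk(x).shape == (3, 5, 8)

    def test_attention_rows_normalize(self, rng):
        blk = nn.MHSABlock(8, 2, rng)
        x = nn.Tensor(rng.normal(size=(2, 6, 8)))
        attn = blk.attention_weights(x)
        assert np.allclose(attn.sum(axis=-1), 1.0)

    def test_identical_tokens_give_uniform_attention(self, rng):
        blk = nn.MHSABlock(8, 2, rng)
        row = rng.normal(size=8)
        x = nn.Tensor(np.tile(row, (1, 5, 1)))
        attn = blk.attention_weights(x)
        assert np.allclose(attn, 1.0 / 5)

    def test_single_head_matches_hand_computed_softmax(self):
        """1 head, d_h = 1, 2 tokens, hand-set projections: the inner
        attention must equal softmax(q kᵀ) v computed by hand."""
        blk = nn.MHSABlock(1, 1, np.random.default_rng(0))
        blk.wq.w.data[:] = 2.0
        blk.wq.b.data[:] = 0.0
        blk.wk.w.data[:] = 1.0
        blk.wk.b.data[:] = 0.0
        blk.wv.w.data[:] = 1.0
        blk.wv.b.data[:] = 0.0
        blk.wo.w.data[:] = 1.0
        blk.wo.b.data[:] = 0.0
        x = nn.Tensor(np.array([[[1.0], [2.0]]]))  # (1, 2, 1)
        out, attn = blk._mha(x, return_attn=True)
        q = 2.0 * x.data[0, :, 0]
        k = x.data[0, :, 0]
        v = x.data[0, :, 0]
        scores = np.outer(q, k)  # d_h = 1, no scaling change: /sqrt(1)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        w_hand = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(attn[0, 0], w_hand)
        assert np.allclose(out.data[0, :, 0], w_hand @ v)


class TestExtract:
    def test_forward_is_deterministic(self, tiny_model, rng):
        x = rng.normal(size=(4, 4, 128))
        f1 = tiny_model.extract(x)
        f2 = tiny_model.extract(x)
        assert np.array_equal(f1, f2)

    def test_zero_input_gives_finite_features(self, tiny_model):
        f = tiny_model.extract(np.zeros((2, 4, 128)))
        assert np.isfinite(f).all()

    def test_feature_width_matches_independent_shape_trace(self):
        """Walk the layer stack symbolically (same-padded temporal convs,
        electrode-collapsing spatial conv, strided pooling, width-preserving
        attention, valid (1,2) encoder, flatten) and compare with the
        actual output width, including the reference-scale configuration."""
        for cfg, v in [(MTSFEConfig(fs=250.0, n_channels=22, seed=0), 750),
                       (MTSFEConfig(fs=128.0, n_channels=4, n_scales=2,
                                    temporal_filters_per_scale=4, pool_stride=8,
                                    mhsa_depth=1, n_heads=2, encoder_filters=4,
                                    seed=0), 128)]:
            t_len = v  # temporal convs are same-padded
            maps = cfg.n_scales * cfg.temporal_filters_per_scale
            maps *= cfg.spatial_depth_multiplier  # electrode axis collapses to 1
            tokens = (t_len - cfg.pool_kernel) // cfg.pool_stride + 1
            # MHSA blocks preserve (tokens, width); branches concatenate in depth
            enc_in_len = tokens
            enc_out_len = enc_in_len - 2 + 1  # valid (1,2) kernel
            expected = cfg.encoder_filters * enc_out_len
            assert cfg.feature_dim(v) == expected
            if v == 128:  # run the small one end to end
                model = MTSFE(cfg)
                f = model.extract(np.zeros((1, cfg.n_channels, v)))
                assert f.shape == (1, expected)

    def test_trial_permutation_equivariance(self, tiny_model, rng):
        x = rng.normal(size=(6, 4, 128))
        perm = rng.permutation(6)
        f = tiny_model.extract(x)
        fp = tiny_model.extract(x[perm])
        assert np.allclose(fp, f[perm], atol=1e-10)

    def test_short_epoch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.extract(np.zeros((1, 4, 16)))


class TestFreezing:
    def test_optimizer_step_changes_only_encoder(self, tiny_cfg, rng):
        model = MTSFE(tiny_cfg)
        model.freeze_for_increment()
        before = {p.name: p.data.copy() for p in model.parameters()}
        digest_before = block_digest(model, BACKBONE_BLOCKS)
        opt = nn.Adam(model.parameters(), lr=0.05)
        f = model(rng.normal(size=(4, 4, 128)))
        (f * f).mean().backward()
        opt.step()
        assert block_digest(model, BACKBONE_BLOCKS) == digest_before
        changed = [p.name for p in model.parameters()
                   if not np.array_equal(p.data, before[p.name])]
        assert changed and all(n.startswith("encoder") for n in changed)

    def test_freeze_is_idempotent_and_invertible(self, tiny_cfg):
        model = MTSFE(tiny_cfg)
        trainable_init = {p.name for p in model.parameters() if p.trainable}
        model.freeze_for_increment()
        once = {p.name for p in model.parameters() if p.trainable}
        model.freeze_for_increment()
        twice = {p.name for p in model.parameters() if p.trainable}
        assert once == twice
        assert all(n.startswith("encoder") for n in once)
        model.unfreeze_all()
        assert {p.name for p in model.parameters() if p.trainable} == trainable_init


class TestCheckpoint:
    def test_roundtrip_restores_parameters(self, tiny_cfg, tmp_path, rng):
        model = MTSFE(tiny_cfg)
        x = rng.normal(size=(3, 4, 128))
        model.recalibrate_bn(x)
        path = tmp_path / "mtsfe.npz"
        save_checkpoint(model, str(path))
        back = load_checkpoint(str(path), tiny_cfg)
        assert np.array_equal(back.extract(x), model.extract(x))

    def test_mismatched_config_refused(self, tiny_cfg, tmp_path):
        model = MTSFE(tiny_cfg)
        path = tmp_path / "mtsfe.npz"
        save_checkpoint(model, str(path))
        other = MTSFEConfig(fs=128.0, n_channels=8, n_scales=2,
                            temporal_filters_per_scale=4, pool_stride=8,
                            mhsa_depth=1, n_heads=2, encoder_filters=4, seed=1)
        with pytest.raises(ValueError):
            load_checkpoint(str(path), other)


def test_dual_branch_weight_swap_symmetry(tiny_cfg, rng):
    """Swapping the two branch networks' weights while swapping the branch
    inputs leaves the encoder input unchanged up to depth-order permutation.
    Verified by feeding an input whose avg-pooled and var-pooled maps are
    exchanged via the weight swap."""
    model = MTSFE(tiny_cfg)
    x = rng.normal(size=(2, 4, 128))
    pre = model.pre_encoder(x).data
    half = pre.shape[1] // 2
    # swap the two MHSA stacks' weights
    for a, b in zip(model.mhsa_avg, model.mhsa_var):
        for pa, pb in zip(a.parameters(), b.parameters()):
            pa.data, pb.data = pb.data.copy(), pa.data.copy()
    # recompute with pooling branches also exchanged
    import gdtil.nn.functional as F
    orig_avg, orig_var = F.avg_pool_time, F.var_pool_time
    F.avg_pool_time, F.var_pool_time = orig_var, orig_avg
    try:
        swapped = model.pre_encoder(x).data
    finally:
        F.avg_pool_time, F.var_pool_time = orig_avg, orig_var
    assert np.allclose(swapped[:, :half], pre[:, half:], atol=1e-10)
    assert np.allclose(swapped[:, half:], pre[:, :half], atol=1e-10)
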