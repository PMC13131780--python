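"""Architecture components against brute-force oracles and shape contracts."""

import numpy as np
import pytest

from swinpick.network import (
    MASK_VALUE,
    ModelConfig,
    PatchExpand3D,
    PatchMerge3D,
    SwinBlock3D,
    SwinUNet3D,
    block_flatten,
    block_unflatten,
    relative_position_index,
    shifted_window_mask,
    skip_fuse,
    window_partition,
    window_reverse,
    WindowAttention3D,
)
from swinpick.nn.autograd import Tensor
from swinpick.nn.layers import LayerNorm


def _t(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


class TestPatchMerge:
    def test_shape_contract(self, rng):
        merge = PatchMerge3D(32, 64, 2, rng)
        out = merge(_t(rng.normal(size=(1, 8, 8, 8, 32))))
        assert out.shape == (1, 4, 4, 4, 64)

    def test_block_flatten_roundtrip(self, rng):
        x = _t(rng.normal(size=(2, 4, 4, 4, 5)))
        flat = block_flatten(x, 2)
        assert flat.shape == (2, 2, 2, 2, 40)
        back = block_unflatten(flat, 2, 5)
        np.testing.assert_array_equal(back.data, x.data)

    def test_identity_projection_reproduces_flattened_blocks(self, rng):
        c, s = 3, 2
        merge = PatchMerge3D(c, c * s**3, s, rng, normalize=False)
        merge.proj.weight.data = np.eye(c * s**3, dtype=np.float32)
        merge.proj.bias.data[:] = 0
        x = _t(rng.normal(size=(1, 4, 4, 4, c)))
        np.testing.assert_allclose(merge(x).data, block_flatten(x, s).data, rtol=1e-6)

    def test_indivisible_dims_rejected(self, rng):
        merge = PatchMerge3D(4, 8, 2, rng)
        with pytest.raises(ValueError, match="divisible"):
            merge(_t(np.zeros((1, 5, 4, 4, 4))))


class TestWindowPartition:
    def test_eight_windows_of_eight_tokens(self, rng):
        x = _t(rng.normal(size=(1, 4, 4, 4, 6)))
        w = window_partition(x, (2, 2, 2))
        assert w.shape == (1, 8, 8, 6)
        back = window_reverse(w, (2, 2, 2), (4, 4, 4))
        np.testing.assert_array_equal(back.data, x.data)

    def test_window_equal_to_extent_is_single_window(self, rng):
        x = _t(rng.normal(size=(1, 2, 2, 2, 3)))
        assert window_partition(x, (2, 2, 2)).shape == (1, 1, 8, 3)

    @pytest.mark.parametrize("window", [(2, 2, 2), (4, 2, 2)])
    def test_roundtrip_for_anisotropic_windows(self, window, rng):
        x = _t(rng.normal(size=(2, 4, 4, 4, 5)))
        back = window_reverse(window_partition(x, window), window, (4, 4, 4))
        np.testing.assert_array_equal(back.data, x.data)


class TestRelativePositionBias:
    def test_table_size_for_222_window(self):
        idx = relative_position_index((2, 2, 2))
        assert idx.shape == (8, 8)
        assert idx.max() == 26  # (2*2-1)^3 = 27 entries
        assert len(np.unique(idx)) == 27

    def test_equal_offsets_share_entries_exhaustively(self):
        window = (2, 2, 2)
        idx = relative_position_index(window)
        coords = [(z, y, x) for z in range(2) for y in range(2) for x in range(2)]
        seen = {}
        for i, ci in enumerate(coords):
            for j, cj in enumerate(coords):
                offset = tuple(a - b for a, b in zip(ci, cj))
                if offset in seen:
                    assert idx[i, j] == seen[offset]
                else:
                    seen[offset] = idx[i, j]

    def test_zero_table_reduces_to_unbiased_attention(self, rng):
        attn = WindowAttention3D(8, 2, 4, (2, 2, 2), rng)
        x = _t(rng.normal(size=(1, 2, 8, 8)))
        base = attn(x).data.copy()
        attn.bias_table.data[:] = rng.normal(size=attn.bias_table.shape)
        assert not np.allclose(attn(x).data, base)
        attn.bias_table.data[:] = 0
        np.testing.assert_allclose(attn(x).data, base, rtol=1e-6)


class TestWindowAttention:
    def test_single_token_window_returns_projected_value(self, rng):
        attn = WindowAttention3D(6, 2, 3, (1, 1, 1), rng)
        x = _t(rng.normal(size=(1, 4, 1, 6)))
        out = attn(x)
        # softmax over one logit is 1: output is proj(V) exactly
        qkv = x.data @ attn.qkv.weight.data + attn.qkv.bias.data
        v = qkv[..., 2 * 6 :]
        expect = v @ attn.proj.weight.data + attn.proj.bias.data
        np.testing.assert_allclose(out.data, expect, atol=1e-5)

    def test_equal_tokens_give_uniform_attention(self, rng):
        attn = WindowAttention3D(5, 1, 4, (2, 2, 2), rng)
        token = rng.normal(size=5).astype(np.float32)
        x = _t(np.broadcast_to(token, (1, 1, 8, 5)).copy())
        out = attn(x).data
        # with all tokens equal, the attention-weighted mean equals any V row
        np.testing.assert_allclose(out - out.mean(axis=2, keepdims=True), 0.0, atol=1e-5)

    def test_matches_dense_bruteforce_oracle(self, rng):
        dim, heads, hd = 12, 3, 4
        attn = WindowAttention3D(dim, heads, hd, (2, 2, 2), rng)
        attn.bias_table.data[:] = rng.normal(size=attn.bias_table.shape).astype(np.float32)
        x = rng.normal(size=(2, 3, 8, dim)).astype(np.float32)
        out = attn(_t(x)).data
        # independent dense computation
        qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
        idx = relative_position_index((2, 2, 2))
        bias = attn.bias_table.data[idx]  # (8, 8, heads)
        expect = np.zeros((2, 3, 8, heads * hd))
        for b in range(2):
            for w in range(3):
                for h in range(heads):
                    sl = slice(h * hd, (h + 1) * hd)
                    q = qkv[b, w, :, 0 * heads * hd :][:, sl]
                    k = qkv[b, w, :, 1 * heads * hd :][:, sl]
                    v = qkv[b, w, :, 2 * heads * hd :][:, sl]
                    logits = q @ k.T / np.sqrt(hd) + bias[:, :, h]
                    e = np.exp(logits - logits.max(axis=1, keepdims=True))
                    p = e / e.sum(axis=1, keepdims=True)
                    expect[b, w, :, sl] = p @ v
        expect = expect @ attn.proj.weight.data + attn.proj.bias.data
        assert np.abs(out - expect).max() <= 1e-5 * max(1.0, np.abs(expect).max())

    def test_full_extent_window_equals_dense_attention(self, rng):
        # window covering the whole grid with no mask is dense attention
        dim = 8
        attn = WindowAttention3D(dim, 2, 4, (2, 2, 2), rng)
        x = rng.normal(size=(1, 2, 2, 2, dim)).astype(np.float32)
        via_windows = window_reverse(
            attn(window_partition(_t(x), (2, 2, 2))), (2, 2, 2), (2, 2, 2)
        ).data
        dense = attn(_t(x.reshape(1, 1, 8, dim))).data.reshape(1, 2, 2, 2, dim)
        np.testing.assert_allclose(via_windows, dense, atol=1e-6)


class TestShiftedWindowMask:
    def test_zero_shift_masks_nothing(self):
        mask = shifted_window_mask((4, 4, 4), (2, 2, 2), (0, 0, 0))
        assert (mask == 0).all()

    def test_1d_analogue_masks_only_wrapped_pair(self):
        # extent 4, window 2, shift 1 along z: the wrapped window holds
        # original positions {3, 0}; exactly that pair is masked
        mask = shifted_window_mask((4, 1, 1), (2, 1, 1), (1, 0, 0))
        assert mask.shape == (2, 2, 2)
        first, second = mask[0], mask[1]
        assert (first == 0).all()  # original {1, 2}: spatially contiguous
        assert second[0, 1] == MASK_VALUE and second[1, 0] == MASK_VALUE
        assert second[0, 0] == 0 and second[1, 1] == 0

    def test_3d_mask_matches_bruteforce_region_ids(self):
        shape, window, shift = (4, 4, 4), (2, 2, 2), (1, 1, 1)
        mask = shifted_window_mask(shape, window, shift)
        # oracle: original coordinate of each rolled position; pairs whose
        # wrap indicator differs on any axis are masked
        coords = np.stack(
            np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
        )
        wrapped = np.stack(
            [(coords[..., a] + shift[a]) % shape[a] < shift[a] for a in range(3)], axis=-1
        )
        win = window_partition(
            Tensor(wrapped.astype(np.float32)[None]), window
        ).data[0].astype(bool)
        for w in range(win.shape[0]):
            for i in range(8):
                for j in range(8):
                    expect_masked = not np.array_equal(win[w, i], win[w, j])
                    assert (mask[w, i, j] == MASK_VALUE) == expect_masked

    def test_masked_pairs_get_negligible_attention(self, rng):
        attn = WindowAttention3D(4, 1, 4, (2, 1, 1), rng)
        mask = shifted_window_mask((4, 1, 1), (2, 1, 1), (1, 0, 0))
        x = _t(rng.normal(size=(1, 2, 2, 4)))
        qkv = attn.qkv(x).data
        # reconstruct the attention row of the masked pair
        logits = np.einsum("bwtc,bwsc->bwts", qkv[..., :4], qkv[..., 4:8]) / 2.0 + mask
        p = np.exp(logits - logits.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        assert p[0, 1, 0, 1] < 1e-6 and p[0, 1, 1, 0] < 1e-6


class TestSwinBlockAndFusion:
    def test_shape_preserved_across_resolutions(self, rng):
        for spatial in [(4, 4, 4), (2, 2, 2)]:
            block = SwinBlock3D(8, 2, 4, (2, 2, 2), shifted=True, rng=rng)
            x = _t(rng.normal(size=(1, *spatial, 8)))
            assert block(x).shape == x.shape

    def test_zeroed_weights_make_block_identity(self, rng):
        block = SwinBlock3D(8, 2, 4, (2, 2, 2), shifted=False, rng=rng)
        for module in (block.attn.qkv, block.attn.proj, block.mlp.fc1, block.mlp.fc2):
            module.weight.data[:] = 0
            module.bias.data[:] = 0
        x = _t(rng.normal(size=(1, 4, 4, 4, 8)))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)

    @pytest.mark.parametrize("dim", [32, 64])
    def test_mlp_hidden_width_is_four_c(self, dim, rng):
        block = SwinBlock3D(dim, 2, 4, (2, 2, 2), shifted=False, rng=rng)
        assert block.mlp.fc1.weight.shape == (dim, 4 * dim)

    def test_skip_fuse_additive_properties(self, rng):
        norm = LayerNorm(6)
        a = _t(rng.normal(size=(1, 2, 2, 2, 6)))
        b = _t(rng.normal(size=(1, 2, 2, 2, 6)))
        fused = skip_fuse(a, b, norm)
        assert fused.shape == a.shape
        np.testing.assert_allclose(fused.data, skip_fuse(b, a, norm).data, atol=1e-6)
        zero = _t(np.zeros_like(a.data))
        np.testing.assert_allclose(
            skip_fuse(a, zero, norm).data, norm(a).data, atol=1e-6
        )
        with pytest.raises(ValueError, match="skip shapes"):
            skip_fuse(a, _t(np.zeros((1, 2, 2, 2, 5))), norm)


class TestPatchExpand:
    def test_shape_contract(self, rng):
        expand = PatchExpand3D(16, 8, 2, rng)
        out = expand(_t(rng.normal(size=(1, 4, 4, 4, 16))))
        assert out.shape == (1, 8, 8, 8, 8)

    def test_expand_then_merge_restores_shape(self, rng):
        expand = PatchExpand3D(16, 8, 2, rng)
        merge = PatchMerge3D(8, 16, 2, rng)
        x = _t(rng.normal(size=(1, 4, 4, 4, 16)))
        assert merge(expand(x)).shape == x.shape


class TestFullNetwork:
    def test_logits_shape_and_softmax_normalization(self, rng):
        model = SwinUNet3D(ModelConfig.reduced(num_classes=5), seed=0)
        x = rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32)
        z = model.forward(x).data
        assert z.shape == (1, 5, 32, 32, 32)
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_decoder_restores_input_resolution_for_64_window(self, rng):
        cfg = ModelConfig.reduced(num_classes=3)
        model = SwinUNet3D(cfg, seed=0)
        x = rng.normal(size=(1, 4, 64, 64, 64)).astype(np.float32)
        assert model.forward(x).data.shape == (1, 3, 64, 64, 64)

    def test_indivisible_input_rejected(self, rng):
        model = SwinUNet3D(ModelConfig.reduced(num_classes=3), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 4, 24, 24, 24), dtype=np.float32))

    def test_class_permutation_consistency(self, rng):
        # permuting head weights permutes logit channels identically
        model = SwinUNet3D(ModelConfig.reduced(num_classes=4), seed=1)
        x = rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32)
        base = model.forward(x).data
        perm = [2, 0, 3, 1]
        model.head.weight.data = model.head.weight.data[:, perm]
        model.head.bias.data = model.head.bias.data[perm]
        permuted = model.forward(x).data
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-5)

    def test_state_dict_roundtrip_reproduces_output(self, rng):
        cfg = ModelConfig.reduced(num_classes=3)
        a = SwinUNet3D(cfg, seed=3)
        b = SwinUNet3D(cfg, seed=4)
        x = rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32)
        assert not np.allclose(a.forward(x).data, b.forward(x).data)
        b.load_state_dict(a.state_dict())
        np.testing.assert_array_equal(a.forward(x).data, b.forward(x).data)

    def test_odd_depths_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(num_classes=2, depths=(1, 2, 2, 2))
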