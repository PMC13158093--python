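"""Network components against independent scalar-loop oracles, routing
endpoint identities, and analytic parameter counting."""

import math

import numpy as np
import pytest

from cvit3d import _nn as nn
from cvit3d.model import (
    CAEFF, CVit3D, DSGC, MSFE, MHSA, EncoderBlock, ModelConfig, SEBlock,
    Tokenizer, VolumeBatch, count_params, preset,
)


def _sig(v):
    return 1.0 / (1.0 + np.exp(-v))


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------

class TestSE:
    def _block(self, channels=2, reduction=2, seed=5):
        return SEBlock(channels, reduction, np.random.default_rng(seed),
                       dtype=np.float64)

    def test_matches_scalar_oracle(self):
        """pool -> bottleneck perceptron -> sigmoid -> rescale, by hand."""
        r = np.random.default_rng(1)
        se = self._block()
        x = r.standard_normal((2, 2, 4, 4, 4))
        out, weights = se(nn.Tensor(x))
        w1, b1 = se.fc1.w.data, se.fc1.b.data
        w2, b2 = se.fc2.w.data, se.fc2.b.data
        for b in range(2):
            pooled = np.array([x[b, c].mean() for c in range(2)])
            h = np.maximum(pooled @ w1 + b1, 0.0)
            wexp = _sig(h @ w2 + b2)
            np.testing.assert_allclose(weights[b], wexp, atol=1e-6)
            for c in range(2):
                np.testing.assert_allclose(out.data[b, c], x[b, c] * wexp[c],
                                           atol=1e-6)

    def test_unit_weights_give_identity(self):
        se = self._block()
        se.fc1.w.data[:] = 0
        se.fc1.b.data[:] = 0
        se.fc2.w.data[:] = 0
        se.fc2.b.data[:] = 50.0  # sigmoid saturates to 1
        x = np.random.default_rng(2).standard_normal((1, 2, 3, 3, 3))
        out, w = se(nn.Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)
        np.testing.assert_allclose(w, 1.0)

    def test_zero_input_gives_zero_output(self):
        se = self._block()
        out, _ = se(nn.Tensor(np.zeros((1, 2, 3, 3, 3))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_rejects_bad_reduction(self):
        with pytest.raises(ValueError, match="reduction"):
            SEBlock(6, 4, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# gate network
# ---------------------------------------------------------------------------

class TestGate:
    def test_zero_weights_give_half(self):
        from cvit3d.model import GateNetwork
        gn = GateNetwork(3, np.random.default_rng(0), dtype=np.float64)
        gn.fc.w.data[:] = 0
        gn.fc.b.data[:] = 0
        g = gn(nn.Tensor(np.random.default_rng(1).standard_normal((2, 3, 4, 4, 4))))
        np.testing.assert_allclose(g.data, 0.5)

    def test_large_bias_saturates(self):
        from cvit3d.model import GateNetwork
        gn = GateNetwork(3, np.random.default_rng(0), dtype=np.float64)
        gn.fc.b.data[:] = 40.0
        g = gn(nn.Tensor(np.random.default_rng(1).standard_normal((1, 3, 2, 2, 2))))
        np.testing.assert_allclose(g.data, 1.0, atol=1e-8)

    def test_matches_scalar_oracle(self):
        from cvit3d.model import GateNetwork
        r = np.random.default_rng(9)
        gn = GateNetwork(4, r, dtype=np.float64)
        x = r.standard_normal((3, 4, 2, 3, 2))
        g = gn(nn.Tensor(x)).data
        for b in range(3):
            pooled = np.array([x[b, c].mean() for c in range(4)])
            np.testing.assert_allclose(
                g[b], _sig(pooled @ gn.fc.w.data + gn.fc.b.data), atol=1e-6)

    def test_rejects_nan(self):
        from cvit3d.model import GateNetwork
        gn = GateNetwork(2, np.random.default_rng(0))
        x = np.zeros((1, 2, 2, 2, 2))
        x[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            gn(nn.Tensor(x))


# ---------------------------------------------------------------------------
# DSGC
# ---------------------------------------------------------------------------

def _loop_depthwise(x, w, b, stride, pad):
    """Independent per-channel convolution oracle (explicit loops)."""
    B, C, D, H, W = x.shape
    k = w.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Do = (D + 2 * pad - k) // stride + 1
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    out = np.zeros((B, C, Do, Ho, Wo))
    for bb in range(B):
        for c in range(C):
            for i in range(Do):
                for j in range(Ho):
                    for l in range(Wo):
                        patch = xp[bb, c, i * stride:i * stride + k,
                                   j * stride:j * stride + k,
                                   l * stride:l * stride + k]
                        out[bb, c, i, j, l] = (patch * w[c, 0]).sum() + b[c]
    return out


def _loop_grouped_pointwise(x, w, b, groups):
    """Independent grouped 1x1x1 convolution oracle."""
    B, C, D, H, W = x.shape
    Cout = w.shape[0]
    cg_in, cg_out = C // groups, Cout // groups
    out = np.zeros((B, Cout, D, H, W))
    for g in range(groups):
        for oc in range(cg_out):
            o = g * cg_out + oc
            acc = np.zeros((B, D, H, W))
            for ic in range(cg_in):
                acc += x[:, g * cg_in + ic] * w[o, ic, 0, 0, 0]
            out[:, o] = acc + b[o]
    return out


class TestDSGC:
    def test_identity_kernels(self):
        """K=1 depthwise identity + identity pointwise reproduce the input."""
        d = DSGC(4, 4, np.random.default_rng(0), kernel=1, padding=0,
                 dtype=np.float64)
        d.depthwise.w.data[:] = 1.0
        d.depthwise.b.data[:] = 0.0
        # groups = gcd(4,4) = 4: each group is 1->1, so scalar weight 1
        d.pointwise.w.data[:] = 1.0
        d.pointwise.b.data[:] = 0.0
        x = np.random.default_rng(1).standard_normal((2, 4, 3, 3, 3))
        np.testing.assert_allclose(d(nn.Tensor(x)).data, x, atol=1e-12)

    def test_gcd_one_is_single_group(self):
        d = DSGC(3, 7, np.random.default_rng(0))
        assert d.pointwise.groups == 1
        assert d.pointwise.w.shape == (7, 3, 1, 1, 1)

    def test_matches_two_stage_loop_oracle(self):
        r = np.random.default_rng(4)
        d = DSGC(6, 9, r, stride=1, padding=1, dtype=np.float64)
        assert d.pointwise.groups == 3  # gcd(6, 9)
        x = r.standard_normal((2, 6, 4, 4, 4))
        got = d(nn.Tensor(x)).data
        mid = _loop_depthwise(x, d.depthwise.w.data, d.depthwise.b.data, 1, 1)
        want = _loop_grouped_pointwise(mid, d.pointwise.w.data,
                                       d.pointwise.b.data, 3)
        np.testing.assert_allclose(got, want, atol=1e-5)


# ---------------------------------------------------------------------------
# CAEFF routing
# ---------------------------------------------------------------------------

class TestCAEFF:
    @pytest.fixture()
    def caeff(self, tiny_config):
        return CAEFF(tiny_config, np.random.default_rng(3), dtype=np.float64)

    @pytest.fixture()
    def x5(self, tiny_config):
        r = np.random.default_rng(8)
        return r.standard_normal((2, 5, *tiny_config.input_shape))

    def test_gate_one_recovers_standard_path(self, caeff, x5, tiny_config):
        out, rec = caeff(nn.Tensor(x5), gate_override=1.0)
        c = tiny_config.stem_channels
        for i in rec["gated_channels"]:
            std = caeff.std_convs[i](nn.Tensor(x5[:, i:i + 1])).data
            np.testing.assert_array_equal(out.data[:, i * c:(i + 1) * c], std)

    def test_gate_zero_recovers_dsgc_path(self, caeff, x5, tiny_config):
        out, rec = caeff(nn.Tensor(x5), gate_override=0.0)
        c = tiny_config.stem_channels
        for i in rec["gated_channels"]:
            alt = caeff.dsgc[i](nn.Tensor(x5[:, i:i + 1])).data
            np.testing.assert_array_equal(out.data[:, i * c:(i + 1) * c], alt)

    def test_convex_blend_between_endpoints(self, caeff, x5, tiny_config):
        """Soft-routed output lies elementwise between the two endpoints."""
        hi, rec = caeff(nn.Tensor(x5), gate_override=1.0)
        lo, _ = caeff(nn.Tensor(x5), gate_override=0.0)
        mid, _ = caeff(nn.Tensor(x5))
        c = tiny_config.stem_channels
        for i in rec["gated_channels"]:
            sl = slice(i * c, (i + 1) * c)
            lo_i = np.minimum(hi.data[:, sl], lo.data[:, sl])
            hi_i = np.maximum(hi.data[:, sl], lo.data[:, sl])
            assert (mid.data[:, sl] >= lo_i - 1e-9).all()
            assert (mid.data[:, sl] <= hi_i + 1e-9).all()

    def test_gates_in_unit_interval(self, caeff, x5):
        _, rec = caeff(nn.Tensor(x5))
        assert ((rec["gates"] > 0) & (rec["gates"] < 1)).all()
        assert ((rec["se_weights"] > 0) & (rec["se_weights"] < 1)).all()

    def test_rejects_wrong_channel_count(self, caeff, tiny_config):
        x = np.zeros((1, 4, *tiny_config.input_shape))
        with pytest.raises(ValueError, match="5 input channels"):
            caeff(nn.Tensor(x))


# ---------------------------------------------------------------------------
# MSFE
# ---------------------------------------------------------------------------

class TestMSFE:
    def test_gn_one_equals_plain_dsgc(self):
        r = np.random.default_rng(2)
        m = MSFE(4, 6, 1, r, dtype=np.float64)
        x = r.standard_normal((2, 4, 4, 4, 4))
        out, _ = m(nn.Tensor(x), gn_override=1.0)
        np.testing.assert_array_equal(out.data, m.dsgc(nn.Tensor(x)).data)

    def test_gn_zero_gives_bias_only_response(self):
        r = np.random.default_rng(2)
        m = MSFE(4, 6, 1, r, dtype=np.float64)
        x = r.standard_normal((2, 4, 4, 4, 4))
        out, _ = m(nn.Tensor(x), gn_override=0.0)
        zero = m.dsgc(nn.Tensor(np.zeros_like(x))).data
        np.testing.assert_array_equal(out.data, zero)

    def test_matches_modulate_then_dsgc_composition(self):
        r = np.random.default_rng(6)
        m = MSFE(4, 6, 2, r, dtype=np.float64)
        x = r.standard_normal((2, 4, 6, 6, 6))
        out, w = m(nn.Tensor(x))
        scaled = x * w[:, :, None, None, None]
        want = m.dsgc(nn.Tensor(scaled)).data
        np.testing.assert_allclose(out.data, want, atol=1e-5)


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

class TestTokenizer:
    def test_token_count_includes_cls(self):
        tk = Tokenizer(3, (2, 2, 2), 8, np.random.default_rng(0))
        x = nn.Tensor(np.random.default_rng(1).standard_normal((2, 3, 2, 2, 2)))
        assert tk(x).shape == (2, 9, 8)

    def test_zero_projection_leaves_positions_only(self):
        tk = Tokenizer(3, (2, 2, 2), 8, np.random.default_rng(0),
                       dtype=np.float64)
        tk.proj.w.data[:] = 0
        tk.proj.b.data[:] = 0
        tk.pos.data[:] = 0
        x = nn.Tensor(np.random.default_rng(1).standard_normal((2, 3, 2, 2, 2)))
        toks = tk(x).data
        np.testing.assert_array_equal(toks[:, 1:], 0.0)
        np.testing.assert_array_equal(
            toks[:, 0], np.broadcast_to(tk.cls.data[0], (2, 8)))

    def test_position_index_map_is_bijection(self):
        grid = (2, 3, 4)
        tk = Tokenizer(3, grid, 8, np.random.default_rng(0))
        seen = set()
        for d in range(grid[0]):
            for h in range(grid[1]):
                for w in range(grid[2]):
                    t = tk.token_index(d, h, w)
                    assert tk.grid_index(t) == (d, h, w)
                    seen.add(t)
        assert seen == set(range(1, 1 + 2 * 3 * 4))


# ---------------------------------------------------------------------------
# attention + encoder
# ---------------------------------------------------------------------------

def _loop_mhsa(x, qkv_w, qkv_b, proj_w, proj_b, heads):
    """Independent multi-head attention oracle with explicit slicing."""
    B, T, E = x.shape
    dh = E // heads
    out = np.zeros_like(x)
    for b in range(B):
        qkv = x[b] @ qkv_w + qkv_b          # [T, 3E]
        q, k, v = qkv[:, :E], qkv[:, E:2 * E], qkv[:, 2 * E:]
        merged = np.zeros((T, E))
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            s = q[:, sl] @ k[:, sl].T / math.sqrt(dh)
            e = np.exp(s - s.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            merged[:, sl] = a @ v[:, sl]
        out[b] = merged @ proj_w + proj_b
    return out


class TestMHSA:
    def test_single_token_attention_is_one(self):
        r = np.random.default_rng(0)
        m = MHSA(8, 2, r, dtype=np.float64)
        x = nn.Tensor(r.standard_normal((1, 1, 8)))
        out, maps = m(x)
        np.testing.assert_allclose(maps, 1.0)
        assert out.shape == (1, 1, 8)

    def test_rows_sum_to_one(self):
        r = np.random.default_rng(1)
        m = MHSA(8, 4, r, dtype=np.float64)
        _, maps = m(nn.Tensor(r.standard_normal((2, 6, 8))))
        np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)
        assert (maps >= 0).all()

    def test_matches_per_head_loop_oracle(self):
        """100 random small cases vs explicit Q/K/V slicing + naive softmax."""
        r = np.random.default_rng(2)
        for trial in range(100):
            heads = int(r.integers(1, 4))
            dh = int(r.integers(2, 5))
            e = heads * dh
            t = int(r.integers(1, 6))
            m = MHSA(e, heads, r, dtype=np.float64)
            x = r.standard_normal((2, t, e))
            got, _ = m(nn.Tensor(x))
            want = _loop_mhsa(x, m.qkv.w.data, m.qkv.b.data,
                              m.proj.w.data, m.proj.b.data, heads)
            np.testing.assert_allclose(got.data, want, atol=1e-5)


class TestEncoderBlock:
    def test_zero_weights_act_as_identity(self):
        r = np.random.default_rng(0)
        blk = EncoderBlock(8, 2, 2.0, r, dtype=np.float64)
        for p in (blk.attn.qkv, blk.attn.proj, blk.fc1, blk.fc2):
            p.w.data[:] = 0
            p.b.data[:] = 0
        x = r.standard_normal((2, 5, 8))
        out, _ = blk(nn.Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_depth_stack_preserves_shape(self):
        r = np.random.default_rng(1)
        blocks = [EncoderBlock(8, 2, 2.0, r) for _ in range(8)]
        x = nn.Tensor(r.standard_normal((2, 5, 8)).astype(np.float32))
        for blk in blocks:
            x, _ = blk(x)
        assert x.shape == (2, 5, 8)

    def test_gradient_reaches_input(self):
        """CLS-loss gradients flow to the input (no detached paths),
        spot-checked against a finite difference."""
        r = np.random.default_rng(2)
        blk = EncoderBlock(6, 2, 2.0, r, dtype=np.float64)
        x = r.standard_normal((1, 3, 6))

        def loss(arr):
            t = nn.Tensor(arr, requires_grad=True)
            out, _ = blk(t)
            return out[:, 0].sum(), t

        val, t = loss(x)
        val.backward()
        assert np.abs(t.grad).max() > 0
        eps = 1e-6
        idx = (0, 1, 2)
        hi = x.copy(); hi[idx] += eps
        lo = x.copy(); lo[idx] -= eps
        fd = (loss(hi)[0].data - loss(lo)[0].data) / (2 * eps)
        assert abs(fd - t.grad[idx]) < 1e-5


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class TestModelForward:
    def test_output_shape_and_probability_range(self, tiny_model, tiny_batch):
        logits, bundle = tiny_model(VolumeBatch(tiny_batch))
        assert logits.shape == (3, 1)
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        assert ((probs > 0) & (probs < 1)).all()
        assert bundle["cls_features"].shape == (3, tiny_model.config.embed_dim)

    def test_duplicated_samples_get_identical_logits(self, tiny_model, tiny_batch):
        dup = np.concatenate([tiny_batch[:1], tiny_batch[:1]])
        logits, _ = tiny_model(VolumeBatch(dup))
        np.testing.assert_array_equal(logits.data[0], logits.data[1])

    def test_seeded_forward_is_bitwise_reproducible(self, tiny_config, tiny_batch):
        a = CVit3D(tiny_config, seed=123)
        b = CVit3D(tiny_config, seed=123)
        la, _ = a(VolumeBatch(tiny_batch))
        lb, _ = b(VolumeBatch(tiny_batch))
        np.testing.assert_array_equal(la.data, lb.data)

    def test_attention_rows_sum_to_one(self, tiny_model, tiny_batch):
        _, bundle = tiny_model(VolumeBatch(tiny_batch))
        for maps in bundle["attention"]:
            np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)

    def test_shape_mismatch_names_stage(self, tiny_model):
        bad = np.zeros((1, 5, 4, 4, 4), dtype=np.float32)
        with pytest.raises(ValueError, match=r"\[input\]"):
            tiny_model(VolumeBatch(bad))

    def test_volume_batch_validation(self):
        with pytest.raises(ValueError, match="length 5"):
            VolumeBatch(np.zeros((1, 4, 2, 2, 2)))
        bad = np.zeros((1, 5, 2, 2, 2))
        bad[0, 0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="NaN/Inf"):
            VolumeBatch(bad)

    def test_checkpoint_roundtrip(self, tiny_model, tiny_batch, tmp_path):
        tiny_model.save(tmp_path / "ckpt.pkl")
        again = CVit3D.load(tmp_path / "ckpt.pkl")
        la, _ = tiny_model(VolumeBatch(tiny_batch))
        lb, _ = again(VolumeBatch(tiny_batch))
        np.testing.assert_array_equal(la.data, lb.data)


class TestCountParams:
    def test_single_conv_hand_count(self):
        # one dense 3x3x3 conv, 1 -> 1 channel, with bias: 27 + 1
        layer = nn.Conv3d(1, 1, 3, rng=np.random.default_rng(0))
        assert layer.w.size + layer.b.size == 28

    def test_paper_preset_head_size(self):
        cfg = preset("paper")
        assert cfg.embed_dim == 768 and cfg.num_heads == 12
        assert cfg.head_dim == 64

    @pytest.mark.parametrize("name", ["desk"])
    def test_analytic_equals_introspection(self, name, tiny_config):
        for cfg in (preset(name), tiny_config):
            total, rows = count_params(cfg)
            assert total == CVit3D(cfg).n_params()
            assert total == sum(r["params"] for r in rows)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(embed_dim=10, num_heads=4)
        with pytest.raises(ValueError, match="5 input sequences"):
            ModelConfig(in_sequences=("a", "b"))

    def test_json_roundtrip(self):
        cfg = preset("desk")
        assert ModelConfig.from_json(cfg.to_json()) == cfg
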