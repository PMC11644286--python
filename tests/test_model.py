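"""Fusion modules, attention gates, decoder ladder, and the full network."""

import numpy as np
import pytest

from mugennet import nn
from mugennet.config import model_preset
from mugennet.losses import total_loss
from mugennet.model import AttentionGate, ChannelAttention, MugenFusion, SEAttention, build_model
from mugennet.nn import Tensor


@pytest.fixture(scope="module")
def feat(request):
    return Tensor(np.random.default_rng(0).standard_normal((2, 16, 8, 8)).astype(np.float32))


class TestSEAttention:
    def test_shape_and_gate_range(self, feat):
        se = SEAttention(16, 4, np.random.default_rng(1))
        out, gates = se(feat, return_gates=True)
        assert out.shape == feat.shape
        assert np.all(gates.data > 0) and np.all(gates.data < 1)

    def test_saturated_bias_passes_through(self, feat):
        se = SEAttention(16, 4, np.random.default_rng(1))
        se.fc2.bias.data[...] = 50.0
        se.fc2.weight.data[...] = 0.0
        out = se(feat)
        np.testing.assert_allclose(out.data, feat.data, rtol=1e-5)

    def test_divisibility_check(self):
        with pytest.raises(ValueError):
            SEAttention(10, 4, np.random.default_rng(0))


class TestChannelAttention:
    def test_gate_depends_only_on_channel_max(self, feat):
        ca = ChannelAttention(16, 4, np.random.default_rng(2))
        g1 = ca.gates(feat).data
        bumped = feat.data.copy()
        # raise a non-maximal pixel of channel 0 without touching the max
        b, c = 0, 0
        flat = bumped[b, c].ravel()
        mx = flat.argmax()
        other = (mx + 1) % flat.size
        flat[other] = (flat[other] + flat[mx]) / 2
        g2 = ca.gates(Tensor(bumped)).data
        np.testing.assert_array_equal(g1, g2)

    def test_zero_channel_gate_matches_network_at_zero(self):
        ca = ChannelAttention(16, 4, np.random.default_rng(2), dtype=np.float64)
        x = Tensor(np.zeros((1, 16, 4, 4)))
        gates = ca.gates(x).data[0]
        hidden = np.maximum(ca.fc1.bias.data, 0) @ ca.fc2.weight.data + ca.fc2.bias.data
        np.testing.assert_allclose(gates, 1 / (1 + np.exp(-hidden)), atol=1e-12)


class TestMugenFusion:
    def test_shape_preserved(self, feat):
        cfg = model_preset("desk")
        fuse = MugenFusion(16, cfg, np.random.default_rng(3))
        out = fuse(feat, feat)
        assert out.shape == feat.shape

    def test_residual_identity_when_learned_path_zeroed(self, feat):
        cfg = model_preset("desk")
        fuse = MugenFusion(16, cfg, np.random.default_rng(3))
        fuse.post.weight.data[...] = 0
        fuse.post.bias.data[...] = 0
        raw = nn.concatenate([feat, feat], axis=1)
        expected = fuse.skip(raw).data
        np.testing.assert_allclose(fuse(feat, feat).data, expected, atol=1e-6)

    def test_shape_mismatch_raises(self, feat):
        cfg = model_preset("desk")
        fuse = MugenFusion(16, cfg, np.random.default_rng(3))
        with pytest.raises(ValueError):
            fuse(feat, Tensor(np.zeros((2, 16, 4, 4), dtype=np.float32)))


class TestAttentionGate:
    def test_coefficients_in_open_interval(self, feat):
        ag = AttentionGate(16, 16, np.random.default_rng(4))
        _, alpha = ag(feat, feat, return_alpha=True)
        assert np.all(alpha.data > 0) and np.all(alpha.data < 1)

    def test_saturated_psi_passes_input_through(self, feat):
        ag = AttentionGate(16, 16, np.random.default_rng(4))
        ag.psi.bias.data[...] = 60.0
        ag.psi.weight.data[...] = 0.0
        out = ag(feat, feat)
        np.testing.assert_allclose(out.data, feat.data, rtol=1e-5)

    def test_coarser_gate_is_upsampled(self):
        rng = np.random.default_rng(5)
        ag = AttentionGate(8, 8, rng)
        g = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        assert ag(g, x).shape == x.shape

    def test_scale_mismatch_raises(self):
        rng = np.random.default_rng(5)
        ag = AttentionGate(8, 8, rng)
        g = Tensor(np.zeros((1, 8, 3, 3), dtype=np.float32))
        x = Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            ag(g, x)


class TestFullForward:
    def test_decoder_ladder_256x192(self):
        model = build_model(model_preset("desk"))
        with nn.no_grad():
            st = model(Tensor(np.zeros((1, 3, 192, 256), dtype=np.float32)))
        assert st.z1.shape[2:] == (24, 32)
        assert st.z2.shape[2:] == (48, 64)
        assert st.z3.shape[2:] == (96, 128)
        assert st.zout.shape == (1, 1, 192, 256)

    def test_all_outputs_full_resolution_probabilities(self, desk_model, train_batch):
        x, _ = train_batch
        with nn.no_grad():
            st = desk_model(Tensor(x[:2]))
        for out in (st.zout, st.s_t, st.s_r, st.s_z):
            assert out.shape == (2, 1, 64, 64)
            assert out.data.min() >= 0.0 and out.data.max() <= 1.0
        for alpha in st.alphas.values():
            assert np.all(alpha.data > 0) and np.all(alpha.data < 1)

    @pytest.mark.parametrize("ablation", ["backbone", "backbone+cb", "backbone+tb"])
    def test_ablation_forward_succeeds(self, ablation, train_batch):
        x, _ = train_batch
        model = build_model(model_preset("desk", ablation=ablation))
        with nn.no_grad():
            st = model(Tensor(x[:1]))
        assert st.zout.shape == (1, 1, 64, 64)
        if ablation in ("backbone", "backbone+cb"):
            assert st.s_t is None
        else:
            assert st.s_t is not None

    def test_gradient_reaches_every_parameter(self, train_batch):
        x, gt = train_batch
        model = build_model(model_preset("desk"))
        st = model(Tensor(x[:4]))
        outs = {k: v.reshape(v.shape[0], v.shape[2], v.shape[3]) for k, v in st.outputs().items()}
        loss, _ = total_loss(outs, gt[:4])
        model.zero_grad()
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_deterministic_forward(self, train_batch):
        x, _ = train_batch
        outs = []
        for _ in range(2):
            model = build_model(model_preset("desk"))
            with nn.no_grad():
                outs.append(model(Tensor(x[:1])).zout.data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_checkpoint_roundtrip_exact(self, tmp_path, train_batch):
        x, _ = train_batch
        model = build_model(model_preset("desk", seed=3))
        model.save(tmp_path / "ckpt.npz")
        clone = build_model(model_preset("desk", seed=99))
        clone.load(tmp_path / "ckpt.npz")
        with nn.no_grad():
            a = model(Tensor(x[:2])).zout.data
            b = clone(Tensor(x[:2])).zout.data
        np.testing.assert_array_equal(a, b)
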