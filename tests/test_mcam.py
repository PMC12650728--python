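"""Multi-scale composite attention: bounds, degeneracies, statistics oracles."""

import numpy as np
import pytest

from snakeseg.exceptions import ConfigurationError
from snakeseg.mcam import MCAM, McamConfig
from snakeseg.nn import Tensor


def make(channels, rng, **kw):
    return MCAM(McamConfig(channels=channels, **kw), rng)


@pytest.mark.parametrize("channels,size", [(8, 16), (16, 32), (32, 16)])
def test_output_shape_preserved(channels, size, rng):
    mcam = make(channels, rng)
    x = Tensor(rng.standard_normal((2, channels, size, size)).astype(np.float32))
    assert mcam(x).shape == x.shape


def test_multiscale_fuse_channel_arithmetic(rng):
    mcam = make(16, rng)
    x = Tensor(rng.standard_normal((1, 16, 32, 32)).astype(np.float32))
    fms = mcam.multiscale_fuse(x)
    assert fms.shape == (1, 4, 32, 32)
    # concatenated branch map before fusion carries 3 * C/4 channels
    assert mcam.fuse.weight.shape == (4, 12, 1, 1)


def test_compression_must_divide_channels():
    with pytest.raises(ConfigurationError):
        McamConfig(channels=10, compression_ratio=4)


def test_spatially_constant_input_propagates_to_constant_fms(rng):
    mcam = make(8, rng)
    x = Tensor(np.full((1, 8, 16, 16), 0.7, dtype=np.float32))
    fms = mcam.multiscale_fuse(x).data
    # replication padding keeps every branch constant, hence Fms constant
    for c in range(fms.shape[1]):
        assert np.ptp(fms[0, c]) < 1e-5


class TestSpatialAttention:
    def test_map_strictly_inside_unit_interval(self, rng):
        mcam = make(8, rng)
        fms = Tensor(rng.standard_normal((2, 2, 12, 12)).astype(np.float32) * 5)
        ms, fs = mcam.spatial_attention(fms)
        assert np.all(ms.data > 0) and np.all(ms.data < 1)
        assert fs.shape == fms.shape

    def test_constant_fms_gives_uniform_rescaling(self, rng):
        mcam = make(8, rng)
        fms = Tensor(np.full((1, 2, 8, 8), 1.3, dtype=np.float32))
        ms, fs = mcam.spatial_attention(fms)
        assert np.ptp(ms.data) < 1e-6
        np.testing.assert_allclose(fs.data, 1.3 * ms.data[0, 0, 0, 0], rtol=1e-5)

    def test_pooling_matches_per_position_loops(self, rng):
        mcam = make(16, rng)
        fms = Tensor(rng.standard_normal((1, 4, 16, 16)).astype(np.float32))
        favg = fms.mean(axis=1, keepdims=True).data[0, 0]
        fmax = fms.max(axis=1, keepdims=True).data[0, 0]
        for r in range(16):
            for c in range(16):
                assert favg[r, c] == pytest.approx(float(np.mean(fms.data[0, :, r, c])), abs=1e-6)
                assert fmax[r, c] == pytest.approx(float(np.max(fms.data[0, :, r, c])), abs=1e-6)


class TestChannelAttention:
    def test_identical_channels_give_neutral_half_weight(self, rng):
        mcam = make(8, rng)
        one = rng.standard_normal((1, 1, 8, 8)).astype(np.float32)
        x = Tensor(np.repeat(one, 8, axis=1))
        mc, _ = mcam.channel_attention_simam(x)
        np.testing.assert_allclose(mc.data, 0.5, atol=1e-6)

    def test_weights_bounded_in_zero_to_half(self, rng):
        mcam = make(8, rng)
        x = Tensor(rng.standard_normal((3, 8, 10, 10)).astype(np.float32) * 4)
        mc, fc = mcam.channel_attention_simam(x)
        assert np.all(mc.data > 0) and np.all(mc.data <= 0.5)
        np.testing.assert_allclose(fc.data, x.data * mc.data, rtol=1e-6)

    def test_statistics_match_two_pass_loop(self, rng):
        cfg = McamConfig(channels=8, epsilon=1e-4)
        mcam = MCAM(cfg, rng)
        x = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
        xt = Tensor(np.concatenate([x, np.zeros((1, 2, 8, 8), np.float32)], axis=1))
        mc, _ = mcam.channel_attention_simam(xt)
        t = float(xt.data.mean())
        for c in range(6):
            mu = float(np.mean(x[0, c]))
            var = float(np.var(x[0, c]))
            ec = (mu - t) ** 2 / (var + cfg.epsilon)
            want = 1.0 / (1.0 + np.exp(ec))
            assert mc.data[0, c, 0, 0] == pytest.approx(want, rel=1e-4)

    def test_invariant_to_spatial_permutation(self, rng):
        mcam = make(8, rng)
        x = rng.standard_normal((1, 8, 6, 6)).astype(np.float32)
        perm = rng.permutation(36)
        xp = x.reshape(1, 8, 36)[:, :, perm].reshape(1, 8, 6, 6)
        mc_a, _ = mcam.channel_attention_simam(Tensor(x))
        mc_b, _ = mcam.channel_attention_simam(Tensor(np.ascontiguousarray(xp)))
        np.testing.assert_allclose(mc_a.data, mc_b.data, rtol=1e-5)

    def test_zero_t_strategy(self, rng):
        mcam = make(8, rng, t_strategy="zero")
        x = Tensor(np.full((1, 8, 4, 4), 2.0, dtype=np.float32))
        mc, _ = mcam.channel_attention_simam(x)
        # constant channels: mu=2, var=0 -> Ec = 4/eps, weight ~ 0
        assert np.all(mc.data < 1e-6)

    def test_single_pixel_map_floored_by_epsilon(self, rng):
        mcam = make(8, rng)
        x = Tensor(rng.standard_normal((1, 8, 1, 1)).astype(np.float32))
        mc, _ = mcam.channel_attention_simam(x)
        assert np.all(np.isfinite(mc.data))


def test_residual_identity_with_zeroed_expansion(rng):
    mcam = make(8, rng)
    mcam.expand.weight.data[:] = 0.0
    x = Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))
    np.testing.assert_array_equal(mcam(x).data, x.data)


def test_every_parameter_receives_gradient(rng):
    mcam = make(8, rng)
    x = Tensor(rng.standard_normal((2, 8, 16, 16)).astype(np.float32))
    out = mcam(x)
    (out * out).sum().backward()
    for name, p in mcam.named_parameters():
        assert p.grad is not None and np.linalg.norm(p.grad) > 0, name
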