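"""Dynamic snake convolution: offsets, sampling, and degeneracy properties."""

import numpy as np
import pytest
from scipy import ndimage

from snakeseg.exceptions import ConfigurationError
from snakeseg.nn import Tensor
from snakeseg.snake_conv import (
    DynamicSnakeConv,
    SnakeKernelSpec,
    predict_offsets,
    sample_bilinear,
    snake_convolve,
)


@pytest.fixture
def spec():
    return SnakeKernelSpec(axis="x", in_channels=2, out_channels=3)


class TestSpecValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            SnakeKernelSpec(axis="x", in_channels=1, out_channels=1, kernel_length=8)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ConfigurationError):
            SnakeKernelSpec(axis="y", in_channels=1, out_channels=1, max_step=0.0)

    def test_bad_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            SnakeKernelSpec(axis="z", in_channels=1, out_channels=1)


class TestPredictOffsets:
    def test_zero_initialized_head_gives_straight_path(self, spec, rng):
        layer = DynamicSnakeConv(spec, rng)
        x = Tensor(rng.standard_normal((2, 2, 10, 10)).astype(np.float32))
        off = layer.predict_offsets(x)
        assert np.all(off.offsets.data == 0.0)

    def test_center_tap_anchored_and_steps_bounded(self, spec, rng):
        layer = DynamicSnakeConv(spec, rng)
        # randomize the head so offsets are nonzero
        layer.offset_head.weight.data = rng.standard_normal(layer.offset_head.weight.shape).astype(np.float32)
        x = Tensor(rng.standard_normal((1, 2, 12, 12)).astype(np.float32))
        off = layer.predict_offsets(x).offsets.data
        K = spec.kernel_length
        c = K // 2
        assert np.all(off[:, c] == 0.0)
        steps = np.abs(np.diff(off, axis=1))
        assert steps.max() <= spec.max_step + 1e-6

    def test_channel_mismatch_raises(self, spec, rng):
        layer = DynamicSnakeConv(spec, rng)
        with pytest.raises(ConfigurationError):
            predict_offsets(np.zeros((1, 5, 8, 8), dtype=np.float32), spec, layer.offset_head)


class TestSampleBilinear:
    def test_integer_coordinates_identity(self, rng):
        x = rng.standard_normal((1, 1, 6, 6)).astype(np.float32)
        rows = np.array([[0.0, 3.0, 5.0]], dtype=np.float32)
        cols = np.array([[0.0, 2.0, 5.0]], dtype=np.float32)
        v = sample_bilinear(x, rows, cols).data[0, 0]
        np.testing.assert_allclose(v, x[0, 0][rows[0].astype(int), cols[0].astype(int)])

    def test_horizontal_midpoint_averages(self):
        x = np.zeros((1, 1, 1, 2), dtype=np.float32)
        x[0, 0, 0, 1] = 1.0
        v = sample_bilinear(x, np.array([[0.0]]), np.array([[0.5]]))
        assert v.data[0, 0, 0] == pytest.approx(0.5)

    def test_matches_naive_four_neighbor_oracle(self, rng):
        x = rng.standard_normal((1, 1, 8, 8)).astype(np.float64)
        rows = rng.uniform(0, 7, (1, 100))
        cols = rng.uniform(0, 7, (1, 100))
        got = sample_bilinear(x, rows, cols).data[0, 0]
        img = x[0, 0]
        for i, (r, c) in enumerate(zip(rows[0], cols[0])):
            r0, c0 = min(int(np.floor(r)), 6), min(int(np.floor(c)), 6)
            fr, fc = r - r0, c - c0
            want = (
                img[r0, c0] * (1 - fr) * (1 - fc)
                + img[r0, c0 + 1] * (1 - fr) * fc
                + img[r0 + 1, c0] * fr * (1 - fc)
                + img[r0 + 1, c0 + 1] * fr * fc
            )
            assert got[i] == pytest.approx(want, abs=1e-6)

    def test_out_of_range_clamps_to_border(self):
        x = np.arange(9, dtype=np.float32).reshape(1, 1, 3, 3)
        v = sample_bilinear(x, np.array([[-5.0, 10.0]]), np.array([[0.0, 2.0]]))
        np.testing.assert_allclose(v.data[0, 0], [0.0, 8.0])

    def test_nonfinite_coordinates_rejected(self):
        x = np.zeros((1, 1, 3, 3), dtype=np.float32)
        with pytest.raises(ValueError):
            sample_bilinear(x, np.array([[np.nan]]), np.array([[0.0]]))


class TestSnakeConvolve:
    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_zero_offsets_reduce_to_standard_convolution(self, axis, rng):
        spec = SnakeKernelSpec(axis=axis, in_channels=2, out_channels=3)
        layer = DynamicSnakeConv(spec, rng)
        x = Tensor(rng.standard_normal((2, 2, 14, 14)).astype(np.float32))
        out = layer(x).data
        kshape = (1, 9) if axis == "x" else (9, 1)
        ref = np.zeros_like(out)
        for n in range(2):
            for o in range(3):
                for c in range(2):
                    ref[n, o] += ndimage.correlate(
                        x.data[n, c].astype(np.float64),
                        layer.weight.data[o, c].reshape(kshape),
                        mode="nearest",
                    )
        assert np.abs(out - ref).max() < 1e-5

    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_random_offsets_match_naive_gather_oracle(self, axis, rng):
        spec = SnakeKernelSpec(axis=axis, in_channels=1, out_channels=1)
        layer = DynamicSnakeConv(spec, rng)
        layer.offset_head.weight.data = (
            rng.standard_normal(layer.offset_head.weight.shape).astype(np.float32) * 0.5
        )
        x = Tensor(rng.standard_normal((1, 1, 12, 12)).astype(np.float32))
        off = layer.predict_offsets(x)
        out = snake_convolve(x, spec, off, layer.weight).data[0, 0]
        w = layer.weight.data[0, 0]
        o = off.offsets.data[0]
        img = x.data[0, 0].astype(np.float64)
        for r in range(12):
            for c in range(12):
                acc = 0.0
                for k in range(9):
                    if axis == "x":
                        rr = np.clip(r + o[k, r, c], 0, 11)
                        cc = np.clip(c + k - 4, 0, 11)
                    else:
                        rr = np.clip(r + k - 4, 0, 11)
                        cc = np.clip(c + o[k, r, c], 0, 11)
                    r0, c0 = min(int(np.floor(rr)), 10), min(int(np.floor(cc)), 10)
                    fr, fc = rr - r0, cc - c0
                    v = (
                        img[r0, c0] * (1 - fr) * (1 - fc)
                        + img[r0, c0 + 1] * (1 - fr) * fc
                        + img[r0 + 1, c0] * fr * (1 - fc)
                        + img[r0 + 1, c0 + 1] * fr * fc
                    )
                    acc += w[k] * v
                assert out[r, c] == pytest.approx(acc, abs=1e-4)

    def test_spatial_size_preserved(self, spec, rng):
        layer = DynamicSnakeConv(spec, rng)
        for h, w in [(7, 11), (16, 16), (9, 33)]:
            x = Tensor(rng.standard_normal((1, 2, h, w)).astype(np.float32))
            assert layer(x).shape == (1, 3, h, w)

    def test_gradients_reach_weights_and_offset_head(self, spec, rng):
        layer = DynamicSnakeConv(spec, rng)
        x = Tensor(rng.standard_normal((2, 2, 10, 10)).astype(np.float32))
        out = layer(x)
        (out * out).sum().backward()
        for name, p in layer.named_parameters():
            assert p.grad is not None and np.linalg.norm(p.grad) > 0, name

    def test_offset_shape_mismatch_rejected(self, spec, rng):
        layer = DynamicSnakeConv(spec, rng)
        x = Tensor(rng.standard_normal((1, 2, 8, 8)).astype(np.float32))
        off = layer.predict_offsets(x)
        bad = Tensor(rng.standard_normal((1, 2, 6, 6)).astype(np.float32))
        with pytest.raises(ConfigurationError):
            snake_convolve(bad, spec, off, layer.weight)
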