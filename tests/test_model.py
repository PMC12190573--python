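import numpy as np
import pytest

from liunet.model import (ArchitectureConfig, InceptionBlockConfig, LIUNet,
                          build_inception_block, build_liunet,
                          count_parameters, estimate_flops, summarize)
from liunet.nn import Adam, BatchNorm3d, Conv3d, Sequential
from liunet.objectives import combined_loss_and_grad

BASELINE_UNET_PARAMS = 19_060_000  # published parameter count of the 3D U-Net baseline


def _block_param_count(cin: int, b: InceptionBlockConfig) -> int:
    """Independent layer-walk count: bias-free convs + 2 BN scalars/channel."""
    p1 = cin * b.c1 + 2 * b.c1
    p3 = (cin * b.reduce3 + 2 * b.reduce3
          + 27 * b.reduce3 * b.c3 + 2 * b.c3)
    p5 = (cin * b.reduce5 + 2 * b.reduce5
          + 125 * b.reduce5 * b.c5 + 2 * b.c5)
    return p1 + p3 + p5


def analytic_param_count(cfg: ArchitectureConfig) -> int:
    """Analytic oracle for the whole network, independent of the layer code."""
    widths = [b.out_channels for b in cfg.level_blocks]
    total = 0
    cin = cfg.in_channels
    for b in cfg.level_blocks:
        total += _block_param_count(cin, b)
        cin = b.out_channels
    below = widths[-1]
    for lvl in range(cfg.depth - 2, -1, -1):
        target = widths[lvl]
        if cfg.upsample_mode == "transposed":
            total += below * (8 * target) + 2 * target
        else:
            total += below * target + 2 * target
        total += _block_param_count(2 * target, cfg.level_blocks[lvl])
        below = widths[lvl]
    total += below * cfg.n_classes + cfg.n_classes  # head conv with bias
    return total


class TestInceptionBlock:
    def test_hand_counted_parameters(self):
        """c1=4, r3=4, c3=8, r5=2, c5=4 at 4 input channels: 24+904+1020."""
        cfg = InceptionBlockConfig(c1=4, c3=8, c5=4, reduce3=4, reduce5=2)
        block = build_inception_block(cfg, in_channels=4)
        assert count_parameters(block) == 1948

    def test_concatenation_and_same_padding(self, rng):
        cfg = InceptionBlockConfig(c1=8, c3=16, c5=8, reduce3=4, reduce5=4)
        block = build_inception_block(cfg, in_channels=4)
        out = block.forward(rng.random((1, 6, 6, 6, 4), dtype=np.float32))
        assert out.shape == (1, 6, 6, 6, 32)

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError):
            InceptionBlockConfig(c1=0, c3=8, c5=4, reduce3=4, reduce5=2)


class TestParameterCounting:
    def test_single_conv_bn_hand_count(self, rng):
        net = Sequential(Conv3d(4, 4, 1, rng), BatchNorm3d(4))
        assert sum(p.size for p in net.parameters()) == 24

    def test_default_network_below_baseline(self):
        n = count_parameters(build_liunet())
        assert n < BASELINE_UNET_PARAMS
        assert n == analytic_param_count(ArchitectureConfig())

    @pytest.mark.parametrize("mode", ["nearest_conv", "transposed"])
    def test_oracle_on_randomized_configs(self, mode):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            widths = [int(w) for w in rng.integers(4, 17, size=rng.integers(2, 6))]
            cfg = ArchitectureConfig.from_widths(widths, upsample_mode=mode)
            assert count_parameters(build_liunet(cfg)) == analytic_param_count(cfg)

    def test_count_independent_of_input_size(self, tiny_arch, rng):
        model = build_liunet(tiny_arch)
        before = count_parameters(model)
        model.forward(rng.random((1, 16, 16, 16, 4), dtype=np.float32))
        model.forward(rng.random((1, 32, 16, 16, 4), dtype=np.float32))
        assert count_parameters(model) == before


class TestForward:
    def test_softmax_head_sums_to_one(self, tiny_arch, rng):
        model = build_liunet(tiny_arch, seed=3)
        out = model.forward(rng.random((1, 16, 16, 16, 4), dtype=np.float32))
        assert out.shape == (1, 16, 16, 16, 4)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-5)

    def test_indivisible_shape_rejected(self, tiny_arch):
        model = build_liunet(tiny_arch)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 30, 30, 30, 4), dtype=np.float32))

    def test_transposed_upsampling_mode(self, rng):
        cfg = ArchitectureConfig.from_widths((4, 8, 16, 32, 32),
                                             upsample_mode="transposed")
        out = build_liunet(cfg).forward(rng.random((1, 16, 16, 16, 4),
                                                   dtype=np.float32))
        assert out.shape == (1, 16, 16, 16, 4)

    def test_seeded_construction_is_deterministic(self, tiny_arch, rng):
        x = rng.random((1, 16, 16, 16, 4), dtype=np.float32)
        a = build_liunet(tiny_arch, seed=7).forward(x)
        b = build_liunet(tiny_arch, seed=7).forward(x)
        np.testing.assert_array_equal(a, b)


class TestFlops:
    def test_scales_linearly_with_voxel_count(self, tiny_arch):
        model = build_liunet(tiny_arch)
        f16 = estimate_flops(model, (16, 16, 16))
        f32 = estimate_flops(model, (32, 32, 32))
        assert f32 == pytest.approx(8 * f16)

    def test_default_magnitude_is_plausible(self):
        # loose scale check only; the convention is framework-dependent
        g = estimate_flops(build_liunet(), (128, 128, 128))
        assert 10.0 < g < 1000.0


class TestEndToEndGradients:
    def test_one_step_decreases_combined_loss(self, tiny_arch, rng):
        model = build_liunet(tiny_arch, seed=5)
        x = rng.random((1, 16, 16, 16, 4), dtype=np.float32)
        labels = rng.integers(0, 4, (1, 16, 16, 16))
        g = np.eye(4, dtype=np.float32)[labels]
        opt = Adam(model.parameters(), lr=1e-3)
        p = model.forward(x, training=True)
        l0, grad = combined_loss_and_grad(p, g)
        opt.zero_grad()
        model.backward(grad.astype(np.float32))
        opt.step()
        l1, _ = combined_loss_and_grad(model.forward(x, training=True), g)
        assert l1 < l0

    def test_weight_gradients_match_finite_differences(self, rng):
        cfg = ArchitectureConfig.from_widths((4, 4))  # depth 2: cheap exact FD
        model = build_liunet(cfg, seed=9)
        for p in model.parameters():  # float64 so the FD step is clean
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        x = rng.random((1, 4, 4, 4, 4))
        labels = rng.integers(0, 4, (1, 4, 4, 4))
        g = np.eye(4)[labels]

        def loss():
            return combined_loss_and_grad(model.forward(x, training=True), g)

        l0, dp = loss()
        for p in model.parameters():
            p.zero_grad()
        model.backward(dp)
        checked = 0
        fd_rng = np.random.default_rng(0)
        for p in model.parameters():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in fd_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()[0]
                flat[idx] = orig - eps
                lm = loss()[0]
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(gflat[idx], rel=2e-2, abs=2e-5)
                checked += 1
        assert checked >= 20


def test_summarize_consistency():
    s = summarize(input_shape=(32, 32, 32))
    assert s.param_millions == pytest.approx(s.param_count / 1e6)
    assert s.output_shape == (32, 32, 32, 4)
    assert s.approx_gflops > 0
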