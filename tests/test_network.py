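"""Network architecture: GHIN semantics, Ghost/SE blocks, generator and
double-scale critics, parameter accounting, autodiff correctness."""

import numpy as np
import pytest

from aggdeblur.autograd import Tensor
from aggdeblur.discriminator import (DiscriminatorConfig,
                                     build_double_scale_discriminator)
from aggdeblur.generator import (AggGenerator, GeneratorConfig, TINY_CONFIG,
                                 build_generator)
from aggdeblur.nn import (Conv2d, GHIN, GhostModule, SEBlock, count_parameters)

RNG = np.random.default_rng(42)


class TestGHIN:
    @pytest.mark.parametrize("shape", [(1, 2, 4, 4), (2, 8, 5, 7),
                                       (1, 16, 8, 8), (3, 5, 6, 6)])
    def test_initialization_is_identity(self, shape):
        """With alpha=1, gamma=0, beta=0 the gate S vanishes and the block
        passes any input through unchanged."""
        ghin = GHIN(shape[1])
        x = RNG.standard_normal(shape).astype(np.float32)
        out = ghin(Tensor(x))
        assert np.abs(out.data - x).max() < 1e-12

    def test_hand_evaluated_gate(self):
        """One normalized channel [[1,3],[1,3]]: mu=2, var=1, x_norm=+-1,
        S=x_norm, y=(1+S)*x = [[0,6],[0,6]]."""
        ghin = GHIN(2, eps=1e-12)
        ghin.gamma.data[:] = 1.0
        x = np.zeros((1, 2, 2, 2), np.float32)
        x[0, 0] = [[1, 3], [1, 3]]
        x[0, 1] = [[5, -2], [0.5, 9]]
        out = ghin(Tensor(x)).data
        assert np.abs(out[0, 0] - [[0, 6], [0, 6]]).max() < 1e-4
        # preserved half passes through bit-identically
        assert np.array_equal(out[0, 1], x[0, 1])

    def test_preserved_channels_untouched(self):
        ghin = GHIN(4)
        ghin.gamma.data[:] = 0.7  # make the normalized path non-trivial
        x = RNG.standard_normal((2, 4, 6, 6)).astype(np.float32)
        out = ghin(Tensor(x)).data
        assert np.array_equal(out[:, 2:4], x[:, 2:4])

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            GHIN(1)

    def test_channel_mismatch_rejected(self):
        ghin = GHIN(4)
        with pytest.raises(ValueError, match="channels"):
            ghin(Tensor(np.zeros((1, 6, 4, 4), np.float32)))


class TestGhost:
    def test_se_neutral_element(self):
        """Forcing unit excitation reduces Attention-Ghost to the plain
        Ghost concat-then-crop pipeline exactly."""
        rng = np.random.default_rng(0)
        block = GhostModule(16, 16, use_se=True, rng=rng)
        rng2 = np.random.default_rng(0)
        plain = GhostModule(16, 16, use_se=False, rng=rng2)
        # identical primary/cheap weights by construction (same rng stream);
        # align explicitly to be safe
        plain.primary.weight.data = block.primary.weight.data.copy()
        plain.primary.bias.data = block.primary.bias.data.copy()
        plain.cheap.weight.data = block.cheap.weight.data.copy()
        plain.cheap.bias.data = block.cheap.bias.data.copy()

        class UnitSE:
            def __call__(self, x):
                return x

        block.se = UnitSE()
        x = Tensor(RNG.random((1, 16, 8, 8), np.float32))
        assert np.array_equal(block(x).data, plain(x).data)

    def test_output_shape(self):
        block = GhostModule(16, 16, rng=np.random.default_rng(1))
        out = block(Tensor(np.random.rand(1, 16, 8, 8).astype(np.float32)))
        assert out.shape == (1, 16, 8, 8)

    def test_parameter_count_closed_form(self):
        """Closed-form count (primary conv + depthwise + SE bottleneck)
        against direct enumeration of trainable arrays."""
        in_ch, out_ch, ratio, k, dw, red = 24, 32, 2, 3, 3, 4
        block = GhostModule(in_ch, out_ch, ratio=ratio, primary_kernel=k,
                            dw_kernel=dw, se_reduction=red,
                            rng=np.random.default_rng(2))
        init = out_ch // ratio
        cat = init * ratio
        hidden = cat // red
        expected = (k * k * in_ch * init + init          # primary conv + bias
                    + dw * dw * init + init              # depthwise + bias
                    + cat * hidden + hidden              # SE squeeze
                    + hidden * cat + cat)                # SE excite
        assert count_parameters(block) == expected


class TestGenerator:
    def test_shape_preserving(self):
        gen = build_generator(TINY_CONFIG)
        x = np.random.rand(1, 3, 64, 64).astype(np.float32)
        out = gen.forward(x)
        assert out.shape == (1, 3, 64, 64)
        assert np.isfinite(out.data).all()

    def test_non_multiple_of_stride_padded(self):
        gen = build_generator(TINY_CONFIG)
        x = np.random.rand(1, 3, 50, 70).astype(np.float32)
        out = gen.forward(x)
        assert out.shape == (1, 3, 50, 70)

    def test_zeroed_projection_is_identity(self):
        gen = build_generator(TINY_CONFIG)
        gen.zero_output_projection()
        x = np.random.rand(2, 3, 32, 32).astype(np.float32) * 0.8 + 0.1
        out = gen.forward(x)
        assert np.abs(out.data - x).max() < 1e-7

    def test_deterministic_forward(self):
        gen = build_generator(TINY_CONFIG)
        x = np.random.rand(1, 3, 32, 32).astype(np.float32)
        assert np.array_equal(gen.forward(x).data, gen.forward(x).data)

    def test_parameter_count_near_published(self):
        gen = build_generator(GeneratorConfig())
        n = count_parameters(gen)
        assert abs(n - 1.53e6) / 1.53e6 < 0.05

    def test_single_conv_count(self):
        conv = Conv2d(3, 16, 3, rng=np.random.default_rng(0))
        assert count_parameters(conv) == 3 * 16 * 9 + 16

    def test_restore_roundtrip(self):
        gen = build_generator(TINY_CONFIG)
        img = np.random.rand(48, 48, 3)
        out = gen.restore(img)
        assert out.shape == (48, 48, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestDiscriminators:
    def test_scale_contract(self):
        g, l = build_double_scale_discriminator(DiscriminatorConfig(seed=0))
        x = np.random.rand(1, 3, 64, 64).astype(np.float32)
        sg, sl = g(x), l(x)
        assert np.isfinite(sg.data).all() and np.isfinite(sl.data).all()
        assert sl.data.shape[2] > sg.data.shape[2]

    def test_determinism(self):
        g, l = build_double_scale_discriminator(DiscriminatorConfig(seed=1))
        x = np.random.rand(2, 3, 32, 32).astype(np.float32)
        assert np.array_equal(g(x).data, g(x).data)
        assert np.array_equal(l(x).data, l(x).data)

    def test_too_small_input_rejected(self):
        g, _ = build_double_scale_discriminator()
        with pytest.raises(ValueError, match="minimum"):
            g(np.random.rand(1, 3, 16, 16).astype(np.float32))

    def test_local_receptive_field_smaller_than_image(self):
        """Gradient-support probe: one local-critic output score depends
        only on a sub-window of the image."""
        _, local = build_double_scale_discriminator(DiscriminatorConfig(seed=2))
        x = Tensor(np.random.rand(1, 3, 64, 64).astype(np.float32))
        x.requires_grad = True
        scores = local(x)
        g = np.zeros(scores.shape, np.float32)
        g[0, 0, 0, 0] = 1.0
        scores.backward(g)
        support = np.abs(x.grad).sum(axis=(0, 1)) > 0
        assert support.sum() < 64 * 64


class TestAutogradNumerics:
    def test_gradient_check_through_generator(self):
        """Analytic gradients of the content loss through a miniature
        generator match central finite differences."""
        from aggdeblur.losses import content_loss

        cfg = GeneratorConfig(stage_widths=[4, 6, 8, 10, 12], lateral_shallow=4,
                              lateral_deep=8, head_width=4, fused_width=16,
                              decoder_mid_width=8, seed=0)
        gen = AggGenerator(cfg)
        rng = np.random.default_rng(3)
        x = rng.random((1, 3, 16, 16), np.float32) * 0.8 + 0.1
        y = rng.random((1, 3, 16, 16), np.float32) * 0.8 + 0.1

        loss = content_loss(gen.forward(x), Tensor(y))
        gen.zero_grad()
        loss.backward()
        params = dict(gen.named_parameters())
        for name in ["final.weight", "stem.weight", "lateral0.bias"]:
            p = params[name]
            idx = rng.integers(0, p.data.size)
            eps = 1e-3
            flat = p.data.ravel()
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = content_loss(gen.forward(x), Tensor(y)).item()
            flat[idx] = orig - eps
            lm = content_loss(gen.forward(x), Tensor(y)).item()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[idx]
            assert abs(num - ana) < 1e-4 + 0.05 * max(abs(num), abs(ana)), name
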