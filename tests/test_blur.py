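"""Blur synthesis: trajectory statistics, PSF construction, convolution."""

import numpy as np
import pytest

from aggdeblur import (BlurSpec, apply_motion_blur, augment_sharp,
                       build_paired_dataset, generate_synthetic_scene,
                       generate_trajectory, trajectory_to_psf)
from aggdeblur.blur import MotionTrajectory, PointSpreadFunction
from aggdeblur.routing import laplacian_variance
from conftest import make_blurred


class TestTrajectory:
    def test_cumulative_sum_identity(self):
        """Positions are partial sums of s_k * exp(i theta_k), recomputed
        here by brute force."""
        traj = generate_trajectory(BlurSpec(intensity=0.75, n_steps=200, seed=3))
        partial = np.array([np.sum(traj.steps[:j + 1] * np.exp(1j * traj.angles[:j + 1]))
                            for j in range(200)])
        assert np.abs(partial - traj.positions).max() < 1e-12
        # stepwise identity z_j - z_{j-1} = s_j e^{i theta_j}
        z = np.concatenate([[0.0 + 0j], traj.positions])
        assert np.abs(np.diff(z) - traj.steps * np.exp(1j * traj.angles)).max() < 1e-12

    def test_zero_intensity_collinear(self):
        traj = generate_trajectory(BlurSpec(intensity=0.0, n_steps=100, seed=5))
        assert np.ptp(traj.angles) == 0.0
        # all positions lie on the ray of the initial heading
        direction = np.exp(1j * traj.angles[0])
        cross = np.abs((traj.positions * direction.conjugate()).imag)
        assert cross.max() < 1e-9

    def test_seeded_determinism(self):
        spec = BlurSpec(intensity=0.6, n_steps=150, seed=7)
        a, b = generate_trajectory(spec), generate_trajectory(spec)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.steps, b.steps)

    def test_extent_bound_and_nonneg_steps(self):
        for seed in range(10):
            spec = BlurSpec(intensity=1.0, n_steps=500, seed=seed)
            traj = generate_trajectory(spec)
            assert np.abs(traj.positions).max() <= spec.max_extent + 1e-9
            assert (traj.steps >= 0).all()

    def test_intensity_monotonicity(self):
        """Mean step length and angle dispersion are non-decreasing in
        intensity (averaged over 50 seeds)."""
        intensities = [0.0, 0.25, 0.5, 0.75, 1.0]
        mean_steps, mean_turns = [], []
        for it in intensities:
            s_acc, t_acc = [], []
            for seed in range(50):
                tr = generate_trajectory(BlurSpec(intensity=it, n_steps=200, seed=seed))
                s_acc.append(tr.steps.mean())
                t_acc.append(np.abs(np.diff(tr.angles)).mean() if it > 0 else 0.0)
            mean_steps.append(np.mean(s_acc))
            mean_turns.append(np.mean(t_acc))
        assert all(b >= a - 1e-12 for a, b in zip(mean_steps, mean_steps[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(mean_turns, mean_turns[1:]))

    @pytest.mark.parametrize("bad", [
        dict(intensity=1.5), dict(intensity=float("nan")), dict(n_steps=0),
        dict(kernel_size=8), dict(kernel_size=1), dict(smoothing_sigma=-1.0),
        dict(max_extent=-3.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            BlurSpec(**bad)


class TestPSF:
    def test_single_point_is_delta(self):
        traj = MotionTrajectory(positions=np.array([0.0 + 0j]),
                                steps=np.array([0.0]), angles=np.array([0.0]),
                                intensity=0.0)
        psf = trajectory_to_psf(traj, 7, smoothing_sigma=0.0)
        expected = np.zeros((7, 7))
        expected[3, 3] = 1.0
        assert np.allclose(psf.kernel, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_unit_mass(self, seed):
        traj = generate_trajectory(BlurSpec(intensity=0.7, n_steps=300, seed=seed))
        psf = trajectory_to_psf(traj, 31, 1.0)
        assert abs(psf.kernel.sum() - 1.0) < 1e-9
        assert (psf.kernel >= 0).all()

    def test_horizontal_line_mass_in_central_row(self):
        """A straight horizontal path rasterizes onto the central row,
        cross-checked against an independent line raster."""
        n = 7
        steps = np.full(n, 6.0 / n)
        angles = np.zeros(n)
        positions = np.cumsum(steps * np.exp(1j * angles))
        traj = MotionTrajectory(positions, steps, angles, 0.0)
        psf = trajectory_to_psf(traj, 15, smoothing_sigma=0.0)
        centre = (15 - 1) // 2
        central_mass = psf.kernel[centre].sum()
        assert central_mass >= 0.95
        # independent oracle: centred samples all have zero imaginary part
        centred = positions - positions.mean()
        assert np.abs(centred.imag).max() < 1e-12

    def test_extent_error_names_required_size(self):
        traj = generate_trajectory(BlurSpec(intensity=0.3, n_steps=100, seed=0,
                                            kernel_size=31))
        with pytest.raises(ValueError, match="required"):
            trajectory_to_psf(traj, 3, 0.0)


class TestApplyBlur:
    def test_delta_psf_is_identity(self, scene64):
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        out = apply_motion_blur(scene64, PointSpreadFunction(delta))
        assert np.allclose(out, scene64, atol=1e-12)

    def test_constant_image_fixed_point(self):
        const = np.full((32, 32, 3), 0.37)
        traj = generate_trajectory(BlurSpec(intensity=0.8, n_steps=200, seed=2,
                                            kernel_size=11))
        psf = trajectory_to_psf(traj, 11, 1.0)
        out = apply_motion_blur(const, psf)
        assert np.allclose(out, const, atol=1e-12)

    def test_matches_dense_convolution(self):
        """Reflective-boundary channel convolution agrees with a naive
        O(n^2 k^2) direct implementation."""
        rng = np.random.default_rng(0)
        img = rng.random((32, 32, 3))
        k = rng.random((5, 5))
        k /= k.sum()
        out = apply_motion_blur(img, PointSpreadFunction(k))

        pad = 2
        expected = np.empty_like(img)
        for c in range(3):
            p = np.pad(img[..., c], pad, mode="symmetric")
            for i in range(32):
                for j in range(32):
                    acc = 0.0
                    for u in range(5):
                        for v in range(5):
                            acc += k[u, v] * p[i + 4 - u, j + 4 - v]
                    expected[i, j, c] = acc
        assert np.abs(out - np.clip(expected, 0, 1)).max() < 1e-6

    def test_mean_preserved_on_texture(self, scene64):
        k = np.full((9, 9), 1.0 / 81)
        out = apply_motion_blur(scene64, PointSpreadFunction(k))
        for c in range(3):
            assert abs(out[..., c].mean() - scene64[..., c].mean()) < 1e-3

    def test_psf_larger_than_image_rejected(self):
        img = np.zeros((8, 8, 3))
        k = np.full((11, 11), 1.0 / 121)
        with pytest.raises(ValueError, match="larger"):
            apply_motion_blur(img, PointSpreadFunction(k))


class TestAugment:
    def test_flip_is_exact_mirror(self):
        img = np.zeros((2, 2, 3))
        img[0, 0] = 1.0
        variants = augment_sharp(img, seed=0)
        assert np.array_equal(variants[0], img[:, ::-1])

    def test_brightness_identity_factor(self, scene64):
        out = augment_sharp(scene64, seed=0, brightness_range=(1.0, 1.0))[2]
        assert np.allclose(out, scene64)

    def test_three_variants_per_image(self, scene64):
        variants = augment_sharp(scene64, seed=1)
        assert len(variants) == 3
        for v in variants:
            assert v.shape == scene64.shape
            assert v.min() >= 0 and v.max() <= 1


class TestPairedDataset:
    def test_split_counts_at_full_scale_ratio(self):
        from aggdeblur.blur import _split_counts
        assert _split_counts(4000, (0.8, 0.1, 0.1)) == (3200, 400, 400)
        assert _split_counts(10, (0.8, 0.1, 0.1)) == (8, 1, 1)

    def test_partition_and_determinism(self, scene_batch):
        imgs = scene_batch[:10]
        kw = dict(intensities=[0.5], ratios=(0.8, 0.1, 0.1), seed=4,
                  spec_kwargs={"n_steps": 100, "kernel_size": 11})
        m1, pairs1 = build_paired_dataset(imgs, **kw)
        m2, _ = build_paired_dataset(imgs, **kw)
        assert m1.entries == m2.entries
        ids = [pid for pid, _ in m1.entries]
        assert sorted(ids) == sorted(pairs1)
        assert len(set(ids)) == len(ids)  # no id in two splits
        assert len(m1.split("train")) == 8
        assert len(m1.split("val")) == 1
        assert len(m1.split("test")) == 1
        for pid, pair in pairs1.items():
            assert pair.sharp.shape == pair.blurred.shape
            assert pair.blurred.min() >= 0 and pair.blurred.max() <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_paired_dataset([])


class TestSyntheticScene:
    def test_deterministic_and_in_range(self):
        a = generate_synthetic_scene(64, 64, seed=0)
        b = generate_synthetic_scene(64, 64, seed=0)
        assert np.array_equal(a, b)
        c = generate_synthetic_scene(128, 128, seed=1)
        assert c.min() >= 0.0 and c.max() <= 1.0

    def test_sharper_than_its_blur(self):
        for seed in range(5):
            scene = generate_synthetic_scene(64, 64, seed=seed)
            blurred = make_blurred(scene, 0.5, seed=seed)
            assert laplacian_variance(scene) > laplacian_variance(blurred)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="32"):
            generate_synthetic_scene(16, 64, seed=0)
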