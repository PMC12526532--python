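"""Motion-blur synthesis from simulated camera trajectories.

A blur kernel is built in three steps: (1) a random walk in the complex
plane, ``z_j = sum_{k<=j} s_k * exp(i*theta_k)``, whose step-length and
turning-angle statistics are controlled by a scalar blur intensity in
[0, 1]; (2) sub-pixel rasterization of the walk onto a square grid followed
by Gaussian smoothing, giving a unit-mass point spread function; (3)
per-channel convolution of the PSF with a sharp RGB image.

Intensity 0 produces a near-straight path (mild, directional blur);
intensity 1 produces a highly random path (complex, smeared blur).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "BlurSpec", "MotionTrajectory", "PointSpreadFunction", "SharpBlurPair",
    "DatasetManifest", "generate_trajectory", "trajectory_to_psf",
    "apply_motion_blur", "augment_sharp", "build_paired_dataset", "blur_image",
]


@dataclass(frozen=True)
class BlurSpec:
    """Parameters of one synthetic motion blur.

    intensity        blur intensity in [0, 1]: path complexity control
    n_steps          number of trajectory steps N
    kernel_size      odd side length of the rasterized PSF, pixels
    smoothing_sigma  Gaussian smoothing width applied to the raster, pixels
    max_extent       bound on |z_j|, pixels (trajectory is rescaled into it)
    seed             RNG seed
    """

    intensity: float = 0.5
    n_steps: int = 2000
    kernel_size: int = 31
    smoothing_sigma: float = 1.0
    max_extent: float = None
    seed: int = 0

    def __post_init__(self):
        if self.max_extent is None:
            object.__setattr__(self, "max_extent", self.kernel_size / 2 - 2)
        if not np.isfinite(self.intensity) or not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity must be in [0, 1], got {self.intensity}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.smoothing_sigma < 0 or not np.isfinite(self.smoothing_sigma):
            raise ValueError("smoothing_sigma must be a finite non-negative real")
        if self.max_extent <= 0 or not np.isfinite(self.max_extent):
            raise ValueError("max_extent must be a finite positive real")


@dataclass
class MotionTrajectory:
    positions: np.ndarray  # complex128, length N
    steps: np.ndarray      # float64, length N, >= 0
    angles: np.ndarray     # float64, length N, radians
    intensity: float


@dataclass
class PointSpreadFunction:
    kernel: np.ndarray     # square, odd side, non-negative, unit mass

    def __post_init__(self):
        k = self.kernel
        if k.ndim != 2 or k.shape[0] != k.shape[1] or k.shape[0] % 2 == 0:
            raise ValueError("PSF kernel must be square with odd side length")
        if (k < 0).any():
            raise ValueError("PSF kernel must be non-negative")
        if abs(float(k.sum()) - 1.0) > 1e-9:
            raise ValueError("PSF kernel must sum to 1")


@dataclass
class SharpBlurPair:
    sharp: np.ndarray      # HWC float in [0, 1]
    blurred: np.ndarray
    spec: BlurSpec


@dataclass
class DatasetManifest:
    entries: List[Tuple[str, str]]          # (pair id, split label)
    split_ratio: Tuple[float, float, float]

    def split(self, label: str) -> List[str]:
        return [pid for pid, lab in self.entries if lab == label]

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"split_ratio": list(self.split_ratio), "entries": self.entries}, indent=1))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(entries=[tuple(e) for e in d["entries"]],
                   split_ratio=tuple(d["split_ratio"]))


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def generate_trajectory(spec: BlurSpec) -> MotionTrajectory:
    """Simulate the complex-plane camera path for ``spec``.

    Step lengths are Beta-distributed with intensity-dependent shape
    (higher intensity -> longer average steps); turning-angle increments are
    uniform in ``±pi*intensity`` with an occasional sign flip that injects
    jitter.  The finished path is rescaled so that ``max |z_j|`` does not
    exceed ``spec.max_extent``, preserving the cumulative-sum identity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    it = spec.intensity

    a, b = 1.0 + 3.0 * it, 3.0 - 2.0 * it
    max_step = spec.max_extent / n * (1.0 + 4.0 * it)
    steps = rng.beta(a, b, size=n) * max_step

    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    increments = rng.uniform(-math.pi * it, math.pi * it, size=n - 1) if n > 1 else np.empty(0)
    if it > 0 and n > 1:
        flip = rng.random(n - 1) < 0.1 * it
        increments = np.where(flip, -increments, increments)
    angles = theta0 + np.concatenate([[0.0], np.cumsum(increments)])

    positions = np.cumsum(steps * np.exp(1j * angles))
    peak = float(np.abs(positions).max())
    if peak > spec.max_extent and peak > 0:
        scale = spec.max_extent / peak
        steps = steps * scale
        positions = positions * scale
    return MotionTrajectory(positions=positions, steps=steps, angles=angles,
                            intensity=it)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def trajectory_to_psf(traj: MotionTrajectory, kernel_size: int,
                      smoothing_sigma: float = 1.0) -> PointSpreadFunction:
    """Rasterize a trajectory into a unit-mass blur kernel.

    Each trajectory sample is splatted with bilinear sub-pixel weights onto
    a ``kernel_size``-square grid centred on the trajectory centroid, the
    raster is Gaussian-smoothed, and the result renormalized to unit mass.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 3")
    pos = traj.positions - traj.positions.mean()
    half = (kernel_size - 1) / 2
    extent = float(np.max(np.abs(np.concatenate([pos.real, pos.imag])))) if pos.size else 0.0
    if extent > half:
        needed = 2 * math.ceil(extent) + 1
        raise ValueError(
            f"trajectory extent {extent:.2f}px exceeds kernel half-size {half:.1f}; "
            f"a kernel of at least {needed}x{needed} is required")

    grid = np.zeros((kernel_size, kernel_size), dtype=np.float64)
    xs = pos.real + half
    ys = pos.imag + half
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    for dy, dx, wgt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                        (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy = np.clip(y0 + dy, 0, kernel_size - 1)
        xx = np.clip(x0 + dx, 0, kernel_size - 1)
        np.add.at(grid, (yy, xx), wgt)

    if smoothing_sigma > 0:
        grid = ndimage.gaussian_filter(grid, smoothing_sigma, mode="constant")
    total = grid.sum()
    if total <= 0:
        raise ValueError("empty rasterized trajectory")
    return PointSpreadFunction(kernel=grid / total)


def apply_motion_blur(image: np.ndarray, psf: PointSpreadFunction) -> np.ndarray:
    """Convolve each RGB channel with the PSF (reflective boundary).

    Unit PSF mass plus reflective padding makes constant images exact fixed
    points and preserves image means up to boundary effects.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HWC RGB image")
    k = psf.kernel
    if k.shape[0] > image.shape[0] or k.shape[1] > image.shape[1]:
        raise ValueError(
            f"PSF {k.shape} larger than image plane {image.shape[:2]}")
    out = np.empty_like(image)
    for c in range(3):
        out[..., c] = ndimage.convolve(image[..., c], k, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def blur_image(image: np.ndarray, spec: BlurSpec) -> np.ndarray:
    """Convenience: trajectory -> PSF -> convolution for one image."""
    traj = generate_trajectory(spec)
    psf = trajectory_to_psf(traj, spec.kernel_size, spec.smoothing_sigma)
    return apply_motion_blur(image, psf)


# ---------------------------------------------------------------------------
# augmentation and dataset pairing
# ---------------------------------------------------------------------------

def augment_sharp(image: np.ndarray, seed: int = 0,
                  rotation_range: float = 15.0,
                  brightness_range: Tuple[float, float] = (0.7, 1.3)) -> List[np.ndarray]:
    """Return three augmented variants: horizontal flip, random rotation
    (reflective fill) and brightness scaling — tripling each sharp source.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flipped = image[:, ::-1].copy()
    angle = rng.uniform(-rotation_range, rotation_range)
    rotated = ndimage.rotate(image, angle, axes=(0, 1), reshape=False,
                             mode="reflect", order=1)
    factor = rng.uniform(*brightness_range)
    brightened = np.clip(image * factor, 0.0, 1.0)
    return [flipped, np.clip(rotated, 0.0, 1.0), brightened]


def _split_counts(n: int, ratios: Sequence[float]) -> Tuple[int, int, int]:
    r0, r1, r2 = ratios
    n_train = int(round(r0 * n))
    n_val = int(round(r1 * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def build_paired_dataset(sharp_images: Sequence[np.ndarray],
                         intensities: Sequence[float] = (0.25, 0.5, 0.75),
                         ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                         seed: int = 0,
                         spec_kwargs: dict = None):
    """Blur every sharp image and partition pairs into train/val/test.

    Each sharp image receives one blurred counterpart whose intensity cycles
    through ``intensities``.  Returns ``(manifest, pairs)`` where ``pairs``
    maps pair identifiers to :class:`SharpBlurPair`.
    """
    if not len(sharp_images):
        raise ValueError("empty dataset: need at least one sharp image")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    spec_kwargs = dict(spec_kwargs or {})
    spec_kwargs.setdefault("kernel_size", 31)

    pairs = {}
    ids = []
    for i, img in enumerate(sharp_images):
        it = float(intensities[i % len(intensities)])
        spec = BlurSpec(intensity=it, seed=seed + 7919 * i, **spec_kwargs)
        pid = f"pair_{i:05d}"
        pairs[pid] = SharpBlurPair(sharp=np.asarray(img, dtype=np.float64),
                                   blurred=blur_image(img, spec), spec=spec)
        ids.append(pid)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train, n_val, n_test = _split_counts(len(ids), ratios)
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    entries = sorted(
        (ids[j], labels[k]) for k, j in enumerate(order))
    manifest = DatasetManifest(entries=entries, split_ratio=tuple(ratios))
    return manifest, pairs
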