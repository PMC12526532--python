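"""Synthetic orchard-like scene generator (test fixture stand-in).

Produces deterministic RGB scenes that emulate the salient structures of
orchard imagery: a textured foliage-like background, disc-shaped fruit
regions, elongated branch strokes and one high-frequency glyph block
(signage analogue).  These are synthetic fixtures — they share the relevant
statistics (edges, texture, discs) with real orchard photographs but none
of their semantics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["generate_synthetic_scene"]


def _disc_mask(h, w, cy, cx, r):
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def generate_synthetic_scene(width: int, height: int, seed: int = 0) -> np.ndarray:
    """Return an HWC RGB image in [0, 1] with fruit/branch/signage analogues."""
    if width < 32 or height < 32:
        raise ValueError(f"scene must be at least 32x32, got {width}x{height}")
    rng = np.random.default_rng(seed)
    h, w = height, width

    # foliage-like background: coarse + fine band-passed noise, greenish
    coarse = ndimage.gaussian_filter(rng.random((h, w)), 3.0)
    fine = ndimage.gaussian_filter(rng.random((h, w)), 0.6)
    lum = 0.35 + 0.3 * (coarse - coarse.mean()) + 0.35 * (fine - fine.mean())
    img = np.stack([0.35 * lum + 0.1, 0.75 * lum + 0.15, 0.3 * lum + 0.08], axis=-1)

    # fruit analogues: >= 3 shaded discs in warm hues
    n_discs = 3 + int(rng.integers(0, 3))
    rmax = max(3, min(h, w) // 8)
    for _ in range(n_discs):
        r = int(rng.integers(max(2, rmax // 2), rmax + 1))
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        mask = _disc_mask(h, w, cy, cx, r)
        yy, xx = np.mgrid[0:h, 0:w]
        shade = np.clip(1.0 - 0.5 * np.hypot(yy - cy + r / 3, xx - cx - r / 3) / r, 0.3, 1.0)
        img[mask, 0] = (0.95 * shade)[mask]
        img[mask, 1] = (0.55 * shade)[mask]
        img[mask, 2] = (0.12 * shade)[mask]

    # branch analogues: elongated dark strokes
    for _ in range(2 + int(rng.integers(0, 3))):
        y0, x0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.4, 0.9) * min(h, w)
        t = np.linspace(0, 1, int(length * 4))
        ys = np.clip(y0 + t * length * np.sin(ang), 0, h - 1).astype(int)
        xs = np.clip(x0 + t * length * np.cos(ang), 0, w - 1).astype(int)
        for dy in (-1, 0):
            for dx in (-1, 0):
                img[np.clip(ys + dy, 0, h - 1), np.clip(xs + dx, 0, w - 1)] = (
                    0.25, 0.15, 0.08)

    # signage analogue: high-frequency binary glyph block
    bh, bw = max(8, h // 6), max(8, w // 6)
    by = int(rng.integers(0, h - bh))
    bx = int(rng.integers(0, w - bw))
    glyph = (rng.random(((bh + 1) // 2, (bw + 1) // 2)) > 0.5).astype(float)
    glyph = glyph.repeat(2, axis=0).repeat(2, axis=1)[:bh, :bw]
    block = 0.15 + 0.8 * glyph
    img[by:by + bh, bx:bx + bw] = block[..., None]

    return np.clip(img, 0.0, 1.0)
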