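"""Image I/O at the package boundary: 8-bit PNG/JPEG files on disk,
float HWC arrays in [0, 1] everywhere inside."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image"]


def read_image(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(path, image: np.ndarray):
    data = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(Path(path), (data * 255.0 + 0.5).astype(np.uint8))
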