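"""Blur-aware dynamic routing: variance-of-Laplacian sharpness estimation
and threshold dispatch between the deblurring network and a bypass.

An image with Laplacian variance ``L`` strictly below the threshold ``T``
is considered significantly blurred and routed through deblurring;
otherwise it bypasses restoration and goes straight to the downstream
consumer.  ``T`` is scene-dependent, not a universal constant: a helper
calibrates it from a sharp reference batch, and it is always overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = ["RoutingDecision", "laplacian_variance", "route", "process",
           "calibrate_threshold"]

_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass(frozen=True)
class RoutingDecision:
    sharpness: float   # L, variance of the Laplacian response
    threshold: float   # T
    route: str         # "deblur" | "bypass"

    def __post_init__(self):
        if (self.route == "deblur") != (self.sharpness < self.threshold):
            raise ValueError("route label inconsistent with L < T rule")


def laplacian_variance(image: np.ndarray) -> float:
    """Variance of the 4-neighbour Laplacian of the BT.601 luma.

    Constant images give exactly 0; the statistic is invariant to adding a
    constant and scales with the square of a contrast factor.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        if image.shape[2] != 3:
            raise ValueError("expected an RGB image")
        image = 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    resp = ndimage.convolve(image, _LAPLACIAN, mode="reflect")
    return float(resp.var())


def route(image: np.ndarray, threshold: float) -> RoutingDecision:
    """Dispatch decision for one image: deblur iff ``L < T`` (strict)."""
    if not np.isfinite(threshold) or threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    sharpness = laplacian_variance(image)
    label = "deblur" if sharpness < threshold else "bypass"
    return RoutingDecision(sharpness=sharpness, threshold=float(threshold),
                           route=label)


def process(image: np.ndarray, threshold: float,
            deblur_fn: Callable[[np.ndarray], np.ndarray],
            downstream_fn: Callable[[np.ndarray], object]):
    """Apply ``deblur_fn`` only on the deblur route, then ``downstream_fn``.

    Returns ``(downstream output, RoutingDecision)``; failures in either
    stage propagate with the decision attached to the exception.
    """
    decision = route(image, threshold)
    try:
        staged = deblur_fn(image) if decision.route == "deblur" else image
        return downstream_fn(staged), decision
    except Exception as err:
        err.routing_decision = decision
        raise


def calibrate_threshold(sharp_images: Iterable[np.ndarray],
                        blurred_images: Iterable[np.ndarray] = None,
                        percentile: float = 25.0) -> float:
    """Calibrate the dispatch threshold from reference images.

    With only a sharp reference batch, T is a low percentile of their
    Laplacian variances; note that by construction roughly that fraction of
    comparable sharp images will then fall below T and be deblurred
    needlessly (a compute cost, not an accuracy loss).  When a blurred
    reference batch is also supplied, T is placed between the two empirical
    distributions (geometric midpoint of the blurred maximum and sharp
    minimum), which separates them exactly whenever they do not overlap.
    """
    sharp_l = [laplacian_variance(img) for img in sharp_images]
    if not sharp_l:
        raise ValueError("need at least one sharp reference image")
    if blurred_images is not None:
        blur_l = [laplacian_variance(img) for img in blurred_images]
        if not blur_l:
            raise ValueError("empty blurred reference batch")
        lo, hi = max(blur_l), min(sharp_l)
        if lo >= hi:
            raise ValueError(
                "blurred and sharp Laplacian-variance distributions overlap; "
                "no separating threshold exists")
        t = float(np.sqrt(lo * hi))
    else:
        t = float(np.percentile(sharp_l, percentile))
    if t <= 0:
        raise ValueError("degenerate reference batch: non-positive threshold")
    return t
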