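"""Training objectives: weighted perceptual+L1 content loss, relativistic
average least-squares adversarial loss, and the total generator loss
``L_G = L_content + 0.005 * L_adv`` with ``L_content = 0.7*L_p + 0.3*L_1``.
"""

from __future__ import annotations

from typing import Callable, Sequence, Tuple, Union

import numpy as np

from .autograd import Tensor

__all__ = [
    "W_PERCEPTUAL", "W_L1", "W_ADV", "identity_extractor",
    "content_loss", "adversarial_losses", "total_generator_loss",
]

W_PERCEPTUAL = 0.7
W_L1 = 0.3
W_ADV = 0.005


def identity_extractor(x: Tensor) -> Tensor:
    """Pixel-space 'feature' extractor; makes L_p a plain MSE.

    Stands in for a deep perceptual backbone when pretrained weights are
    unavailable; any callable mapping an NCHW tensor to features can be
    plugged in instead.
    """
    return x


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def content_loss(pred, target,
                 feature_extractor: Callable[[Tensor], Tensor] = identity_extractor
                 ) -> Tensor:
    """``0.7 * L_p + 0.3 * L_1``: mean squared feature distance plus mean
    absolute pixel error.  Returns a scalar tensor (differentiable when the
    inputs carry gradients)."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    fp = feature_extractor(pred)
    ft = feature_extractor(target.detach())
    diff = fp - ft.detach()
    l_p = (diff * diff).mean()
    l_1 = (pred - target.detach()).abs().mean()
    return W_PERCEPTUAL * l_p + W_L1 * l_1


def _ra_ls(a: Tensor, b: Tensor) -> Tensor:
    """½[mean((a − mean(b) − 1)²) + mean((b − mean(a) + 1)²)]."""
    da = a - b.mean() - 1.0
    db = b - a.mean() + 1.0
    return 0.5 * ((da * da).mean() + (db * db).mean())


def adversarial_losses(real_scores, fake_scores) -> Tuple[Tensor, Tensor]:
    """Relativistic average least-squares GAN losses.

    ``d_loss`` drives real scores one unit above the average fake score (and
    vice versa); ``g_loss`` is the same form with roles swapped.  When lists
    of score maps from several critics are supplied the per-critic losses
    are summed.  Both losses depend only on score differences, so a shared
    shift of all scores leaves them unchanged.
    """
    if isinstance(real_scores, (list, tuple)):
        if len(real_scores) != len(fake_scores) or not real_scores:
            raise ValueError("need matching non-empty per-critic score lists")
        g_total, d_total = None, None
        for r, f in zip(real_scores, fake_scores):
            g, d = adversarial_losses(r, f)
            g_total = g if g_total is None else g_total + g
            d_total = d if d_total is None else d_total + d
        return g_total, d_total
    real, fake = _as_tensor(real_scores), _as_tensor(fake_scores)
    if real.size == 0 or fake.size == 0:
        raise ValueError("empty score arrays")
    if not (np.isfinite(real.data).all() and np.isfinite(fake.data).all()):
        raise ValueError("non-finite critic scores")
    d_loss = _ra_ls(real, fake)
    g_loss = _ra_ls(fake, real)
    return g_loss, d_loss


def total_generator_loss(content: Union[float, Tensor],
                         adv: Union[float, Tensor]) -> Union[float, Tensor]:
    """``L_G = L_content + 0.005 * L_adv``."""
    return content + W_ADV * adv
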