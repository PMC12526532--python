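"""Adversarial training of the deblurring generator.

Exposes a statsmodels-style model object: :class:`AggDeblurGAN` is built
from paired data, ``fit()`` runs the alternating 1:1 generator/critic
update loop with Adam (default moments, no weight decay, no gradient
clipping) and returns a :class:`TrainingResults` carrying the loss history,
the trained weights and a ``summary()`` table.

The learning-rate schedule holds the initial rate for the first epochs and
then decays linearly to the final rate at the last epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autograd import Tensor, no_grad
from .blur import SharpBlurPair
from .discriminator import DiscriminatorConfig, build_double_scale_discriminator
from .generator import AggGenerator, GeneratorConfig
from .losses import adversarial_losses, content_loss, identity_extractor, total_generator_loss
from .nn import Adam, count_parameters

__all__ = ["TrainConfig", "learning_rate", "AggDeblurGAN", "TrainingResults",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published schedule)."""

    lr_init: float = 1e-4
    lr_final: float = 1e-6
    decay_start_epoch: int = 10
    total_epochs: int = 200
    batch_size: int = 4
    d_steps_per_g_step: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.lr_final < self.lr_init:
            raise ValueError("lr_final must be below lr_init")
        if not 0 <= self.decay_start_epoch < self.total_epochs:
            raise ValueError("decay_start_epoch must precede total_epochs")


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at ``epoch`` (0-based start of epoch).

    Constant at ``lr_init`` through ``decay_start_epoch``, then linear to
    ``lr_final`` at ``total_epochs``; continuous at the kink and monotone
    non-increasing afterwards.
    """
    if not 0 <= epoch <= cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.total_epochs}]")
    if epoch <= cfg.decay_start_epoch:
        return cfg.lr_init
    frac = (epoch - cfg.decay_start_epoch) / (cfg.total_epochs - cfg.decay_start_epoch)
    return cfg.lr_init + frac * (cfg.lr_final - cfg.lr_init)


def _to_nchw(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float32).transpose(2, 0, 1)


class TrainingResults:
    """Outcome of a fit: per-epoch loss history plus the trained networks."""

    def __init__(self, model: "AggDeblurGAN", history: pd.DataFrame,
                 g_updates: int, d_updates: int):
        self.model = model
        self.generator = model.generator
        self.history = history
        self.g_updates = g_updates
        self.d_updates = d_updates

    @property
    def final_losses(self) -> dict:
        return self.history.iloc[-1].to_dict()

    def restore(self, image: np.ndarray) -> np.ndarray:
        """Deblur one HWC image with the trained generator."""
        return self.generator.restore(image)

    def save(self, path):
        save_checkpoint(self.generator, path)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Deblurring GAN fit",
            "=" * 46,
            f"generator parameters   {count_parameters(self.generator):>12,d}",
            f"epochs                 {len(h):>12d}",
            f"generator updates      {self.g_updates:>12d}",
            f"critic updates         {self.d_updates:>12d}",
            f"first-epoch L_content  {h['L_content'].iloc[0]:>12.5f}",
            f"final-epoch L_content  {h['L_content'].iloc[-1]:>12.5f}",
            f"final-epoch L_G        {h['L_G'].iloc[-1]:>12.5f}",
            f"final learning rate    {h['lr'].iloc[-1]:>12.2e}",
            "=" * 46,
        ]
        return "\n".join(lines)


class AggDeblurGAN:
    """Deblurring GAN bound to a paired dataset.

    Parameters
    ----------
    pairs
        Sequence of :class:`SharpBlurPair` or ``(blurred, sharp)`` HWC
        arrays in [0, 1].
    generator_config, discriminator_config
        Architecture configurations; reduced-width configs keep CPU
        training tractable.
    feature_extractor
        Callable for the perceptual term of the content loss; defaults to
        the identity (pixel-space MSE).
    """

    def __init__(self, pairs: Sequence,
                 generator_config: Optional[GeneratorConfig] = None,
                 discriminator_config: Optional[DiscriminatorConfig] = None,
                 feature_extractor: Callable = identity_extractor):
        if not len(pairs):
            raise ValueError("empty dataset: need at least one sharp/blur pair")
        self._blur, self._sharp = [], []
        for p in pairs:
            if isinstance(p, SharpBlurPair):
                b, s = p.blurred, p.sharp
            else:
                b, s = p
            self._blur.append(_to_nchw(b))
            self._sharp.append(_to_nchw(s))
        self._blur = np.stack(self._blur)
        self._sharp = np.stack(self._sharp)
        self.generator = AggGenerator(generator_config)
        self.critics = build_double_scale_discriminator(discriminator_config)
        self.feature_extractor = feature_extractor

    # -- one optimization step ------------------------------------------------
    def _g_step(self, x, y, g_opt):
        pred = self.generator.forward(x)
        c_loss = content_loss(pred, Tensor(y), self.feature_extractor)
        with no_grad():
            real_scores = [c(Tensor(y)) for c in self.critics]
        fake_scores = [c(pred) for c in self.critics]
        g_adv, _ = adversarial_losses([Tensor(r.data) for r in real_scores],
                                      fake_scores)
        total = total_generator_loss(c_loss, g_adv)
        for net in (self.generator, *self.critics):
            net.zero_grad()
        total.backward()
        g_opt.step()
        return float(c_loss.item()), float(g_adv.item()), float(total.item()), pred.data

    def _d_step(self, pred_data, y, d_opt):
        real_scores = [c(Tensor(y)) for c in self.critics]
        fake_scores = [c(Tensor(pred_data)) for c in self.critics]
        _, d_loss = adversarial_losses(real_scores, fake_scores)
        for net in (self.generator, *self.critics):
            net.zero_grad()
        d_loss.backward()
        d_opt.step()
        return float(d_loss.item())

    # -- fit ------------------------------------------------------------------
    def fit(self, config: Optional[TrainConfig] = None,
            checkpoint_path=None, verbose: bool = False) -> TrainingResults:
        cfg = config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        n = len(self._blur)
        g_opt = Adam(self.generator.parameters(), lr=cfg.lr_init)
        d_params = [p for c in self.critics for p in c.parameters()]
        d_opt = Adam(d_params, lr=cfg.lr_init)

        rows = []
        g_updates = d_updates = 0
        for epoch in range(1, cfg.total_epochs + 1):
            lr = learning_rate(epoch - 1, cfg)
            g_opt.lr = d_opt.lr = lr
            order = rng.permutation(n)
            ep_c, ep_adv, ep_g, ep_d = [], [], [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x, y = self._blur[idx], self._sharp[idx]
                c_val, adv_val, tot_val, pred_data = self._g_step(x, y, g_opt)
                g_updates += 1
                if not np.isfinite(tot_val):
                    raise FloatingPointError(
                        f"non-finite generator loss at epoch {epoch} "
                        f"(content={c_val}, adv={adv_val}); aborting")
                for _ in range(cfg.d_steps_per_g_step):
                    d_val = self._d_step(pred_data, y, d_opt)
                    d_updates += 1
                    if not np.isfinite(d_val):
                        raise FloatingPointError(
                            f"non-finite critic loss at epoch {epoch}; aborting")
                ep_c.append(c_val)
                ep_adv.append(adv_val)
                ep_g.append(tot_val)
                ep_d.append(d_val)
            rows.append({"epoch": epoch, "lr": lr,
                         "L_content": float(np.mean(ep_c)),
                         "L_adv": float(np.mean(ep_adv)),
                         "L_G": float(np.mean(ep_g)),
                         "L_D": float(np.mean(ep_d))})
            if verbose:
                r = rows[-1]
                print(f"epoch {epoch:3d}  lr={lr:.2e}  "
                      f"L_content={r['L_content']:.5f}  L_G={r['L_G']:.5f}")
            if checkpoint_path is not None:
                save_checkpoint(self.generator, checkpoint_path)
        history = pd.DataFrame(rows).set_index("epoch")
        return TrainingResults(self, history, g_updates, d_updates)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(generator: AggGenerator, path):
    """Serialize generator weights plus its architecture config (npz)."""
    import json
    from dataclasses import asdict

    state = generator.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(generator.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> AggGenerator:
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"].tobytes()).decode())
        gen = AggGenerator(GeneratorConfig(**cfg_dict))
        gen.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return gen
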