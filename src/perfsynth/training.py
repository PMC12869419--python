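"""Alternating adversarial training and whole-volume inference.

Each iteration first updates the four map-specific PatchGAN
discriminators on one real and one generated pair per sample, then
freezes them and updates the multitask generator on the combined
objective (adversarial + lambda1 L1 + lambda2 extrema + lambda3
multimodal).  Adam with beta1 = 0.5, beta2 = 0.999 and a constant
learning rate of 1e-4 for both networks; batch normalization when the
batch size exceeds one, instance normalization otherwise.  After every
epoch the generator loss is recorded on a held-out validation split
sampled at the image level.

Default hyperparameters are the full-scale settings (256 px, base width
64, 50 epochs, batch 8); the test surface runs a width/resolution-scaled
configuration so the whole loop fits on one CPU.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import losses as L
from ._autodiff import Tensor
from ._nn import Adam
from .network import (Generator, NetworkConfig, build_discriminators,
                      build_generator, pilo_rescale, save_checkpoint)
from .preprocessing import (MAP_RANGES, EmptyMaskError, WindowSpec,
                            denormalize_map, resize_to, skull_strip,
                            stack_pseudo_rgb, window_hu)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "validate",
    "infer_volume",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (full-scale defaults)."""

    epochs: int = 50
    batch_size: int = 8
    lr: float = 1e-4               # constant; no decay
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    val_size: int = 100            # slices, sampled at the image level
    seed: int = 0
    checkpoint_every: int = 0      # epochs; 0 disables
    d_steps: int = 1               # discriminator updates per generator update
    loss_weights: L.LossWeights = field(default_factory=L.LossWeights)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class TrainHistory:
    """Per-iteration loss reports and per-epoch validation losses."""

    iterations: list = field(default_factory=list)   # dicts (LossReport.to_dict)
    val_loss: list = field(default_factory=list)     # one per epoch
    seed: int = 0
    wall_clock: float = 0.0

    def save_jsonl(self, path):
        with open(path, "w") as fh:
            for row in self.iterations:
                fh.write(json.dumps(row) + "\n")


def _batch_arrays(samples) -> tuple:
    x = np.stack([s.ncct3 for s in samples]).astype(np.float32)
    maps = {
        k: np.stack([s.maps[k] for s in samples])[:, None].astype(np.float32)
        for k in samples[0].maps
    }
    mask = np.stack([s.brain_mask for s in samples])[:, None].astype(np.float32)
    return x, maps, mask


def _generator_terms(gen_maps: dict, real_maps: dict, mask, w: L.LossWeights):
    """Non-adversarial generator losses on mask-multiplied maps."""
    masked = {k: v * Tensor(mask) for k, v in gen_maps.items()}
    l1 = L.l1_loss(masked, {k: Tensor(v) for k, v in real_maps.items()})
    ext = L.extrema_loss(masked, {k: Tensor(v) for k, v in real_maps.items()},
                         eps=w.eps, mask=mask)
    mml = L.multimodal_loss(masked["cbf"], masked["mtt"], Tensor(real_maps["cbv"]),
                            consistency_factor=w.consistency_factor)
    return masked, l1, ext, mml


def train(dataset, cfg: TrainConfig, out_dir=None):
    """Adversarial training; returns (generator, discriminators, history)."""
    if not dataset:
        raise ValueError("empty dataset")
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    # validation split at the image level
    n_val = min(cfg.val_size, max(1, len(dataset) // 5))
    order = rng.permutation(len(dataset))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]
    if not train_set:
        raise ValueError("dataset too small to split")

    net_cfg = replace(cfg.network,
                      norm_kind="batch" if cfg.batch_size > 1 else "instance")
    gen = build_generator(net_cfg, seed=cfg.seed)
    discs = build_discriminators(net_cfg, seed=cfg.seed + 1)
    pool = np.stack([s.ncct3 for s in train_set])
    gen.set_input_stats(pool.mean(), pool.std())

    opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=cfg.adam_beta1,
                 beta2=cfg.adam_beta2)
    opt_d = {k: Adam(d.parameters(), lr=cfg.lr, beta1=cfg.adam_beta1,
                     beta2=cfg.adam_beta2) for k, d in discs.items()}
    w = cfg.loss_weights
    history = TrainHistory(seed=cfg.seed)

    for epoch in range(cfg.epochs):
        idx = rng.permutation(len(train_set))
        for start in range(0, len(idx) - cfg.batch_size + 1, cfg.batch_size):
            batch = [train_set[i] for i in idx[start:start + cfg.batch_size]]
            x, real_maps, mask = _batch_arrays(batch)
            xt = Tensor(x)

            # -- discriminator updates (generator output detached) -----
            for _ in range(cfg.d_steps):
                with_frozen = gen.forward(xt)
                fake = {k: (v * Tensor(mask)).detach() for k, v in with_frozen.items()}
                d_real = {k: discs[k](xt, Tensor(real_maps[k])) for k in discs}
                d_fake = {k: discs[k](xt, fake[k]) for k in discs}
                loss_d, _ = L.gan_loss(d_real, d_fake, eps=w.eps)
                for d in discs.values():
                    d.zero_grad()
                loss_d.backward()
                for k in discs:
                    opt_d[k].step()

            # -- generator update (discriminators frozen) --------------
            gen_maps = gen.forward(xt)
            masked, l1, ext, mml = _generator_terms(gen_maps, real_maps, mask, w)
            d_fake = {k: discs[k](xt, masked[k]) for k in discs}
            d_real = {k: Tensor(np.asarray(dr.data)) for k, dr in d_real.items()}
            _, gan_g = L.gan_loss(d_real, d_fake, eps=w.eps,
                                  non_saturating=w.non_saturating)
            total_g = gan_g + w.lambda1 * l1 + w.lambda2 * ext + w.lambda3 * mml
            if not np.isfinite(float(total_g)):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}: "
                    f"gan={float(gan_g)} l1={float(l1)} ext={float(ext)} mml={float(mml)}"
                )
            gen.zero_grad()
            for d in discs.values():
                d.zero_grad()
            total_g.backward()
            opt_g.step()   # discriminator optimizers untouched: D frozen

            report = L.LossReport(
                gan_D=float(loss_d), gan_G=float(gan_g), l1=float(l1),
                extrema=float(ext), multimodal=float(mml),
                total_G=float(total_g), total_D=float(loss_d),
            )
            history.iterations.append(report.to_dict())

        history.val_loss.append(validate(gen, val_set, w))
        if out_dir and cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(f"{out_dir}/epoch{epoch + 1:03d}", gen, discs,
                            extra={"epoch": epoch + 1, "seed": cfg.seed})

    history.wall_clock = time.time() - t0
    if out_dir:
        save_checkpoint(f"{out_dir}/final", gen, discs,
                        extra={"epoch": cfg.epochs, "seed": cfg.seed})
        history.save_jsonl(f"{out_dir}/history.jsonl")
    return gen, discs, history


def validate(gen: Generator, val_set, w: L.LossWeights | None = None,
             discs: dict | None = None, batch_size: int = 8) -> float:
    """Generator-side objective on a held-out set, no weight updates.

    Without discriminators this is the lambda-weighted non-adversarial
    part (L1 + extrema + multimodal); passing ``discs`` adds the
    adversarial term.
    """
    if not val_set:
        raise ValueError("empty validation set")
    w = w or L.LossWeights()
    was_training = gen.training
    gen.eval()
    try:
        total, n = 0.0, 0
        for start in range(0, len(val_set), batch_size):
            batch = val_set[start:start + batch_size]
            x, real_maps, mask = _batch_arrays(batch)
            xt = Tensor(x)
            gen_maps = gen.forward(xt)
            masked, l1, ext, mml = _generator_terms(gen_maps, real_maps, mask, w)
            loss = w.lambda1 * float(l1) + w.lambda2 * float(ext) + w.lambda3 * float(mml)
            if discs is not None:
                d_fake = {k: discs[k](xt, masked[k]) for k in discs}
                d_real = {k: Tensor(np.ones_like(d_fake[k].data)) for k in discs}
                _, gan_g = L.gan_loss(d_real, d_fake, eps=w.eps,
                                      non_saturating=w.non_saturating)
                loss += float(gan_g)
            total += loss * len(batch)
            n += len(batch)
        return total / n
    finally:
        gen.train(was_training)


def validation_l1(gen: Generator, val_set, batch_size: int = 8) -> float:
    """Plain held-out L1 in normalized map space (monitoring metric)."""
    w = L.LossWeights(lambda1=1.0, lambda2=0.0, lambda3=0.0)
    return validate(gen, val_set, w, batch_size=batch_size)


def infer_volume(gen: Generator, ncct_volume, axial_spacing: float = 1.0,
                 offset_mm: float = 4.0, alphas: tuple = (1.0, 1.0),
                 window: WindowSpec = WindowSpec(), batch_size: int = 8) -> dict:
    """Synthesize the four perfusion volumes from an NCCT volume.

    One prediction per axial position that has both +-offset
    neighbours; boundary slices are skipped and reported.  Outputs are
    denormalized to physical units and masked to the brain.  ``alphas``
    = (alpha_perf, alpha_anat) rescales the PILO layer for the forward
    passes only; (1, 1) leaves the trained weights untouched.

    Returns a dict with per-kind (Z', H, W) volumes, the predicted
    ``positions``, and the ``skipped`` boundary indices.
    """
    vol = np.asarray(ncct_volume, dtype=float)
    o = int(round(offset_mm / axial_spacing))
    if vol.shape[0] <= 2 * o:
        raise ValueError(f"volume too thin for a +-{o}-slice context")
    size = gen.cfg.image_size
    windowed = window_hu(vol, window)
    positions = list(range(o, vol.shape[0] - o))
    skipped = list(range(o)) + list(range(vol.shape[0] - o, vol.shape[0]))

    stacks, masks = [], []
    for z in positions:
        ncct3 = stack_pseudo_rgb(windowed, z, offset_mm, axial_spacing)
        try:
            mask = skull_strip(ncct3[1])
        except EmptyMaskError:
            # no detectable brain on this slice: emit an all-zero map
            mask = np.zeros(ncct3.shape[1:], dtype=bool)
        ncct3 = resize_to(ncct3 * mask[None], size)
        masks.append(resize_to(mask, size, is_mask=True))
        stacks.append(ncct3)

    saved = {k: b.pilo.weight.data.copy() for k, b in gen.branches.items()}
    for b in gen.branches.values():
        b.pilo.weight.data = pilo_rescale(b.pilo.weight.data, *alphas)
    was_training = gen.training
    gen.eval()
    try:
        outputs = {k: [] for k in gen.branches}
        for start in range(0, len(stacks), batch_size):
            x = np.stack(stacks[start:start + batch_size]).astype(np.float32)
            m = np.stack(masks[start:start + batch_size])[:, None]
            maps = gen.forward(Tensor(x))
            for k, v in maps.items():
                out = np.clip(v.data, 0.0, 1.0) * m
                outputs[k].append(denormalize_map(out[:, 0], MAP_RANGES[k]) * m[:, 0])
        result = {k: np.concatenate(v, axis=0) for k, v in outputs.items()}
    finally:
        for k, b in gen.branches.items():
            b.pilo.weight.data = saved[k]
        gen.train(was_training)
    result["positions"] = positions
    result["skipped"] = skipped
    return result
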