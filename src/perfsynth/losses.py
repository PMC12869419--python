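"""Physiology-informed adversarial objective for perfusion-map synthesis.

Four terms drive the generator:

* **GAN loss** — patchwise binary cross-entropy against the four
  map-specific discriminators, averaged over the map kinds (the 1/N
  prefactor of the adversarial objective).  The generator side uses the
  non-saturating ``-log D(fake)`` form by default.
* **L1 loss** — mean absolute difference between generated and real
  maps in normalized [0, 1] map space, averaged over map kinds.
* **Multimodal loss** — the central volume principle (CBV = CBF x MTT)
  applied *literally on normalized maps*: the mean absolute difference
  between the elementwise product of the synthesized CBF and MTT maps
  and the real CBV map.  Note that with the canonical normalization
  ranges the physical identity would carry a factor of 3; the loss is
  intentionally the literal normalized-product form, with an optional
  ``consistency_factor`` exposed for experimentation (default 1).
* **Extrema loss** — a weighted MSE that emphasizes pixels far from the
  map's min-max midpoint, i.e. exactly the hypo-/hyper-perfused regions
  a stroke reader cares about.  The real map is min-max normalized to
  [-0.5, 0.5] and squared to form the weight map; the error term is the
  squared difference of the min-max normalized generated and real maps.

All functions accept NumPy arrays or autodiff tensors and return 0-d
tensors (``float()`` them for reporting); gradients flow when inputs
require them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor

_LOG = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "LossReport",
    "gan_loss",
    "l1_loss",
    "multimodal_loss",
    "extrema_weight_map",
    "extrema_loss",
    "total_objective",
]


@dataclass
class LossWeights:
    """Weights of the auxiliary generator loss terms.

    The source hyperparameters are exposed, not hard-coded: lambda1
    follows the pix2pix convention for the L1 term; lambda2 and lambda3
    put the extrema and multimodal terms on comparable footing on
    phantom batches at initialization.
    """

    lambda1: float = 100.0   # L1
    lambda2: float = 100.0   # extrema
    lambda3: float = 10.0    # multimodal
    eps: float = 1e-7
    non_saturating: bool = True
    consistency_factor: float = 1.0  # optional x3 unit factor, default off

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class LossReport:
    """Per-term loss values for one iteration (floats, for logging)."""

    gan_D: float = 0.0
    gan_G: float = 0.0
    l1: float = 0.0
    extrema: float = 0.0
    multimodal: float = 0.0
    total_G: float = 0.0
    total_D: float = 0.0
    per_map: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("gan_D", "gan_G", "l1", "extrema", "multimodal", "total_G", "total_D")}
        for kind, sub in self.per_map.items():
            for term, v in sub.items():
                d[f"{kind}_{term}"] = v
        return d


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _pairs(d_real, d_fake):
    """Normalize input to a list of (real, fake) patch-map pairs."""
    if isinstance(d_real, dict):
        return [(d_real[k], d_fake[k]) for k in d_real]
    if isinstance(d_real, (list, tuple)):
        return list(zip(d_real, d_fake))
    return [(d_real, d_fake)]


def gan_loss(d_real, d_fake, eps: float = 1e-7, non_saturating: bool = True):
    """Adversarial loss from patch probability maps.

    Accepts a single pair, a sequence of pairs, or dicts keyed by map
    kind; the result is averaged over the map kinds.  Returns
    ``(loss_D, loss_G)``: the discriminator minimizes ``loss_D``
    (equivalently maximizes the adversarial objective) and the generator
    minimizes ``loss_G``.
    """
    pairs = _pairs(d_real, d_fake)
    loss_d = loss_g = 0.0
    for real, fake in pairs:
        real = _t(real).clamp(eps, 1.0 - eps)
        fake = _t(fake).clamp(eps, 1.0 - eps)
        loss_d = loss_d + -(real.log().mean() + (1.0 - fake).log().mean())
        if non_saturating:
            loss_g = loss_g + -(fake.log().mean())
        else:
            loss_g = loss_g + (1.0 - fake).log().mean()
    n = float(len(pairs))
    return loss_d * (1.0 / n), loss_g * (1.0 / n)


def l1_loss(generated, real):
    """Mean absolute difference, averaged over pixels then map kinds."""
    pairs = _pairs(generated, real)
    total = 0.0
    for gen, ref in pairs:
        gen, ref = _t(gen), _t(ref)
        if gen.shape != ref.shape:
            raise ValueError(f"shape mismatch: {gen.shape} vs {ref.shape}")
        total = total + (gen - ref).abs().mean()
    return total * (1.0 / len(pairs))


def multimodal_loss(gen_cbf, gen_mtt, real_cbv, consistency_factor: float = 1.0):
    """Central-volume-principle residual on normalized maps.

    ``mean | CBF_gen * MTT_gen * factor - CBV_real |`` with ``factor``
    defaulting to 1 (the literal normalized-product form).
    """
    gen_cbf, gen_mtt, real_cbv = _t(gen_cbf), _t(gen_mtt), _t(real_cbv)
    if not (gen_cbf.shape == gen_mtt.shape == real_cbv.shape):
        raise ValueError("multimodal loss inputs must share a shape")
    prod = gen_cbf * gen_mtt
    if consistency_factor != 1.0:
        prod = prod * consistency_factor
    return (prod - real_cbv).abs().mean()


def _spatial_axes(x: Tensor) -> tuple | None:
    """Reduce over the trailing two axes when batched, else globally."""
    return (-2, -1) if x.ndim >= 3 else None


def _minmax_norm(x: Tensor, eps: float, mask=None) -> Tensor:
    """Min-max normalize to [0, 1] per image (within `mask` if given)."""
    axes = _spatial_axes(x)
    if mask is not None:
        m = _t(mask)
        big = 1e9
        lo = (x * m + (1.0 - m) * big).amin(axis=axes, keepdims=axes is not None)
        hi = (x * m - (1.0 - m) * big).amax(axis=axes, keepdims=axes is not None)
    else:
        lo = x.amin(axis=axes, keepdims=axes is not None)
        hi = x.amax(axis=axes, keepdims=axes is not None)
    return (x - lo) * ((hi - lo + eps) ** -1.0)


def extrema_weight_map(real_map, eps: float = 1e-7, mask=None):
    """Weight map emphasizing extreme pixels of the real perfusion map.

    The map is min-max normalized to [-0.5, 0.5] and squared, so the
    weights lie in [0, 0.25]: zero at the midpoint, maximal at the
    extremes.  A constant map carries no extremes: its weight map is
    identically zero (logged as a warning).
    """
    pm = _t(real_map)
    w = _minmax_norm(pm, eps, mask) - 0.5
    w = w * w
    nonconst = _nonconstant_indicator(pm.data, eps, mask)
    if not nonconst.all():
        _LOG.warning("constant perfusion map: extrema weight map set to zero")
        w = w * Tensor(nonconst.astype(pm.data.dtype))
    return w


def _nonconstant_indicator(data: np.ndarray, eps: float, mask=None) -> np.ndarray:
    """1 where the (masked) image has spread > eps, else 0; broadcastable."""
    axes = (-2, -1) if data.ndim >= 3 else None
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        lo = np.where(m, data, np.inf).min(axis=axes, keepdims=axes is not None)
        hi = np.where(m, data, -np.inf).max(axis=axes, keepdims=axes is not None)
    else:
        lo = data.min(axis=axes, keepdims=axes is not None)
        hi = data.max(axis=axes, keepdims=axes is not None)
    return np.asarray(hi - lo) > eps


def extrema_loss(generated, real, eps: float = 1e-7, mask=None):
    """Extrema-weighted MSE between min-max normalized map pairs.

    Averaged over pixels, then over map kinds when given dicts/lists.
    Min-max statistics are computed per image (within the brain mask if
    one is supplied), never across the batch.
    """
    pairs = _pairs(generated, real)
    total = 0.0
    for gen, ref in pairs:
        gen, ref = _t(gen), _t(ref)
        if gen.shape != ref.shape:
            raise ValueError(f"shape mismatch: {gen.shape} vs {ref.shape}")
        w = extrema_weight_map(ref, eps, mask)
        h = _minmax_norm(gen, eps, mask) - _minmax_norm(ref, eps, mask)
        total = total + (w * h * h).mean()
    return total * (1.0 / len(pairs))


def total_objective(gan_G, l1, extrema, multimodal, w: LossWeights,
                    gan_D=None) -> LossReport:
    """Combine the generator terms; totals obey
    ``total_G = gan_G + lambda1*l1 + lambda2*extrema + lambda3*multimodal``.
    """
    tg = gan_G + w.lambda1 * l1 + w.lambda2 * extrema + w.lambda3 * multimodal
    return LossReport(
        gan_G=float(gan_G), l1=float(l1), extrema=float(extrema),
        multimodal=float(multimodal), total_G=float(tg),
        gan_D=float(gan_D) if gan_D is not None else 0.0,
        total_D=float(gan_D) if gan_D is not None else 0.0,
    )
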