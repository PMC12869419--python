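"""Multitask generator and PatchGAN discriminators for NCCT-to-CTP synthesis.

The generator is a pix2pix-style U-Net with a twist: the first
``shared_depth`` encoder stages are shared across the four perfusion-map
tasks (CBF, CBV, MTT, TTP); each task then owns the remaining encoder
stages, a full skip-connected decoder, and a physician-in-the-loop
(PILO) output layer.  The PILO layer is a 1x1 transposed convolution
over the concatenation of the decoded perfusion channel with the three
pseudo-RGB NCCT channels; rescaling its input-channel weights at
inference trades hemodynamic against anatomical content without
retraining.

Parameter-count ledger
----------------------
Every convolution (and transposed convolution) carries a bias term;
normalization layers carry *no* learnable affine parameters.  With the
default channel ladder (64, 128, 256, 512, 512, 512, 512, 512) this
yields exactly 209,352,408 trainable generator parameters and
11,063,044 across the four discriminators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn as nn
from ._autodiff import Tensor, concatenate, conv_transpose2d

__all__ = [
    "MAP_KINDS",
    "NetworkConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "build_discriminators",
    "count_parameters",
    "parameter_report",
    "receptive_field",
    "pilo_forward",
    "pilo_rescale",
    "save_checkpoint",
    "load_checkpoint",
]

#: Canonical perfusion-map order used throughout the package.
MAP_KINDS = ("cbf", "cbv", "mtt", "ttp")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` is derived from ``image_size`` and ``base_width``
    when left empty: one stride-2 stage per factor of two down to a 1x1
    bottleneck, channel width doubling from ``base_width`` and capped at
    ``8 * base_width`` (the standard pix2pix ladder).
    """

    input_channels: int = 3
    map_count: int = 4
    image_size: int = 256
    base_width: int = 64
    shared_depth: int = 4
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    leaky_slope: float = 0.2
    norm_kind: str = "batch"        # "batch" or "instance"
    conv_bias: bool = True          # ledger: biases everywhere
    norm_affine: bool = False       # ledger: no affine scale/shift
    pilo_kernel: int = 1
    encoder_widths: tuple = field(default_factory=tuple)
    disc_widths: tuple = field(default_factory=tuple)

    def __post_init__(self):
        n = int(np.log2(self.image_size))
        if 2**n != self.image_size:
            raise ValueError("image_size must be a power of two")
        if not self.encoder_widths:
            self.encoder_widths = tuple(
                min(self.base_width * 2**i, self.base_width * 8) for i in range(n)
            )
        if len(self.encoder_widths) != n:
            raise ValueError("encoder width ladder must halve the image to 1x1")
        if not (1 <= self.shared_depth < len(self.encoder_widths)):
            raise ValueError("shared_depth must leave at least one task stage")
        if self.norm_kind not in ("batch", "instance"):
            raise ValueError(f"unknown norm kind: {self.norm_kind}")
        if self.pilo_kernel % 2 != 1:
            raise ValueError("pilo_kernel must be odd to preserve image size")
        if not self.disc_widths:
            b = self.base_width
            self.disc_widths = (b, 2 * b, 4 * b, 8 * b, 1)

    @property
    def n_stages(self) -> int:
        return len(self.encoder_widths)

    @property
    def decoder_widths(self) -> tuple:
        """Mirror of the encoder ladder; final stage emits one channel."""
        return tuple(reversed(self.encoder_widths[:-1])) + (1,)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("encoder_widths", "disc_widths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _make_norm(cfg: NetworkConfig, channels: int) -> nn.Module:
    if cfg.norm_kind == "batch":
        return nn.BatchNorm2d(channels)
    return nn.InstanceNorm2d(channels)


class _EncoderStage(nn.Module):
    """Conv -> (norm) -> LeakyReLU downsampling block."""

    def __init__(self, cfg, c_in, c_out, rng, norm=True):
        super().__init__()
        self.slope = cfg.leaky_slope
        self.conv = self.add_module(
            "conv",
            nn.Conv2d(c_in, c_out, cfg.kernel, cfg.stride, cfg.padding,
                      bias=cfg.conv_bias, rng=rng),
        )
        self.norm = self.add_module("norm", _make_norm(cfg, c_out)) if norm else None

    def forward(self, x):
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        return y.leaky_relu(self.slope)


class _DecoderStage(nn.Module):
    """ConvT -> (norm) -> activation upsampling block."""

    def __init__(self, cfg, c_in, c_out, rng, norm=True, final=False):
        super().__init__()
        self.slope = cfg.leaky_slope
        self.final = final
        self.conv = self.add_module(
            "conv",
            nn.ConvTranspose2d(c_in, c_out, cfg.kernel, cfg.stride, cfg.padding,
                               bias=cfg.conv_bias, rng=rng),
        )
        self.norm = (
            self.add_module("norm", _make_norm(cfg, c_out)) if norm and not final
            else None
        )

    def forward(self, x):
        y = self.conv(x)
        if self.final:
            return y.tanh()
        if self.norm is not None:
            y = self.norm(y)
        return y.leaky_relu(self.slope)


class _TaskBranch(nn.Module):
    """Task-specific encoder tail, skip-connected decoder, and PILO layer."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        widths, n = cfg.encoder_widths, cfg.n_stages
        self.encoders = []
        for k in range(cfg.shared_depth, n):
            st = _EncoderStage(cfg, widths[k - 1], widths[k], rng, norm=(k < n - 1))
            self.encoders.append(self.add_module(f"enc{k + 1}", st))
        dec_w = cfg.decoder_widths
        self.decoders = []
        c_in = widths[-1]
        for k in range(n):
            final = k == n - 1
            st = _DecoderStage(cfg, c_in, dec_w[k], rng, final=final)
            self.decoders.append(self.add_module(f"dec{k + 1}", st))
            if not final:
                c_in = dec_w[k] + widths[n - 2 - k]  # skip from encoder n-1-k
        self.pilo = self.add_module(
            "pilo",
            nn.ConvTranspose2d(cfg.map_count, 1, cfg.pilo_kernel, 1,
                               (cfg.pilo_kernel - 1) // 2, bias=True, rng=rng),
        )
        # identity-ish start: pass the perfusion channel through untouched
        w = self.pilo.weight.data
        w[:] = rng.normal(0.0, 0.02, w.shape)
        w[0, 0, w.shape[2] // 2, w.shape[3] // 2] = 1.0

    def forward(self, shared_feats: list, x_raw: Tensor) -> tuple:
        h = shared_feats[-1]
        feats = list(shared_feats)
        for st in self.encoders:
            h = st(h)
            feats.append(h)
        bottleneck = h
        for k, st in enumerate(self.decoders):
            h = st(h)
            if k < len(self.decoders) - 1:
                h = concatenate([h, feats[len(feats) - 2 - k]], axis=1)
        perf = (h + 1.0) * 0.5  # Tanh [-1,1] -> [0,1] map space
        out = pilo_forward(perf, x_raw, self.pilo)
        return out, bottleneck


class Generator(nn.Module):
    """Shared-encoder multitask U-Net emitting all four perfusion maps."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.encoder_widths
        self.shared = []
        c_in = cfg.input_channels
        for k in range(cfg.shared_depth):
            st = _EncoderStage(cfg, c_in, widths[k], rng, norm=(k > 0))
            self.shared.append(self.add_module(f"shared{k + 1}", st))
            c_in = widths[k]
        self.branches = {}
        for kind in MAP_KINDS[: cfg.map_count]:
            self.branches[kind] = self.add_module(kind, _TaskBranch(cfg, rng))
        # z-score standardization applied at the network input boundary
        self.input_mean = 0.0
        self.input_sd = 1.0

    def set_input_stats(self, mean: float, sd: float):
        self.input_mean, self.input_sd = float(mean), float(sd)

    def forward(self, x, return_bottlenecks: bool = False):
        """Map a (N, 3, S, S) windowed NCCT stack to four [0,1] maps."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        xs = (x - self.input_mean) * (1.0 / self.input_sd)
        feats = []
        h = xs
        for st in self.shared:
            h = st(h)
            feats.append(h)
        maps, necks = {}, {}
        for kind, branch in self.branches.items():
            maps[kind], necks[kind] = branch(feats, x)
        if return_bottlenecks:
            return maps, necks
        return maps

    def _buffers(self):
        return {"input_stats": np.array([self.input_mean, self.input_sd])}

    def _set_buffer(self, name, value):
        if name != "input_stats":
            raise KeyError(name)
        self.input_mean, self.input_sd = float(value[0]), float(value[1])


class Discriminator(nn.Module):
    """70x70 PatchGAN over a 4-channel (pseudo-RGB NCCT + map) pair.

    Five 4x4 convolution stages with strides (2, 2, 2, 1, 1); sigmoid
    patch output, so each output unit scores one receptive-field patch.
    """

    STRIDES = (2, 2, 2, 1, 1)

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        widths = cfg.disc_widths
        c_in = cfg.input_channels + 1
        self.stages = []
        for k, (c_out, s) in enumerate(zip(widths, self.STRIDES)):
            conv = nn.Conv2d(c_in, c_out, cfg.kernel, s, cfg.padding,
                             bias=cfg.conv_bias, rng=rng)
            self.stages.append(self.add_module(f"conv{k + 1}", conv))
            norm = _make_norm(cfg, c_out) if 0 < k < len(widths) - 1 else None
            if norm is not None:
                self.add_module(f"norm{k + 1}", norm)
            c_in = c_out
        self.norms = [self._modules.get(f"norm{k + 1}") for k in range(len(widths))]
        self.slope = cfg.leaky_slope

    def forward(self, ncct3, perf_map):
        h = concatenate([_as_tensor(ncct3), _as_tensor(perf_map)], axis=1)
        last = len(self.stages) - 1
        for k, conv in enumerate(self.stages):
            h = conv(h)
            if k == last:
                return h.sigmoid()
            if self.norms[k] is not None:
                h = self.norms[k](h)
            h = h.leaky_relu(self.slope)
        raise AssertionError("unreachable")


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------
# Builders and introspection
# ---------------------------------------------------------------------

def build_generator(cfg: NetworkConfig | None = None, seed: int = 0) -> Generator:
    return Generator(cfg or NetworkConfig(), seed=seed)


def build_discriminator(cfg: NetworkConfig | None = None, seed: int = 0) -> Discriminator:
    return Discriminator(cfg or NetworkConfig(), seed=seed)


def build_discriminators(cfg: NetworkConfig | None = None, seed: int = 0) -> dict:
    """One PatchGAN per perfusion-map kind."""
    cfg = cfg or NetworkConfig()
    return {
        kind: Discriminator(cfg, seed=seed + i)
        for i, kind in enumerate(MAP_KINDS[: cfg.map_count])
    }


def count_parameters(model) -> int:
    """Total trainable scalars of a module, or a dict/list of modules."""
    if isinstance(model, dict):
        return sum(count_parameters(m) for m in model.values())
    if isinstance(model, (list, tuple)):
        return sum(count_parameters(m) for m in model)
    return sum(p.data.size for p in model.parameters())


def parameter_report(model: nn.Module) -> dict:
    """Per-block parameter counts; blocks sum exactly to the total."""
    report: dict[str, int] = {}
    for name, p in model.named_parameters():
        block = name.rsplit(".", 2)[0] if name.count(".") >= 2 else name.rsplit(".", 1)[0]
        report[block] = report.get(block, 0) + p.data.size
    report["total"] = sum(report.values())
    return report


def receptive_field(stages) -> int:
    """Receptive field (pixels per side) of stacked (kernel, stride) stages.

    RF grows by (k - 1) times the product of all earlier strides.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("empty stage list")
    rf, jump = 1, 1
    for k, s in stages:
        rf += (k - 1) * jump
        jump *= s
    return rf


# ---------------------------------------------------------------------
# PILO: physician-in-the-loop output layer
# ---------------------------------------------------------------------

def pilo_forward(branch_output, ncct3, pilo) -> Tensor:
    """Fuse the decoded perfusion channel with the NCCT channels.

    `pilo` is the branch's 4-to-1 transposed-convolution layer; input
    channel 0 is the perfusion channel, channels 1..3 the NCCT stack.
    """
    x = concatenate([_as_tensor(branch_output), _as_tensor(ncct3)], axis=1)
    return conv_transpose2d(x, pilo.weight, pilo.bias, pilo.stride, pilo.pad)


def pilo_rescale(weights: np.ndarray, alpha_perf: float, alpha_anat: float) -> np.ndarray:
    """Rescale PILO input-channel weight slices; (1, 1) is the identity.

    ``alpha_perf`` scales the synthesized-perfusion channel,
    ``alpha_anat`` the three anatomical NCCT channels.
    """
    if alpha_perf < 0 or alpha_anat < 0:
        raise ValueError("PILO scale factors must be non-negative")
    out = np.array(weights, copy=True)
    out[0] *= alpha_perf
    out[1:] *= alpha_anat
    return out


# ---------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(path, generator: Generator, discriminators: dict | None = None,
                    extra: dict | None = None):
    """Write weights (npz) plus a JSON manifest sufficient to rebuild."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {f"gen/{k}": v for k, v in generator.state_dict().items()}
    if discriminators:
        for kind, d in discriminators.items():
            arrays.update({f"disc_{kind}/{k}": v for k, v in d.state_dict().items()})
    np.savez(path / "weights.npz", **arrays)
    manifest = {
        "config": generator.cfg.to_dict(),
        "map_kinds": list(generator.branches),
        "has_discriminators": bool(discriminators),
    }
    if extra:
        manifest.update(extra)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> tuple:
    """Rebuild (generator, discriminators-or-None, manifest) from disk."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cfg = NetworkConfig.from_dict(manifest["config"])
    data = np.load(path / "weights.npz")
    gen = Generator(cfg)
    gen.load_state_dict(
        {k[len("gen/"):]: data[k] for k in data.files if k.startswith("gen/")}
    )
    discs = None
    if manifest.get("has_discriminators"):
        discs = build_discriminators(cfg)
        for kind, d in discs.items():
            prefix = f"disc_{kind}/"
            d.load_state_dict(
                {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            )
    return gen, discs, manifest
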