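"""Preprocessing of paired NCCT / perfusion-map volumes into training slices.

Pipeline order: Hounsfield windowing -> skull stripping -> resizing ->
pseudo-RGB stacking -> map normalization -> static augmentation ->
z-score standardization at batch assembly.  Windowing precedes
stripping so the bone threshold is scanner-independent; augmentation
acts on normalized data so the zero fill value stays meaningful.

The pseudo-RGB input stacks the axial slice with its neighbours at a
fixed vertical offset (default 4 mm), giving the network above/below
context.  Maps are stored in [0, 1] via the canonical physiological
ranges; zero-mean/unit-sd standardization is applied only at the
network input boundary using training-pool statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, transform

__all__ = [
    "WindowSpec",
    "MapRange",
    "MAP_RANGES",
    "AugmentSpec",
    "PairedSlice",
    "DatasetStats",
    "BoundaryError",
    "EmptyMaskError",
    "window_hu",
    "normalize_map",
    "denormalize_map",
    "stack_pseudo_rgb",
    "skull_strip",
    "resize_to",
    "augment",
    "build_training_set",
    "slices_from_case",
]


class BoundaryError(IndexError):
    """Requested slice lacks neighbours at the required vertical offset."""


class EmptyMaskError(ValueError):
    """Skull stripping produced an empty brain mask; case excluded."""


@dataclass(frozen=True)
class WindowSpec:
    """Hounsfield display window (brain window by default)."""

    center: float = 40.0
    width: float = 80.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")


@dataclass(frozen=True)
class MapRange:
    """Physical normalization range of one perfusion-map kind."""

    map_kind: str
    lo: float
    hi: float


#: Canonical normalization ranges mapping physical values to [0, 1].
MAP_RANGES = {
    "cbf": MapRange("cbf", 0.0, 60.0),   # mL/100g/min
    "cbv": MapRange("cbv", 0.0, 4.0),    # mL/100g
    "mtt": MapRange("mtt", 0.0, 12.0),   # s
    "ttp": MapRange("ttp", 0.0, 25.0),   # s
}


@dataclass(frozen=True)
class AugmentSpec:
    """Static augmentation parameters (horizontal flip, rotation, shift)."""

    p_hflip: float = 0.5
    rotation_range: float = 10.0    # degrees, uniform in +-range
    translation_range: int = 30     # pixels, uniform integer in +-range
    copies_per_slice: int = 1


@dataclass
class PairedSlice:
    """One training sample: pseudo-RGB NCCT + four normalized maps."""

    ncct3: np.ndarray           # (3, S, S) in [0, 1]
    maps: dict                  # kind -> (S, S) in [0, 1]
    brain_mask: np.ndarray      # bool (S, S)
    z_index: int
    case_id: str


@dataclass(frozen=True)
class DatasetStats:
    """Training-pool NCCT statistics for input standardization."""

    mean: float
    sd: float


def window_hu(volume, w: WindowSpec = WindowSpec()) -> np.ndarray:
    """Linear HU window: [center - width/2, center + width/2] -> [0, 1]."""
    x = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("non-finite HU values")
    lo = w.center - w.width / 2.0
    return np.clip((x - lo) / w.width, 0.0, 1.0)


def _resolve_range(r) -> MapRange:
    if isinstance(r, str):
        try:
            return MAP_RANGES[r.lower()]
        except KeyError:
            raise KeyError(f"unknown map kind: {r!r}") from None
    return r


def normalize_map(arr, r) -> np.ndarray:
    """Physical units -> [0, 1] via the map kind's canonical range."""
    r = _resolve_range(r)
    x = np.asarray(arr, dtype=np.float64)
    return np.clip((x - r.lo) / (r.hi - r.lo), 0.0, 1.0)


def denormalize_map(arr, r) -> np.ndarray:
    """[0, 1] -> physical units; inverse of :func:`normalize_map` in range."""
    r = _resolve_range(r)
    return np.asarray(arr, dtype=np.float64) * (r.hi - r.lo) + r.lo


def stack_pseudo_rgb(volume, z: int, offset_mm: float = 4.0,
                     axial_spacing: float = 1.0) -> np.ndarray:
    """Stack slices (z - o, z, z + o) as a 3-channel image.

    The offset is rounded to the nearest whole slice; a slice without
    both neighbours raises :class:`BoundaryError` (no silent padding).
    """
    vol = np.asarray(volume)
    o = int(round(offset_mm / axial_spacing))
    if z - o < 0 or z + o >= vol.shape[0]:
        raise BoundaryError(
            f"slice {z} lacks +-{o}-slice neighbours in a {vol.shape[0]}-slice volume"
        )
    return np.stack([vol[z - o], vol[z], vol[z + o]], axis=0)


def skull_strip(windowed, lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    """Brain mask from a windowed [0, 1] NCCT slice.

    Saturated pixels (bone) and near-zero background are thresholded
    away; the largest connected component is kept, speckle removed and
    interior holes (ventricles) filled.  The resulting mask is strictly
    inside the skull ring.
    """
    img = np.asarray(windowed)
    candidates = (img > lo) & (img < hi)
    candidates = ndimage.binary_opening(
        candidates, structure=ndimage.generate_binary_structure(2, 1))
    if not candidates.any():
        raise EmptyMaskError("no brain tissue found after thresholding")
    labels = measure.label(candidates, connectivity=1)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def resize_to(img, size: int = 256, is_mask: bool = False) -> np.ndarray:
    """Resize to (size, size): bilinear for intensities, nearest for masks."""
    img = np.asarray(img)
    if img.shape[-2:] == (size, size):
        return img
    order = 0 if is_mask else 1
    out = transform.resize(img.astype(float), img.shape[:-2] + (size, size),
                           order=order, anti_aliasing=False, preserve_range=True)
    return out.astype(bool) if is_mask else out


def _apply_geom(img: np.ndarray, flip: bool, angle_deg: float,
                shift: tuple, order: int) -> np.ndarray:
    """One rigid transform (flip, rotate about center, translate), zero fill."""
    out = img[:, ::-1] if flip else img
    if angle_deg != 0.0:
        out = ndimage.rotate(out, angle_deg, reshape=False, order=order,
                             cval=0.0, prefilter=False)
    if shift != (0, 0):
        out = ndimage.shift(out, shift, order=0 if order == 0 else 1,
                            cval=0.0, prefilter=False)
    return out


def augment(s: PairedSlice, a: AugmentSpec, rng: np.random.Generator) -> PairedSlice:
    """Apply ONE sampled rigid transform to all channels and the mask."""
    flip = bool(rng.random() < a.p_hflip)
    angle = float(rng.uniform(-a.rotation_range, a.rotation_range))
    shift = (int(rng.integers(-a.translation_range, a.translation_range + 1)),
             int(rng.integers(-a.translation_range, a.translation_range + 1)))
    ncct3 = np.stack([_apply_geom(c, flip, angle, shift, order=1) for c in s.ncct3])
    maps = {k: _apply_geom(v, flip, angle, shift, order=1) for k, v in s.maps.items()}
    mask = _apply_geom(s.brain_mask.astype(np.uint8), flip, angle, shift,
                       order=0).astype(bool)
    return PairedSlice(ncct3=np.clip(ncct3, 0.0, 1.0),
                       maps={k: np.clip(v, 0.0, 1.0) for k, v in maps.items()},
                       brain_mask=mask, z_index=s.z_index, case_id=s.case_id)


def slices_from_case(case, window: WindowSpec = WindowSpec(),
                     offset_mm: float = 4.0, size: int = 256) -> list:
    """Window, strip, resize and stack one phantom/volume case.

    Emits one :class:`PairedSlice` per axial position that has both
    +-offset neighbours; maps are normalized to [0, 1] and masked.
    """
    windowed = window_hu(case.ncct, window)
    o = int(round(offset_mm / case.axial_spacing))
    out = []
    for z in range(o, case.ncct.shape[0] - o):
        ncct3 = stack_pseudo_rgb(windowed, z, offset_mm, case.axial_spacing)
        mask = skull_strip(ncct3[1])
        ncct3 = resize_to(ncct3 * mask[None], size)
        mask_r = resize_to(mask, size, is_mask=True)
        maps = {
            k: resize_to(normalize_map(v[z], k), size) * mask_r
            for k, v in case.maps.items()
        }
        out.append(PairedSlice(ncct3=ncct3, maps=maps, brain_mask=mask_r,
                               z_index=z, case_id=case.case_id))
    return out


def build_training_set(cases, a: AugmentSpec = AugmentSpec(), seed: int = 0,
                       window: WindowSpec = WindowSpec(), offset_mm: float = 4.0,
                       size: int = 256) -> tuple:
    """Static augmentation of preprocessed cases into a training pool.

    Returns ``(samples, stats)`` where each source slice contributes
    ``copies_per_slice`` augmented variants (reproducible per-item
    seeds) and ``stats`` holds the pooled NCCT mean/sd used for
    standardization at the network boundary.
    """
    if not cases:
        raise ValueError("no input cases")
    samples = []
    for ci, case in enumerate(cases):
        base_slices = slices_from_case(case, window, offset_mm, size)
        for s in base_slices:
            for copy in range(a.copies_per_slice):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed,
                                           spawn_key=(ci, s.z_index, copy))
                )
                samples.append(augment(s, a, rng))
    pool = np.stack([s.ncct3 for s in samples])
    stats = DatasetStats(mean=float(pool.mean()), sd=float(pool.std()))
    return samples, stats
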