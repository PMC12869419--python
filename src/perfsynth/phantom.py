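"""Synthetic paired NCCT + perfusion-map brain phantoms.

Each phantom is a small axial stack mimicking the statistical structure
the synthesis network and its evaluation assume: an elliptical brain
inside a high-attenuation skull ring, gray/white tissue compartments
with distinct Hounsfield values and perfusion baselines, elliptical
ventricles, and (optionally) an elliptical ischemic lesion with an
infarct core (relative CBF < 30% of the mirrored contralateral tissue,
reduced CBV, prolonged MTT) inside a penumbra (delayed TTP, preserved
CBV).  The four maps obey the central volume principle

    CBV [mL/100g] = CBF [mL/100g/min] * MTT [s] / 60

exactly before noise, and within noise tolerance after the
multiplicative log-normal map noise.  All maps are zero outside the
brain and lie inside the canonical normalization ranges
(CBF [0,60], CBV [0,4], MTT [0,12], TTP [0,25]).

The NCCT lesion correlate is controlled separately (``ncct_hypodensity``)
and defaults to zero, emulating CT-occult early stroke where the
non-contrast scan shows no visible lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .evaluation import classify_severity, mismatch_ratio

__all__ = [
    "TissueClass",
    "TissueParams",
    "LesionSpec",
    "PhantomSpec",
    "PhantomCase",
    "GeometryError",
    "make_phantom",
    "sample_cohort",
    "save_case",
    "save_cohort",
    "load_case",
]


class GeometryError(ValueError):
    """Lesion geometry is inconsistent with the brain mask."""


@dataclass(frozen=True)
class TissueClass:
    """Hounsfield and perfusion baselines of one tissue compartment."""

    hu: float
    cbf: float   # mL/100g/min
    mtt: float   # s
    ttp: float   # s

    @property
    def cbv(self) -> float:
        return self.cbf * self.mtt / 60.0


@dataclass(frozen=True)
class TissueParams:
    """Normal-tissue parameters.

    Baselines sit in the interiors of the canonical normalization
    ranges (gray-matter CBF ~50, white ~22 mL/100g/min; MTT 4-5 s) --
    typical textbook values, configurable per phantom.
    """

    gray: TissueClass = TissueClass(hu=38.0, cbf=50.0, mtt=4.0, ttp=8.0)
    white: TissueClass = TissueClass(hu=28.0, cbf=22.0, mtt=4.8, ttp=10.0)
    csf: TissueClass = TissueClass(hu=10.0, cbf=2.0, mtt=4.0, ttp=12.0)
    skull_hu: float = 1000.0
    air_hu: float = -1000.0


#: Canonical physical ranges of the four map kinds.
_RANGES = {"cbf": (0.0, 60.0), "cbv": (0.0, 4.0), "mtt": (0.0, 12.0), "ttp": (0.0, 25.0)}


@dataclass(frozen=True)
class LesionSpec:
    """Elliptical ischemic lesion: core strictly inside penumbra.

    ``core_cbf_fraction`` is the core CBF relative to the mirrored
    contralateral tissue and must be below the 30% infarct-core
    threshold; ``penumbra_ttp_delay`` is the TTP prolongation in seconds
    and must exceed the 6 s at-risk threshold.
    """

    center: tuple          # (row, col) pixels
    core_axes: tuple       # (semi_r, semi_c) pixels
    penumbra_axes: tuple
    core_cbf_fraction: float = 0.2
    penumbra_ttp_delay: float = 8.0
    core_cbv_fraction: float = 0.45
    penumbra_cbf_fraction: float = 0.75
    ncct_hypodensity: float = 0.0

    def __post_init__(self):
        if not (0 < self.core_cbf_fraction < 0.30):
            raise ValueError("core_cbf_fraction must be in (0, 0.30)")
        if self.penumbra_ttp_delay <= 6.0:
            raise ValueError("penumbra_ttp_delay must exceed 6 s")
        if not (self.core_axes[0] < self.penumbra_axes[0]
                and self.core_axes[1] < self.penumbra_axes[1]):
            raise ValueError("core axes must be strictly inside penumbra axes")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters of one synthetic subject."""

    image_size: int = 256
    slice_count: int = 11
    axial_spacing: float = 1.0  # mm, NCCT grid
    tissue_params: TissueParams = field(default_factory=TissueParams)
    lesion: LesionSpec | None = None
    noise_sd: float = 3.0       # HU, additive Gaussian on NCCT
    map_noise: float = 0.05     # log-sd of multiplicative log-normal map noise
    seed: int = 0

    def __post_init__(self):
        for tissue in (self.tissue_params.gray, self.tissue_params.white,
                       self.tissue_params.csf):
            if not 0 <= tissue.cbf <= 60:
                raise ValueError("baseline CBF outside [0, 60]")
            if not 0 <= tissue.mtt <= 12:
                raise ValueError("baseline MTT outside [0, 12]")
            if not 0 <= tissue.ttp <= 25:
                raise ValueError("baseline TTP outside [0, 25]")
            if not 0 <= tissue.cbv <= 4:
                raise ValueError("derived CBV outside [0, 4]")


@dataclass
class PhantomCase:
    """One synthetic subject: NCCT, four physical-unit maps, masks."""

    case_id: str
    ncct: np.ndarray                 # (Z, H, W) HU
    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    core_mask: np.ndarray            # bool (Z, H, W)
    penumbra_mask: np.ndarray
    brain_mask: np.ndarray
    severity: str                    # none | mild_moderate | severe
    seed: int
    axial_spacing: float = 1.0

    @property
    def maps(self) -> dict:
        return {"cbf": self.cbf, "cbv": self.cbv, "mtt": self.mtt, "ttp": self.ttp}


def _ellipse(h: int, w: int, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def make_phantom(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Generate one phantom; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    s, z_n = spec.image_size, spec.slice_count
    tp = spec.tissue_params
    center = (s / 2.0, s / 2.0)
    brain_axes = np.array([0.41, 0.345]) * s

    ncct = np.full((z_n, s, s), tp.air_hu, dtype=np.float64)
    maps = {k: np.zeros((z_n, s, s)) for k in _RANGES}
    brain = np.zeros((z_n, s, s), dtype=bool)
    core = np.zeros((z_n, s, s), dtype=bool)
    penumbra = np.zeros((z_n, s, s), dtype=bool)

    zc = (z_n - 1) / 2.0
    for z in range(z_n):
        # slow axial deformation: slices shrink away from the stack center
        scale = 1.0 - 0.25 * ((z - zc) / max(z_n, 2)) ** 2
        ax = brain_axes * scale
        brain_z = _ellipse(s, s, center, ax)
        gap_z = _ellipse(s, s, center, ax + 0.012 * s) & ~brain_z
        skull_z = _ellipse(s, s, center, ax + 0.012 * s + 0.03 * s) & ~brain_z & ~gap_z
        white_z = _ellipse(s, s, center, ax * 0.70) & brain_z
        vent_z = np.zeros_like(brain_z)
        for side in (-1, 1):
            vent_z |= _ellipse(s, s, (center[0], center[1] + side * 0.05 * s),
                               (0.10 * s * scale, 0.03 * s * scale))
        vent_z &= brain_z

        hu = np.full((s, s), tp.air_hu)
        hu[skull_z] = tp.skull_hu
        hu[gap_z] = 0.0  # thin subarachnoid rim, dark on the brain window
        hu[brain_z] = tp.gray.hu
        hu[white_z] = tp.white.hu
        hu[vent_z] = tp.csf.hu

        base = {}
        for k in ("cbf", "mtt", "ttp"):
            f = np.zeros((s, s))
            f[brain_z] = getattr(tp.gray, k)
            f[white_z] = getattr(tp.white, k)
            f[vent_z] = getattr(tp.csf, k)
            # smooth within the brain so tissue transitions are gradual
            f = gaussian_filter(f, sigma=2.0)
            f[~brain_z] = 0.0
            base[k] = f
        base["cbv"] = base["cbf"] * base["mtt"] / 60.0

        if spec.lesion is not None:
            _apply_lesion(spec.lesion, base, hu, brain_z, center[1],
                          core, penumbra, z, s)

        ncct[z] = hu
        brain[z] = brain_z
        for k in _RANGES:
            maps[k][z] = base[k]

    if spec.noise_sd > 0:
        ncct += rng.normal(0.0, spec.noise_sd, ncct.shape)
    if spec.map_noise > 0:
        for k in _RANGES:
            maps[k] *= np.exp(rng.normal(0.0, spec.map_noise, maps[k].shape))
    for k, (lo, hi) in _RANGES.items():
        np.clip(maps[k], lo, hi, out=maps[k])
        maps[k][~brain] = 0.0

    ratio = mismatch_ratio(core, penumbra)
    severity = classify_severity(ratio).label
    return PhantomCase(
        case_id=case_id, ncct=ncct, brain_mask=brain, core_mask=core,
        penumbra_mask=penumbra, severity=severity, seed=spec.seed,
        axial_spacing=spec.axial_spacing, **maps,
    )


def _apply_lesion(lesion: LesionSpec, base: dict, hu: np.ndarray,
                  brain_z: np.ndarray, mid_col: float,
                  core: np.ndarray, penumbra: np.ndarray, z: int, s: int):
    pen_z = _ellipse(s, s, lesion.center, lesion.penumbra_axes)
    core_z = _ellipse(s, s, lesion.center, lesion.core_axes)
    if (pen_z & ~brain_z).any():
        raise GeometryError("penumbra extends outside the brain mask")
    cols = np.nonzero(pen_z.any(axis=0))[0]
    if cols.size and cols.min() <= mid_col <= cols.max():
        raise GeometryError("lesion crosses the mirror midline")

    mirrored = {k: v[:, ::-1] for k, v in base.items()}
    pen_only = pen_z & ~core_z
    # penumbra: delayed TTP, preserved CBV, mildly reduced CBF
    base["ttp"][pen_z] += lesion.penumbra_ttp_delay
    base["cbf"][pen_only] = (lesion.penumbra_cbf_fraction
                             * mirrored["cbf"][pen_only])
    # core: CBF below 30% of contralateral, reduced CBV; MTT follows from
    # the central volume principle and comes out prolonged
    base["cbf"][core_z] = lesion.core_cbf_fraction * mirrored["cbf"][core_z]
    base["cbv"][pen_only] = mirrored["cbv"][pen_only]
    base["cbv"][core_z] = lesion.core_cbv_fraction * mirrored["cbv"][core_z]
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_new = 60.0 * base["cbv"][pen_z] / base["cbf"][pen_z]
    base["mtt"][pen_z] = np.nan_to_num(mtt_new, nan=0.0, posinf=12.0)
    # re-derive CBV from the rounded MTT so the identity is float-exact
    base["cbv"][pen_z] = base["cbf"][pen_z] * base["mtt"][pen_z] / 60.0
    base["ttp"][core_z] += 2.0
    if lesion.ncct_hypodensity:
        hu[core_z] -= lesion.ncct_hypodensity
    core[z] |= core_z
    penumbra[z] |= pen_z


# ---------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------

_CLASSES = ("none", "mild_moderate", "severe")


def sample_cohort(n: int, class_mix=(0.62, 0.17, 0.21), seed: int = 0,
                  image_size: int = 256, slice_count: int = 11,
                  **spec_kwargs) -> list:
    """Draw ``n`` phantoms with severity classes ~ multinomial(class_mix).

    The default mix matches a stroke-referral test cohort oversampled
    for infarction (62% none / 17% mild-moderate / 21% severe).
    Per-case seeds are derived reproducibly from ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be 3 proportions summing to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n, p=mix)
    cases = []
    for i, lab in enumerate(labels):
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = _sample_case(_CLASSES[lab], case_seed, image_size, slice_count,
                            f"case{i:04d}", **spec_kwargs)
        cases.append(case)
    return cases


def _sample_case(target: str, seed: int, image_size: int, slice_count: int,
                 case_id: str, **spec_kwargs) -> PhantomCase:
    rng = np.random.default_rng(seed)
    s = image_size
    for _ in range(20):
        lesion = None
        if target != "none":
            if target == "mild_moderate":
                area_ratio = rng.uniform(0.12, 0.42)
            else:
                area_ratio = rng.uniform(0.58, 0.88)
            pen = (rng.uniform(0.07, 0.11) * s, rng.uniform(0.06, 0.09) * s)
            cr = np.sqrt(area_ratio)
            side = rng.choice((-1, 1))
            # keep the lesion inside one hemisphere, clear of the midline
            col = s / 2.0 + side * (pen[1] + rng.uniform(0.04, 0.10) * s)
            row = s / 2.0 + rng.uniform(-0.08, 0.08) * s
            lesion = LesionSpec(center=(row, col),
                                core_axes=(cr * pen[0], cr * pen[1]),
                                penumbra_axes=pen)
        spec = PhantomSpec(image_size=s, slice_count=slice_count,
                           lesion=lesion, seed=int(rng.integers(0, 2**31 - 1)),
                           **spec_kwargs)
        try:
            case = make_phantom(spec, case_id=case_id)
        except GeometryError:
            continue
        if case.severity == target:
            return case
    raise RuntimeError(f"could not realize severity class {target!r}")


# ---------------------------------------------------------------------
# I/O: NIfTI volumes per map + npz bundle + cohort manifest
# ---------------------------------------------------------------------

def save_case(case: PhantomCase, out_dir) -> Path:
    import nibabel as nib

    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([1.0, 1.0, case.axial_spacing, 1.0])
    volumes = {"ncct": case.ncct, **case.maps,
               "brain_mask": case.brain_mask.astype(np.uint8),
               "core_mask": case.core_mask.astype(np.uint8),
               "penumbra_mask": case.penumbra_mask.astype(np.uint8)}
    for name, vol in volumes.items():
        img = nib.Nifti1Image(np.moveaxis(np.asarray(vol), 0, -1).astype(np.float32),
                              affine)
        nib.save(img, out / f"{name}.nii.gz")
    np.savez_compressed(
        out / "bundle.npz", severity=case.severity, seed=case.seed,
        axial_spacing=case.axial_spacing, **volumes,
    )
    return out


def load_case(case_dir) -> PhantomCase:
    case_dir = Path(case_dir)
    data = np.load(case_dir / "bundle.npz")
    return PhantomCase(
        case_id=case_dir.name, ncct=data["ncct"],
        cbf=data["cbf"], cbv=data["cbv"], mtt=data["mtt"], ttp=data["ttp"],
        core_mask=data["core_mask"].astype(bool),
        penumbra_mask=data["penumbra_mask"].astype(bool),
        brain_mask=data["brain_mask"].astype(bool),
        severity=str(data["severity"]), seed=int(data["seed"]),
        axial_spacing=float(data["axial_spacing"]),
    )


def save_cohort(cases, out_dir) -> Path:
    out = Path(out_dir)
    rows = []
    for case in cases:
        save_case(case, out)
        rows.append({"case_id": case.case_id, "seed": case.seed,
                     "severity": case.severity})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
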