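"""Image-quality metrics and ischemia-severity stratification.

SSIM and UQI are computed in sliding windows over the pair of images,
cropped to the tight bounding box of the brain mask so background does
not inflate the scores.  SSIM uses an 11x11 Gaussian window (sigma 1.5)
with stabilizers c1 = (0.01 L)^2, c2 = (0.03 L)^2 on dynamic range
L = 1 in normalized map space; UQI is the same statistic with zero
stabilizers over an 8x8 uniform window.  Both are symmetric and equal
to 1 on identical images.

Severity follows the mismatch-ratio convention: the infarct-core pixel
count divided by the penumbra pixel count over the whole stack.  A
ratio of 0 is "none", (0, 0.5] "mild_moderate", > 0.5 "severe".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricParams",
    "SeverityClass",
    "EvalReport",
    "brain_bounding_box",
    "ssim",
    "uqi",
    "mismatch_ratio",
    "classify_severity",
    "severity_from_maps",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class MetricParams:
    """Window and stabilizer conventions for SSIM/UQI."""

    dynamic_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    ssim_window: int = 11
    ssim_sigma: float = 1.5   # Gaussian weighting; <= 0 means uniform
    uqi_window: int = 8

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass(frozen=True)
class SeverityClass:
    """Mismatch-ratio severity grade."""

    label: str   # none | mild_moderate | severe
    ratio: float


def brain_bounding_box(brain_mask) -> tuple:
    """Tight axis-aligned box containing all mask pixels.

    Returns ``(rows, cols)`` slices usable to crop a 2-D image.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    rr = np.nonzero(mask.any(axis=1))[0]
    cc = np.nonzero(mask.any(axis=0))[0]
    return slice(rr[0], rr[-1] + 1), slice(cc[0], cc[-1] + 1)


def _window_kernel(size: int, sigma: float) -> np.ndarray:
    if sigma and sigma > 0:
        ax = np.arange(size) - (size - 1) / 2.0
        g = np.exp(-(ax**2) / (2.0 * sigma**2))
        k = np.outer(g, g)
    else:
        k = np.ones((size, size))
    return k / k.sum()


def _window_stats(x: np.ndarray, y: np.ndarray, kernel: np.ndarray):
    """Weighted means/variances/covariance over all valid window positions."""
    k = kernel.shape[0]
    if x.shape[0] < k or x.shape[1] < k:
        raise ValueError(f"image smaller than the {k}x{k} metric window")

    def wmean(img):
        win = np.lib.stride_tricks.sliding_window_view(img, kernel.shape)
        return np.tensordot(win, kernel, axes=([2, 3], [0, 1]))

    mx, my = wmean(x), wmean(y)
    vx = wmean(x * x) - mx * mx
    vy = wmean(y * y) - my * my
    cxy = wmean(x * y) - mx * my
    return mx, my, vx, vy, cxy


def ssim(x, y, p: MetricParams = MetricParams()) -> float:
    """Mean local structural similarity of two same-shape images."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("ssim inputs must share a shape")
    kernel = _window_kernel(p.ssim_window, p.ssim_sigma)
    mx, my, vx, vy, cxy = _window_stats(x, y, kernel)
    c1, c2 = p.c1, p.c2
    num = (2.0 * mx * my + c1) * (2.0 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return float(np.mean(num / den))


def uqi(x, y, p: MetricParams = MetricParams(), tol: float = 1e-12) -> float:
    """Universal quality index: SSIM with zero stabilizing constants.

    Windows where the denominator vanishes contribute 1 when the two
    windows agree (equal means, both constant) and 0 otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("uqi inputs must share a shape")
    kernel = _window_kernel(p.uqi_window, 0.0)
    mx, my, vx, vy, cxy = _window_stats(x, y, kernel)
    num = 4.0 * cxy * mx * my
    den = (vx + vy) * (mx * mx + my * my)
    out = np.empty_like(num)
    ok = np.abs(den) > tol
    out[ok] = num[ok] / den[ok]
    degenerate_equal = ~ok & (np.abs(mx - my) <= 1e-9) & (vx + vy <= tol)
    out[~ok] = np.where(degenerate_equal[~ok], 1.0, 0.0)
    return float(np.mean(out))


def mismatch_ratio(core_mask, penumbra_mask) -> float:
    """Core-to-penumbra pixel ratio summed over all axial slices.

    0/0 is defined as 0 (no lesion); positive core with empty penumbra
    yields +inf (graded severe).
    """
    core = np.asarray(core_mask, dtype=bool)
    pen = np.asarray(penumbra_mask, dtype=bool)
    if core.shape != pen.shape:
        raise ValueError("mask shapes differ")
    n_core, n_pen = int(core.sum()), int(pen.sum())
    if n_pen == 0:
        return 0.0 if n_core == 0 else float("inf")
    return n_core / n_pen


def classify_severity(ratio: float) -> SeverityClass:
    """Grade a mismatch ratio: 0 -> none, (0, 0.5] -> mild_moderate, > 0.5 -> severe."""
    if ratio < 0:
        raise ValueError("mismatch ratio must be non-negative")
    if ratio == 0:
        label = "none"
    elif ratio <= 0.5:
        label = "mild_moderate"
    else:
        label = "severe"
    return SeverityClass(label=label, ratio=float(ratio))


def severity_from_maps(cbf, ttp, brain_mask, cbf_fraction: float = 0.30,
                       ttp_delay: float = 6.0) -> tuple:
    """Threshold-based severity surrogate from CBF/TTP volumes.

    Core: CBF below ``cbf_fraction`` of the mirrored contralateral
    median; penumbra: TTP exceeding the contralateral median by more
    than ``ttp_delay`` seconds.  Masks are evaluated within the brain.
    Returns ``(severity, core_mask, penumbra_mask)``.
    """
    cbf = np.asarray(cbf, dtype=float)
    ttp = np.asarray(ttp, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    cbf_m = cbf[..., ::-1]
    ttp_med = np.median(ttp[brain]) if brain.any() else 0.0
    core = brain & (cbf < cbf_fraction * cbf_m)
    pen = brain & (ttp > ttp_med + ttp_delay)
    pen |= core
    sev = classify_severity(mismatch_ratio(core, pen))
    return sev, core, pen


@dataclass
class EvalReport:
    """Cohort evaluation: per-case/per-map metrics plus stratified summaries."""

    table: pd.DataFrame                 # case_id, map_kind, ssim, uqi, ratio, severity
    by_severity: pd.DataFrame
    by_lesion_presence: pd.DataFrame

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def evaluate_cohort(predicted: dict, reference, p: MetricParams = MetricParams(),
                    normalized: bool = True) -> EvalReport:
    """Score predicted maps against reference phantom cases.

    ``predicted`` maps case_id -> {map_kind -> (Z, H, W) volume in
    normalized [0, 1] map space}; ``reference`` is a list of phantom
    cases.  SSIM/UQI are computed per axial slice inside the brain
    bounding box and averaged per case and map kind.  Predicted slices
    may cover only an interior sub-stack; they are aligned to the
    reference by trailing position.
    """
    from .preprocessing import normalize_map

    ref_by_id = {c.case_id: c for c in reference}
    missing = set(predicted) - set(ref_by_id)
    if missing:
        raise KeyError(f"predictions without a reference case: {sorted(missing)}")
    rows = []
    for case_id, maps in predicted.items():
        ref = ref_by_id[case_id]
        ratio = mismatch_ratio(ref.core_mask, ref.penumbra_mask)
        severity = classify_severity(ratio).label
        for kind, pred_vol in maps.items():
            ref_vol = ref.maps[kind] if not normalized else normalize_map(
                ref.maps[kind], kind)
            pred_vol = np.asarray(pred_vol, dtype=float)
            z0 = ref_vol.shape[0] - pred_vol.shape[0]
            if z0 < 0:
                raise ValueError(f"{case_id}/{kind}: more predicted than reference slices")
            off = z0 // 2
            ss, uu = [], []
            for zi in range(pred_vol.shape[0]):
                z_ref = zi + off
                box = brain_bounding_box(ref.brain_mask[z_ref])
                ss.append(ssim(pred_vol[zi][box], ref_vol[z_ref][box], p))
                uu.append(uqi(pred_vol[zi][box], ref_vol[z_ref][box], p))
            rows.append({"case_id": case_id, "map_kind": kind,
                         "ssim": float(np.mean(ss)), "uqi": float(np.mean(uu)),
                         "ratio": ratio, "severity": severity})
    table = pd.DataFrame(rows)
    table["lesion"] = np.where(table["ratio"] > 0, "ratio>0", "ratio=0")
    agg = {"ssim": ["mean", "std"], "uqi": ["mean", "std"], "case_id": "nunique"}
    by_sev = table.groupby(["map_kind", "severity"]).agg(agg)
    by_les = table.groupby(["map_kind", "lesion"]).agg(agg)
    return EvalReport(table=table, by_severity=by_sev, by_lesion_presence=by_les)
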