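"""SSIM/UQI against loop oracles and skimage; severity stratification."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from perfsynth.evaluation import (MetricParams, brain_bounding_box,
                                  classify_severity, evaluate_cohort,
                                  mismatch_ratio, severity_from_maps, ssim, uqi)
from perfsynth.preprocessing import normalize_map

RNG = np.random.default_rng(55)


# ---------------------------------------------------------------------
# Direct sliding-window oracles
# ---------------------------------------------------------------------

def _gauss_kernel(size, sigma):
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def oracle_ssim(x, y, p: MetricParams):
    k = _gauss_kernel(p.ssim_window, p.ssim_sigma)
    n = p.ssim_window
    vals = []
    for i in range(x.shape[0] - n + 1):
        for j in range(x.shape[1] - n + 1):
            wx, wy = x[i:i + n, j:j + n], y[i:i + n, j:j + n]
            mx, my = (k * wx).sum(), (k * wy).sum()
            vx = (k * wx * wx).sum() - mx**2
            vy = (k * wy * wy).sum() - my**2
            cxy = (k * wx * wy).sum() - mx * my
            vals.append(((2 * mx * my + p.c1) * (2 * cxy + p.c2))
                        / ((mx**2 + my**2 + p.c1) * (vx + vy + p.c2)))
    return float(np.mean(vals))


def oracle_uqi(x, y, p: MetricParams):
    n = p.uqi_window
    vals = []
    for i in range(x.shape[0] - n + 1):
        for j in range(x.shape[1] - n + 1):
            wx, wy = x[i:i + n, j:j + n], y[i:i + n, j:j + n]
            mx, my = wx.mean(), wy.mean()
            vx, vy = (wx * wx).mean() - mx**2, (wy * wy).mean() - my**2
            cxy = (wx * wy).mean() - mx * my
            den = (vx + vy) * (mx**2 + my**2)
            if abs(den) > 1e-12:
                vals.append(4 * cxy * mx * my / den)
            else:
                vals.append(1.0 if abs(mx - my) <= 1e-9 and vx + vy <= 1e-12 else 0.0)
    return float(np.mean(vals))


class TestBoundingBox:
    def test_full_frame_mask_gives_full_image_box(self):
        rows, cols = brain_bounding_box(np.ones((5, 7), dtype=bool))
        assert (rows, cols) == (slice(0, 5), slice(0, 7))

    def test_single_pixel_gives_1x1_box(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 4] = True
        rows, cols = brain_bounding_box(mask)
        assert (rows, cols) == (slice(2, 3), slice(4, 5))

    def test_phantom_box_excludes_background_corners(self, small_case):
        rows, cols = brain_bounding_box(small_case.brain_mask[5])
        assert rows.start > 0 and cols.start > 0
        assert rows.stop < 64 and cols.stop < 64

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            brain_bounding_box(np.zeros((4, 4), dtype=bool))


class TestSsim:
    def test_identity_is_one(self):
        x = RNG.random((24, 24))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        x, y = RNG.random((20, 20)), RNG.random((20, 20))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_matches_sliding_window_oracle_on_16x16(self):
        p = MetricParams()
        for _ in range(5):
            x, y = RNG.random((16, 16)), RNG.random((16, 16))
            assert ssim(x, y, p) == pytest.approx(oracle_ssim(x, y, p), abs=1e-10)

    def test_binary_inversion_matches_oracle(self):
        p = MetricParams()
        x = (RNG.random((16, 16)) > 0.5).astype(float)
        assert ssim(x, 1.0 - x, p) == pytest.approx(oracle_ssim(x, 1.0 - x, p),
                                                    abs=1e-10)

    def test_constant_pair_equal_via_stabilizers(self):
        x = np.full((16, 16), 0.4)
        assert ssim(x, x.copy()) == pytest.approx(1.0)

    def test_matches_skimage_reference(self):
        x, y = RNG.random((32, 32)), RNG.random((32, 32))
        ours = ssim(x, y)
        ref = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=1.0)
        assert ours == pytest.approx(ref, abs=1e-4)

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestUqi:
    def test_identity_is_one(self):
        x = RNG.random((20, 20))
        assert uqi(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        x, y = RNG.random((16, 16)), RNG.random((16, 16))
        assert uqi(x, y) == pytest.approx(uqi(y, x), abs=1e-12)

    def test_matches_loop_oracle(self):
        p = MetricParams()
        for _ in range(5):
            x, y = RNG.random((16, 16)), RNG.random((16, 16))
            assert uqi(x, y, p) == pytest.approx(oracle_uqi(x, y, p), abs=1e-10)

    def test_equals_ssim_with_zero_stabilizers_and_uniform_window(self):
        x = RNG.random((16, 16)) + 0.5   # keep window stats away from zero
        y = x + RNG.normal(0, 0.05, x.shape)
        p_uqi = MetricParams(uqi_window=8)
        p_ssim = MetricParams(k1=0.0, k2=0.0, ssim_window=8, ssim_sigma=0.0)
        assert uqi(x, y, p_uqi) == pytest.approx(ssim(x, y, p_ssim), abs=1e-10)

    def test_constant_equal_windows_contribute_one(self):
        x = np.full((12, 12), 0.3)
        assert uqi(x, x.copy()) == pytest.approx(1.0)

    def test_constant_unequal_windows_contribute_zero(self):
        x = np.full((12, 12), 0.3)
        assert uqi(x, x + 0.2) == pytest.approx(0.0)


class TestMonotoneDegradation:
    def test_metrics_non_increasing_with_noise_level(self, small_case):
        ref = normalize_map(small_case.cbf[5], "cbf")
        box = brain_bounding_box(small_case.brain_mask[5])
        ref = ref[box]
        levels = [0.0, 0.02, 0.05, 0.1, 0.2]
        med_ssim, med_uqi = [], []
        for sd in levels:
            ss, uu = [], []
            for seed in range(20):
                noisy = ref + np.random.default_rng(seed).normal(0, sd, ref.shape)
                ss.append(ssim(ref, noisy))
                uu.append(uqi(ref, noisy))
            med_ssim.append(np.median(ss))
            med_uqi.append(np.median(uu))
        assert all(a >= b - 1e-9 for a, b in zip(med_ssim, med_ssim[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(med_uqi, med_uqi[1:]))


class TestSeverity:
    def test_mismatch_ratio_examples(self):
        z = np.zeros((2, 4, 4), dtype=bool)
        pen = z.copy()
        pen[:, :2] = True
        assert mismatch_ratio(z, pen) == 0.0
        core = z.copy()
        core[0, 0, :2] = True
        assert mismatch_ratio(pen, pen) == 1.0
        assert mismatch_ratio(core, z) == np.inf

    def test_hand_ratio_04(self):
        core = np.zeros(1000, dtype=bool)
        pen = np.zeros(1000, dtype=bool)
        core[:100] = True
        pen[:250] = True
        assert mismatch_ratio(core, pen) == pytest.approx(0.4)

    @pytest.mark.parametrize("ratio,label", [
        (0.0, "none"), (0.5, "mild_moderate"), (0.51, "severe"),
        (0.001, "mild_moderate"), (np.inf, "severe"),
    ])
    def test_classification_thresholds(self, ratio, label):
        assert classify_severity(ratio).label == label

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(-0.1)

    def test_threshold_surrogate_recovers_phantom_severity(self, lesion_case):
        sev, core, pen = severity_from_maps(lesion_case.cbf, lesion_case.ttp,
                                            lesion_case.brain_mask)
        assert sev.label == lesion_case.severity
        # detected core should overlap the simulated one substantially
        truth = lesion_case.core_mask
        overlap = (core & truth).sum() / truth.sum()
        assert overlap > 0.6


class TestEvaluateCohort:
    def test_perfect_predictions_score_one_everywhere(self, small_case):
        refs = [small_case]
        preds = {small_case.case_id: {
            k: normalize_map(v, k) for k, v in small_case.maps.items()}}
        report = evaluate_cohort(preds, refs)
        assert np.allclose(report.table["ssim"], 1.0)
        assert np.allclose(report.table["uqi"], 1.0)
        assert set(report.table["severity"]) == {small_case.severity}

    def test_stratum_sizes_match_labels(self, small_case):
        refs = [small_case]
        preds = {small_case.case_id: {
            k: normalize_map(v, k) for k, v in small_case.maps.items()}}
        report = evaluate_cohort(preds, refs)
        assert (report.table["lesion"] == "ratio>0").all()

    def test_unpaired_prediction_rejected(self, small_case):
        with pytest.raises(KeyError):
            evaluate_cohort({"nonexistent": {}}, [small_case])
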