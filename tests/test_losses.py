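"""Objective terms against naive loop oracles and finite differences."""

import numpy as np
import pytest

from perfsynth._autodiff import Tensor
from perfsynth.losses import (LossWeights, extrema_loss, extrema_weight_map,
                              gan_loss, l1_loss, multimodal_loss,
                              total_objective)

RNG = np.random.default_rng(77)
EPS = 1e-7


# ---------------------------------------------------------------------
# Naive loop oracles (kept deliberately dumb and independent)
# ---------------------------------------------------------------------

def oracle_l1(pairs):
    acc = 0.0
    for gen, ref in pairs:
        total, n = 0.0, 0
        for g, r in zip(gen.ravel(), ref.ravel()):
            total += abs(g - r)
            n += 1
        acc += total / n
    return acc / len(pairs)


def oracle_multimodal(cbf, mtt, cbv):
    total, n = 0.0, 0
    for a, b, c in zip(cbf.ravel(), mtt.ravel(), cbv.ravel()):
        total += abs(a * b - c)
        n += 1
    return total / n


def oracle_minmax(img, eps=EPS):
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo + eps)


def oracle_extrema(pairs, eps=EPS):
    acc = 0.0
    for gen, ref in pairs:
        w = (oracle_minmax(ref, eps) - 0.5) ** 2
        h = (oracle_minmax(gen, eps) - oracle_minmax(ref, eps)) ** 2
        total, n = 0.0, 0
        for wv, hv in zip(w.ravel(), h.ravel()):
            total += wv * hv
            n += 1
        acc += total / n
    return acc / len(pairs)


def oracle_gan_d(pairs, eps=EPS):
    acc = 0.0
    for real, fake in pairs:
        tr = tf = 0.0
        for v in np.clip(real, eps, 1 - eps).ravel():
            tr += np.log(v)
        for v in np.clip(fake, eps, 1 - eps).ravel():
            tf += np.log(1 - v)
        acc += -(tr / real.size + tf / fake.size)
    return acc / len(pairs)


# ---------------------------------------------------------------------
# Closed-form and hand cases
# ---------------------------------------------------------------------

class TestGanLoss:
    def test_uninformative_discriminator_gives_2_ln_2(self):
        half = np.full((2, 1, 3, 3), 0.5)
        loss_d, loss_g = gan_loss(half, half)
        assert float(loss_d) == pytest.approx(2 * np.log(2), abs=1e-12)
        assert float(loss_g) == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_discriminator_loss_tends_to_zero(self):
        real = np.full((1, 1, 4, 4), 1.0 - 1e-7)
        fake = np.full((1, 1, 4, 4), 1e-7)
        loss_d, _ = gan_loss(real, fake)
        assert float(loss_d) < 1e-5

    def test_patch_map_matches_scalar_brute_force(self):
        for _ in range(100):
            real = RNG.uniform(0.01, 0.99, (2, 1, 3, 3))
            fake = RNG.uniform(0.01, 0.99, (2, 1, 3, 3))
            pairs = [(real, fake), (fake, real)]
            loss_d, _ = gan_loss([p[0] for p in pairs], [p[1] for p in pairs])
            assert float(loss_d) == pytest.approx(oracle_gan_d(pairs), abs=1e-12)

    def test_saturating_flag_changes_generator_side(self):
        fake = np.full((1, 1, 2, 2), 0.3)
        real = np.full((1, 1, 2, 2), 0.7)
        _, g_ns = gan_loss(real, fake, non_saturating=True)
        _, g_sat = gan_loss(real, fake, non_saturating=False)
        assert float(g_ns) == pytest.approx(-np.log(0.3), abs=1e-9)
        assert float(g_sat) == pytest.approx(np.log(0.7), abs=1e-9)


class TestL1Loss:
    def test_identity_is_zero(self):
        x = RNG.random((2, 1, 8, 8))
        assert float(l1_loss(x, x)) == 0.0

    def test_constant_offset(self):
        x = RNG.uniform(0.0, 0.8, (2, 1, 8, 8))
        assert float(l1_loss(x + 0.1, x)) == pytest.approx(0.1, abs=1e-12)

    def test_matches_loop_oracle_on_random_batches(self):
        for _ in range(100):
            pairs = [(RNG.random((8, 8)), RNG.random((8, 8))) for _ in range(4)]
            got = float(l1_loss([p[0] for p in pairs], [p[1] for p in pairs]))
            assert got == pytest.approx(oracle_l1(pairs), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestMultimodalLoss:
    def test_consistent_triple_is_zero(self):
        ones = np.ones((4, 4))
        assert float(multimodal_loss(ones, ones, ones)) == 0.0

    def test_zero_cbf_gives_cbv_mean(self):
        z = np.zeros((4, 4))
        c = np.full((4, 4), 0.37)
        assert float(multimodal_loss(z, z, c)) == pytest.approx(0.37, abs=1e-12)

    def test_matches_loop_oracle(self):
        for _ in range(100):
            a, b, c = (RNG.random((8, 8)) for _ in range(3))
            assert float(multimodal_loss(a, b, c)) == pytest.approx(
                oracle_multimodal(a, b, c), abs=1e-12)

    def test_consistency_factor_applies(self):
        a = np.full((2, 2), 0.5)
        assert float(multimodal_loss(a, a, a, consistency_factor=3.0)) == (
            pytest.approx(abs(3 * 0.25 - 0.5), abs=1e-12))


class TestExtremaWeightMap:
    def test_hand_case_three_levels(self):
        w = extrema_weight_map(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(w.data, [0.25, 0.0, 0.25], atol=1e-6)

    def test_midpoint_pixel_has_zero_weight(self):
        w = extrema_weight_map(np.array([0.2, 0.5, 0.8]))
        assert float(w.data[1]) == pytest.approx(0.0, abs=1e-6)

    def test_affine_rescaling_invariance(self):
        pm = RNG.random((8, 8))
        a = extrema_weight_map(pm).data
        b = extrema_weight_map(3.0 * pm + 2.0).data
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_constant_map_gives_zero_weights(self):
        w = extrema_weight_map(np.full((4, 4), 0.3))
        np.testing.assert_allclose(w.data, 0.0, atol=1e-12)


class TestExtremaLoss:
    def test_identity_is_zero(self):
        x = RNG.random((8, 8))
        assert float(extrema_loss(x, x)) == pytest.approx(0.0, abs=1e-12)

    def test_positive_affine_transform_is_zero(self):
        x = RNG.random((8, 8))
        assert float(extrema_loss(2.0 * x + 0.3, x)) == pytest.approx(0.0, abs=1e-6)

    def test_matches_loop_oracle(self):
        for _ in range(100):
            pairs = [(RNG.random((8, 8)), RNG.random((8, 8))) for _ in range(4)]
            got = float(extrema_loss([p[0] for p in pairs], [p[1] for p in pairs]))
            assert got == pytest.approx(oracle_extrema(pairs), abs=1e-12)

    def test_error_at_extremes_weighs_more_than_at_midpoint(self):
        ref = np.linspace(0.0, 1.0, 64).reshape(8, 8)
        err = 0.2
        at_extreme = ref.copy()
        at_extreme[0, 0] += err          # pixel at the minimum
        at_mid = ref.copy()
        at_mid[3, 7] += err              # pixel near the midpoint (value ~0.5)
        assert float(extrema_loss(at_extreme, ref)) > float(extrema_loss(at_mid, ref))


class TestTotalObjective:
    def test_pure_gan_when_lambdas_zero(self):
        w = LossWeights(lambda1=0, lambda2=0, lambda3=0)
        rep = total_objective(0.7, 0.5, 0.5, 0.5, w)
        assert rep.total_G == pytest.approx(0.7)

    def test_weighted_combination_arithmetic(self):
        w = LossWeights(lambda1=100, lambda2=0, lambda3=0)
        rep = total_objective(0.7, 0.1, 0.0, 0.0, w)
        assert rep.total_G == pytest.approx(10.7)

    def test_perfect_generator_against_uninformative_discriminator(self):
        w = LossWeights()
        rep = total_objective(-np.log(0.5), 0.0, 0.0, 0.0, w, gan_D=2 * np.log(2))
        assert rep.total_G == pytest.approx(-np.log(0.5))
        assert rep.total_D == pytest.approx(2 * np.log(2))

    def test_negative_lambdas_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-1)


# ---------------------------------------------------------------------
# Gradients and properties
# ---------------------------------------------------------------------

def _fd_check(f, x: Tensor, rtol=1e-4, h=1e-6):
    f(x).backward()
    g = x.grad.copy()
    for _ in range(6):
        idx = tuple(RNG.integers(0, s) for s in x.shape)
        x.data[idx] += h
        up = float(f(x).data)
        x.data[idx] -= 2 * h
        dn = float(f(x).data)
        x.data[idx] += h
        num = (up - dn) / (2 * h)
        assert abs(num - g[idx]) <= rtol * (1.0 + abs(num)), (num, g[idx])


class TestGradients:
    def test_l1_gradient(self):
        ref = RNG.random((4, 4))
        x = Tensor(RNG.random((4, 4)), requires_grad=True)
        _fd_check(lambda t: l1_loss(t, Tensor(ref)), x)

    def test_multimodal_gradient(self):
        mtt = RNG.random((4, 4))
        cbv = RNG.random((4, 4))
        x = Tensor(RNG.random((4, 4)), requires_grad=True)
        _fd_check(lambda t: multimodal_loss(t, Tensor(mtt), Tensor(cbv)), x)

    def test_extrema_gradient(self):
        ref = RNG.random((4, 4))
        x = Tensor(RNG.random((4, 4)), requires_grad=True)
        _fd_check(lambda t: extrema_loss(t, Tensor(ref)), x)

    def test_gan_generator_gradient_through_probabilities(self):
        x = Tensor(RNG.uniform(0.1, 0.9, (4, 4)), requires_grad=True)

        def f(t):
            _, g = gan_loss(Tensor(np.full((4, 4), 0.8)), t)
            return g

        _fd_check(f, x)


class TestNonNegativity:
    @pytest.mark.parametrize("trial", range(10))
    def test_all_auxiliary_losses_non_negative(self, trial):
        rng = np.random.default_rng(trial)
        a, b, c = (rng.random((6, 6)) for _ in range(3))
        assert float(l1_loss(a, b)) >= 0
        assert float(extrema_loss(a, b)) >= 0
        assert float(multimodal_loss(a, b, c)) >= 0
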