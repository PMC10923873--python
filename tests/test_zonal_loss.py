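"""Zonal loss: hand-evaluated values, an independent per-voxel scalar
oracle, the forbidden-pattern suppression property, and autodiff parity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symzone import nn
from symzone.zonal_loss import (LossConfig, constrain_probs, focal_loss_binary,
                                focal_loss_binary_t, modified_ce, zonal_loss,
                                zonal_loss_t)


from tests._oracle import scalar_zonal_loss as scalar_loss_oracle


def _single(p0, p1, m0, m1):
    return (np.array([[[[p0]]], [[[p1]]]]), np.array([[[[m0]]], [[[m1]]]]))


class TestConstraints:
    def test_max_rule_background(self):
        p, m = np.array([0.3, 0.6]).reshape(2, 1), np.array([0, 0]).reshape(2, 1)
        np.testing.assert_allclose(constrain_probs(p, m).ravel(), [0.6, 0.6])

    def test_min_rule_tz_lesion(self):
        p, m = np.array([0.2, 0.8]).reshape(2, 1), np.array([1, 1]).reshape(2, 1)
        np.testing.assert_allclose(constrain_probs(p, m).ravel(), [0.2, 0.2])

    def test_pz_lesion_passthrough(self):
        p, m = np.array([0.9, 0.1]).reshape(2, 1), np.array([1, 0]).reshape(2, 1)
        np.testing.assert_allclose(constrain_probs(p, m).ravel(), [0.9, 0.1])

    def test_forbidden_label_raises(self):
        p, m = np.array([0.5, 0.5]).reshape(2, 1), np.array([0, 1]).reshape(2, 1)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            constrain_probs(p, m)


class TestHandValues:
    def test_background_with_inconsistent_prediction(self):
        p, m = _single(0.3, 0.6, 0, 0)
        assert modified_ce(p, m) == pytest.approx(2 * -math.log(0.4), abs=1e-5)

    def test_tz_lesion_focal(self):
        p, m = _single(0.5, 0.5, 1, 1)
        got = zonal_loss(p, m, LossConfig(gamma=2.0))
        assert got == pytest.approx(2 * 0.25 * -math.log(0.5), abs=1e-5)

    def test_pz_lesion_constraints_inactive(self):
        p, m = _single(0.8, 0.3, 1, 0)
        expected = -math.log(0.8) - math.log(0.7)
        assert modified_ce(p, m) == pytest.approx(expected, abs=1e-5)

    def test_perfect_prediction_is_zero_up_to_eps(self):
        p, m = _single(1.0, 1.0, 1, 1)
        assert zonal_loss(p, m, LossConfig(gamma=0.0)) == pytest.approx(0.0, abs=1e-5)

    def test_binary_focal_hand_value(self):
        p = np.array([[0.5]])
        m = np.array([[1]])
        got = focal_loss_binary(p, m, LossConfig(gamma=2.0))
        assert got == pytest.approx(0.25 * -math.log(0.5), abs=1e-5)
        assert focal_loss_binary(np.array([[1.0]]), np.array([[1]]),
                                 LossConfig(gamma=2.0)) == pytest.approx(0, abs=1e-5)
        assert focal_loss_binary(np.array([[0.0]]), np.array([[0]]),
                                 LossConfig(gamma=2.0)) == pytest.approx(0, abs=1e-5)


def _random_instance(rng):
    p = rng.uniform(0, 1, size=(2, 4, 8, 8))
    zone = rng.integers(0, 3, size=(4, 8, 8))  # 0 bg, 1 pz-lesion, 2 tz-lesion
    m = np.stack([(zone >= 1).astype(int), (zone == 2).astype(int)])
    return p, m


def test_vectorized_loss_matches_scalar_oracle(rng):
    """100 random (2,4,8,8) instances agree with the per-voxel loop to 1e-6."""
    for k in range(100):
        p, m = _random_instance(rng)
        gamma = [0.0, 1.0, 2.0][k % 3]
        got = zonal_loss(p, m, LossConfig(gamma=gamma))
        want = scalar_loss_oracle(p, m, gamma)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-6)


def test_gamma_zero_reduces_to_modified_ce(rng):
    p, m = _random_instance(rng)
    assert zonal_loss(p, m, LossConfig(gamma=0.0)) == modified_ce(p, m)
    # plain binary CE from the focal baseline at gamma = 0
    pb = rng.uniform(0.01, 0.99, size=(1, 4, 4))
    mb = rng.integers(0, 2, size=(1, 4, 4))
    want = float(-(mb * np.log(pb) + (1 - mb) * np.log(1 - pb)).sum())
    assert focal_loss_binary(pb, mb, LossConfig(gamma=0.0)) == pytest.approx(
        want, rel=1e-9)


def test_suppression_strictly_penalizes_p1_above_p0():
    """For background voxels the loss rises strictly in p1 once p1 > p0."""
    p0 = 0.4
    grid = np.linspace(0.41, 0.99, 30)
    for gamma in (0.0, 2.0):
        losses = [
            zonal_loss(*_single(p0, p1, 0, 0), LossConfig(gamma=gamma))
            for p1 in grid
        ]
        assert np.all(np.diff(losses) > 0)
    # the constraint doubles the marginal penalty above p0: channel 0's
    # max() starts tracking p1 on top of channel 1's own term
    def slope(p1):
        h = 1e-4
        f = lambda q: zonal_loss(*_single(p0, q, 0, 0), LossConfig(gamma=0.0))
        return (f(p1 + h) - f(p1 - h)) / (2 * h)

    assert slope(0.6) > 1.5 * slope(0.2)


def test_tz_lesion_loss_nonincreasing_in_p1_below_p0():
    """For m=[1,1] the min() makes the loss flat/decreasing while p1 < p0."""
    p0 = 0.8
    grid = np.linspace(0.05, 0.79, 25)
    losses = [
        zonal_loss(*_single(p0, p1, 1, 1), LossConfig(gamma=2.0)) for p1 in grid
    ]
    assert np.all(np.diff(losses) <= 1e-12)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 10**6))
def test_loss_invariant_to_voxel_permutation(seed):
    rng = np.random.default_rng(seed)
    p, m = _random_instance(rng)
    perm = rng.permutation(p[0].size)
    p_perm = p.reshape(2, -1)[:, perm].reshape(p.shape)
    m_perm = m.reshape(2, -1)[:, perm].reshape(m.shape)
    cfg = LossConfig(gamma=2.0)
    assert zonal_loss(p, m, cfg) == pytest.approx(zonal_loss(p_perm, m_perm, cfg),
                                                  rel=1e-9)


def test_autodiff_loss_matches_numpy_and_finite_difference(rng):
    p, m = _random_instance(rng)
    p = p.astype(np.float32)[None]
    mb = m[None]
    cfg = LossConfig(gamma=2.0)
    pt = nn.Tensor(p, requires_grad=True)
    loss = zonal_loss_t(pt, mb, cfg)
    assert loss.item() == pytest.approx(zonal_loss(p[0], m, cfg), rel=1e-4)
    loss.backward()
    # finite differences away from max/min tie points
    eps = 1e-3
    flat = p.copy()
    checked = 0
    for idx in [(0, 0, 1, 2, 3), (0, 1, 3, 4, 5), (0, 0, 2, 7, 7)]:
        if abs(p[idx[0], 0, idx[2], idx[3], idx[4]]
               - p[idx[0], 1, idx[2], idx[3], idx[4]]) < 0.05:
            continue
        up, dn = flat.copy(), flat.copy()
        up[idx] += eps
        dn[idx] -= eps
        num = (zonal_loss_t(nn.Tensor(up), mb, cfg).item()
               - zonal_loss_t(nn.Tensor(dn), mb, cfg).item()) / (2 * eps)
        assert pt.grad[idx] == pytest.approx(num, rel=5e-2, abs=1e-3)
        checked += 1
    assert checked > 0


def test_binary_focal_autodiff_matches_numpy(rng):
    p = rng.uniform(0.05, 0.95, size=(1, 1, 4, 4, 4)).astype(np.float32)
    m = rng.integers(0, 2, size=(1, 1, 4, 4, 4)).astype(np.float32)
    cfg = LossConfig(gamma=2.0)
    got = focal_loss_binary_t(nn.Tensor(p), m, cfg).item()
    assert got == pytest.approx(focal_loss_binary(p[0], m[0], cfg), rel=1e-4)


def test_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="shape"):
        zonal_loss(np.zeros((2, 2, 2, 2)), np.zeros((2, 2, 2, 3), dtype=int))


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(gamma=-1.0)
    with pytest.raises(ValueError):
        LossConfig(eps=0.1)
    with pytest.raises(ValueError):
        LossConfig(reduction="median")
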