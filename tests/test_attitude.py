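"""Euler-angle kinematics, roll/pitch EKF, yaw integration, gravity removal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from stancecom import (EkfConfig, ImuSeries, STANDARD_GRAVITY, euler_to_matrix,
                       estimate_roll_pitch, integrate_yaw, transform_accel)
from stancecom.attitude import AttitudeSeries, vertical_rate

G = STANDARD_GRAVITY
FS = 100.0
angles = st.floats(min_value=-np.pi, max_value=np.pi)


def test_zero_angles_give_identity():
    np.testing.assert_allclose(euler_to_matrix(0, 0, 0), np.eye(3), atol=1e-15)


def test_pure_yaw_quarter_turn():
    T = euler_to_matrix(np.pi / 2, 0, 0)
    np.testing.assert_allclose(T @ [1, 0, 0], [0, 1, 0], atol=1e-15)


@given(angles, angles, angles)
@settings(max_examples=100, deadline=None)
def test_rotation_group_properties(psi, theta, phi):
    T = euler_to_matrix(psi, theta, phi)
    np.testing.assert_allclose(T.T @ T, np.eye(3), atol=1e-12)
    assert np.linalg.det(T) == pytest.approx(1.0, abs=1e-12)


def test_matches_scipy_zyx_convention(rng):
    """Independent oracle: intrinsic Z-Y-X rotation from scipy."""
    eul = rng.uniform(-np.pi, np.pi, size=(50, 3))
    ours = euler_to_matrix(eul[:, 0], eul[:, 1], eul[:, 2])
    ref = Rotation.from_euler("ZYX", eul).as_matrix()
    np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_batch_orthonormality(rng):
    eul = rng.uniform(-np.pi, np.pi, size=(1000, 3))
    T = euler_to_matrix(eul[:, 0], eul[:, 1], eul[:, 2])
    eye = np.einsum("nij,nik->njk", T, T)
    assert np.abs(eye - np.eye(3)).max() < 1e-12
    assert np.abs(np.linalg.det(T) - 1).max() < 1e-12


# ---------------------------------------------------------------------------
# EKF roll/pitch


def _static_imu(phi, theta, n, placement="thigh"):
    T = euler_to_matrix(0.0, theta, phi)
    f = np.tile(T.T @ [0, 0, G], (n, 1))
    return ImuSeries(np.arange(n) / FS, f, np.zeros((n, 3)), placement)


def test_level_stationary_sensor():
    att = estimate_roll_pitch(_static_imu(0.0, 0.0, 300))
    np.testing.assert_allclose(att.theta, 0.0, atol=1e-12)
    np.testing.assert_allclose(att.phi, 0.0, atol=1e-12)


@pytest.mark.parametrize("theta_true", [np.deg2rad(5), np.deg2rad(-12)])
def test_constant_tilt_convergence(theta_true):
    """Noiseless static tilt is recovered to < 1e-3 rad within a second."""
    att = estimate_roll_pitch(_static_imu(0.0, theta_true, 300))
    assert np.abs(att.theta[100:] - theta_true).max() < 1e-3
    assert np.abs(att.phi[100:]).max() < 1e-3


def test_oscillating_tilt_tracked():
    """+-2 deg pitch wobble at 0.3 Hz, sensor on the rotation axis:
    consistent noiseless gyro/accel streams are tracked to < 0.2 deg."""
    n = int(30 * FS)
    t = np.arange(n) / FS
    amp = np.deg2rad(2.0)
    theta = amp * np.sin(2 * np.pi * 0.3 * t)
    theta_dot = amp * 2 * np.pi * 0.3 * np.cos(2 * np.pi * 0.3 * t)
    T = euler_to_matrix(np.zeros(n), theta, np.zeros(n))
    f = np.einsum("nij,j->ni", np.swapaxes(T, 1, 2), [0, 0, G])
    w = np.einsum("nij,nj->ni", np.swapaxes(T, 1, 2),
                  np.column_stack([np.zeros(n), theta_dot, np.zeros(n)]))
    att = estimate_roll_pitch(ImuSeries(t, f, w, "thigh"))
    rmse = np.sqrt(np.mean((att.theta[200:] - theta[200:]) ** 2))
    assert rmse < np.deg2rad(0.2)


def test_free_fall_flagged_and_coasts():
    n = 200
    f = np.zeros((n, 3))
    f[:50] = [0, 0, G]  # quiet start, then the specific force collapses
    imu = ImuSeries(np.arange(n) / FS, f, np.zeros((n, 3)), "thigh")
    att = estimate_roll_pitch(imu)
    assert att.low_observability[60:].all()
    # gyro-only prediction holds the last attitude
    np.testing.assert_allclose(att.theta[60:], att.theta[49], atol=1e-9)


# ---------------------------------------------------------------------------
# yaw integration


def _imu_with_rate(wz, placement):
    n = wz.shape[0]
    f = np.tile([0.0, 0.0, G], (n, 1))
    w = np.column_stack([np.zeros(n), np.zeros(n), wz])
    return ImuSeries(np.arange(n) / FS, f, w, placement)


def test_zero_rate_zero_yaw():
    thigh = _imu_with_rate(np.zeros(100), "thigh")
    lower = _imu_with_rate(np.zeros(100), "lower_leg")
    att = estimate_roll_pitch(thigh)
    psi1, psi2 = integrate_yaw(thigh, lower, att, att)
    assert np.all(psi1 == 0.0) and np.all(psi2 == 0.0)


def test_constant_rate_integrates_exactly():
    n = 1001  # 10 s plus the initial sample
    thigh = _imu_with_rate(np.full(n, 0.1), "thigh")
    lower = _imu_with_rate(np.full(n, 0.1), "lower_leg")
    a1, a2 = (estimate_roll_pitch(x) for x in (thigh, lower))
    psi1, psi2 = integrate_yaw(thigh, lower, a1, a2)
    assert psi1[-1] == pytest.approx(1.0, rel=1e-12)
    np.testing.assert_array_equal(psi1, psi2)


def test_shared_rate_averages_out_noise(rng):
    """Independent rate noise on the two sensors: the common yaw stays
    within the O(sigma sqrt(n))/f_s random-walk envelope of the true
    integral, and both outputs are identical."""
    n, sigma = 3000, 0.05
    s = 0.3 * np.sin(2 * np.pi * 0.5 * np.arange(n) / FS)
    errs = []
    for _ in range(20):
        thigh = _imu_with_rate(s + rng.normal(0, sigma, n), "thigh")
        lower = _imu_with_rate(s + rng.normal(0, sigma, n), "lower_leg")
        a1, a2 = (estimate_roll_pitch(x) for x in (thigh, lower))
        psi1, psi2 = integrate_yaw(thigh, lower, a1, a2)
        np.testing.assert_array_equal(psi1, psi2)
        true = np.concatenate([[0], np.cumsum(s[:-1]) / FS])
        errs.append(psi1[-1] - true[-1])
    # averaging the two sensors halves the variance: sigma/sqrt(2)
    envelope = 4 * sigma / np.sqrt(2) * np.sqrt(n) / FS
    assert np.abs(np.mean(errs)) < envelope
    assert np.std(errs) < envelope


def test_length_mismatch_rejected():
    thigh = _imu_with_rate(np.zeros(100), "thigh")
    lower = _imu_with_rate(np.zeros(90), "lower_leg")
    a1, a2 = (estimate_roll_pitch(x) for x in (thigh, lower))
    with pytest.raises(ValueError, match="lengths differ"):
        integrate_yaw(thigh, lower, a1, a2)


def test_vertical_rate_is_yaw_invariant(rng):
    """Omega_z depends only on roll/pitch, so any yaw gives the same value."""
    w = rng.normal(size=(50, 3))
    f = np.tile([0.0, 0.0, G], (50, 1))
    imu = ImuSeries(np.arange(50) / FS, f, w, "thigh")
    att0 = AttitudeSeries(np.zeros(50), np.full(50, 0.3), np.full(50, -0.2))
    att1 = att0.with_yaw(rng.uniform(-np.pi, np.pi, 50))
    om0 = vertical_rate(imu, att0)
    om1 = vertical_rate(imu, att1)
    np.testing.assert_allclose(om0, om1, atol=1e-14)
    # and it matches the z-row of T @ omega directly
    ref = np.einsum("nij,nj->ni", att1.T, w)[:, 2]
    np.testing.assert_allclose(om1, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# acceleration transform


def test_gravity_cancellation_any_attitude(rng):
    n = 40
    psi, theta, phi = rng.uniform(-1, 1, (3, n))
    att = AttitudeSeries(psi, theta, phi)
    f = np.einsum("nij,j->ni", np.swapaxes(att.T, 1, 2), [0, 0, G])
    imu = ImuSeries(np.arange(n) / FS, f, np.zeros((n, 3)), "head")
    a = transform_accel(imu, att, G)
    assert np.abs(a).max() < 1e-12


def test_free_fall_gives_minus_g():
    n = 10
    att = AttitudeSeries(np.zeros(n), np.zeros(n), np.zeros(n))
    imu = ImuSeries(np.arange(n) / FS, np.zeros((n, 3)), np.zeros((n, 3)), "head")
    a = transform_accel(imu, att, G)
    np.testing.assert_allclose(a, np.tile([0, 0, -G], (n, 1)), atol=1e-15)


def test_matches_analytic_second_derivative(trial_updown):
    """Transforming the synthetic thigh stream with the true attitude
    reproduces the analytic COM acceleration of that segment."""
    tr = trial_updown.truth
    n = trial_updown.times.shape[0]
    att = AttitudeSeries(tr["angles"]["psi_s"], tr["angles"]["theta_s1"],
                         np.zeros(n))
    a = transform_accel(trial_updown.imus["thigh"], att,
                        trial_updown.params.g)
    # independent oracle: second difference of the analytic COM position
    # (after the start-up ramp, where the stencil truncation error is tiny)
    acc_ref = np.gradient(np.gradient(tr["positions"]["s1"], 1 / FS, axis=0),
                          1 / FS, axis=0)
    np.testing.assert_allclose(a[300:-5], acc_ref[300:-5], atol=1e-3)
    # and the generator's closed-form acceleration agrees to roundoff
    np.testing.assert_allclose(a, tr["acc_s1"], atol=1e-10)
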