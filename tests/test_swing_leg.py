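"""Swing-leg geometry and the Newton–Euler hip load."""

import numpy as np
import pytest

from stancecom import STANDARD_GRAVITY, hip_load, segment_coms
from stancecom.attitude import AttitudeSeries, euler_to_matrix, transform_accel
from conftest import WINDOW

FS = 100.0


def _att(psi, theta, phi, n=5):
    return AttitudeSeries(np.full(n, float(psi)), np.full(n, float(theta)),
                          np.full(n, float(phi)))


def _static_load(att1, att2, params, n=5):
    coms = segment_coms(att1, att2, params)
    zeros = np.zeros((n, 3))
    return hip_load(att1, att2, zeros, zeros, zeros, zeros, coms, params, FS)


def test_hanging_leg_geometry(params):
    p = params
    coms = segment_coms(_att(0, 0, 0), _att(0, 0, 0), p)
    np.testing.assert_allclose(coms.r_s1[0], [0, 0, -(p.L_s1 - p.l_s1)],
                               atol=1e-15)
    np.testing.assert_allclose(coms.r_s2[0],
                               [0, 0, -p.L_s1 - (p.L_s2 - p.l_s2)], atol=1e-15)


def test_horizontal_thigh_geometry(params):
    p = params
    coms = segment_coms(_att(0, -np.pi / 2, 0), _att(0, 0, 0), p)
    r = coms.r_s1[0]
    assert abs(r[2]) < 1e-12  # horizontal
    assert np.linalg.norm(r) == pytest.approx(p.L_s1 - p.l_s1, rel=1e-12)


def test_mass_weighted_mean_identity(params, rng):
    p = params
    n = 200
    a1 = AttitudeSeries(*rng.uniform(-np.pi, np.pi, (3, n)))
    a2 = AttitudeSeries(*rng.uniform(-np.pi, np.pi, (3, n)))
    coms = segment_coms(a1, a2, p)
    lhs = p.m_s1 * coms.r_s1 + p.m_s2 * coms.r_s2
    rhs = (p.m_s1 + p.m_s2) * coms.r_s
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)
    # rigid-link lengths are preserved for any attitude
    np.testing.assert_allclose(np.linalg.norm(coms.r_s1, axis=1),
                               p.L_s1 - p.l_s1, rtol=1e-12)
    knee = np.einsum("nij,j->ni", a1.T, [0, 0, -p.L_s1])
    np.testing.assert_allclose(np.linalg.norm(coms.r_s2 - knee, axis=1),
                               p.L_s2 - p.l_s2, rtol=1e-12)


def test_static_weight_transmitted(params):
    p = params
    load = _static_load(_att(0, -0.4, 0.1), _att(0, -0.1, 0.0), p)
    expected = [0, 0, -(p.m_s1 + p.m_s2) * p.g]
    np.testing.assert_allclose(load.R_s, np.tile(expected, (5, 1)), atol=1e-10)


def test_hanging_leg_zero_hip_moment(params):
    load = _static_load(_att(0, 0, 0), _att(0, 0, 0), params)
    np.testing.assert_allclose(load.N_s, 0.0, atol=1e-12)


def test_tilted_static_leg_moment_is_weight_times_offset(params):
    """A leg held at constant pitch loads the hip with a couple equal to
    segment weight x horizontal COM offset; forward offset pitches the
    pelvis forward (positive moment about the +Y axis)."""
    p = params
    att1, att2 = _att(0, -0.5, 0), _att(0, -0.2, 0)
    coms = segment_coms(att1, att2, p)
    load = _static_load(att1, att2, p)
    expected_ny = p.g * (p.m_s1 * coms.r_s1[0, 0] + p.m_s2 * coms.r_s2[0, 0])
    assert coms.r_s1[0, 0] > 0  # forward offset for negative pitch
    assert load.N_s[0, 1] == pytest.approx(expected_ny, rel=1e-12)
    assert load.N_s[0, 1] > 0
    np.testing.assert_allclose(load.N_s[:, [0, 2]], 0.0, atol=1e-12)


def test_newton_euler_oracle(trial_updown):
    """Hip load from exact attitudes/accelerations matches the generator's
    independent whole-leg Newton–Euler computation."""
    trial = trial_updown
    p, tr = trial.params, trial.truth
    n = trial.times.shape[0]
    att1 = AttitudeSeries(tr["angles"]["psi_s"], tr["angles"]["theta_s1"],
                          np.zeros(n))
    att2 = AttitudeSeries(tr["angles"]["psi_s"], tr["angles"]["theta_s2"],
                          np.zeros(n))
    coms = segment_coms(att1, att2, p)
    acc1 = transform_accel(trial.imus["thigh"], att1, p.g)
    acc2 = transform_accel(trial.imus["lower_leg"], att2, p.g)
    load = hip_load(att1, att2, acc1, acc2,
                    trial.imus["thigh"].angular_velocity,
                    trial.imus["lower_leg"].angular_velocity,
                    coms, p, FS)
    assert np.abs(load.R_s - tr["R_s"])[WINDOW].max() < 0.1
    assert np.abs(load.N_s - tr["N_s"])[WINDOW].max() < 0.01


def test_linearity_in_segment_mass(params, profile):
    """Scaling both segment masses scales force and moment alike."""
    from dataclasses import replace
    p2 = replace(params, m_s1=2 * params.m_s1, m_s2=2 * params.m_s2)
    att1, att2 = _att(0, -0.5, 0.2), _att(0, -0.1, 0.1)
    l1 = _static_load(att1, att2, params)
    l2 = _static_load(att1, att2, p2)
    np.testing.assert_allclose(l2.R_s, 2 * l1.R_s, rtol=1e-12)
    np.testing.assert_allclose(l2.N_s, 2 * l1.N_s, rtol=1e-12, atol=1e-14)


def test_frame_consistency_under_yaw(params, rng):
    """Rotating every input by a fixed yaw rotates the hip load the same way."""
    p = params
    n = 50
    t = np.arange(n) / FS
    th = -0.5 + 0.05 * np.sin(2 * np.pi * 0.75 * t)
    att1 = AttitudeSeries(np.zeros(n), th, np.zeros(n))
    att2 = AttitudeSeries(np.zeros(n), 0.5 * th, np.zeros(n))
    acc1 = rng.normal(0, 0.5, (n, 3))
    acc2 = rng.normal(0, 0.5, (n, 3))
    gyr1 = rng.normal(0, 0.3, (n, 3))
    gyr2 = rng.normal(0, 0.3, (n, 3))
    coms = segment_coms(att1, att2, p)
    base = hip_load(att1, att2, acc1, acc2, gyr1, gyr2, coms, p, FS)

    c = 0.8
    Rz = euler_to_matrix(c, 0.0, 0.0)
    att1r = att1.with_yaw(att1.psi + c)
    att2r = att2.with_yaw(att2.psi + c)
    comsr = segment_coms(att1r, att2r, p)
    rot = hip_load(att1r, att2r, acc1 @ Rz.T, acc2 @ Rz.T, gyr1, gyr2,
                   comsr, p, FS)
    np.testing.assert_allclose(rot.R_s, base.R_s @ Rz.T, atol=1e-10)
    np.testing.assert_allclose(rot.N_s, base.N_s @ Rz.T, atol=1e-10)


def test_impulse_consistency(trial_updown):
    """Over whole swing cycles the mean hip force equals the static weight."""
    trial = trial_updown
    p = trial.params
    ncyc = int(round(24 / 0.75 * FS))  # 24 full cycles from 10 s on
    seg = trial.truth["R_s"][1000:1000 + ncyc]
    static = np.array([0, 0, -(p.m_s1 + p.m_s2) * p.g])
    np.testing.assert_allclose(seg.mean(axis=0), static, atol=5e-3)


def test_shape_mismatch_rejected(params):
    att = _att(0, 0, 0, n=5)
    coms = segment_coms(att, att, params)
    with pytest.raises(ValueError, match="shape"):
        hip_load(att, att, np.zeros((4, 3)), np.zeros((5, 3)),
                 np.zeros((5, 3)), np.zeros((5, 3)), coms, params, FS)
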