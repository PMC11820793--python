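"""Swing-leg (subsystem) COM and the load it transmits to the non-stance hip.

The raised leg is a two-link chain — thigh and lower leg (including the
foot) — suspended from the non-stance hip joint Q.  Its segment COMs follow
directly from the two sensor attitudes and the segment geometry; the force
and couple it applies to the main system at Q follow from Newton–Euler
inverse dynamics using the gravity-free segment COM accelerations (measured
by the IMUs, which ride at the segment COM heights) and the gyro rates.

Sign conventions: ``R_s`` and ``N_s`` are the force [N] and couple [N·m]
exerted *by the swing leg on the main system* at Q.  With the leg hanging
at rest in any pose, ``R_s = (0, 0, -(m_s1+m_s2) g)`` and ``N_s`` equals
the weight times the horizontal COM offset (the static plausibility check
every implementation choice here was validated against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import BodyParams
from .attitude import AttitudeSeries
from .signal_processing import differentiate


@dataclass
class SubsystemComSeries:
    """Per-sample swing-leg COM vectors in the hip-anchored frame Q-xyz [m]."""

    r_s1: np.ndarray
    r_s2: np.ndarray
    r_s: np.ndarray


@dataclass
class HipLoadSeries:
    """Force/couple on the main system at the non-stance hip, per sample.

    Intermediates (per-segment inertial forces ``R_si`` and Euler-equation
    couples ``N_si``) are retained for testing and debug output.
    """

    R_s: np.ndarray
    N_s: np.ndarray
    R_s1: np.ndarray
    R_s2: np.ndarray
    N_s1: np.ndarray
    N_s2: np.ndarray


def segment_coms(
    att_s1: AttitudeSeries, att_s2: AttitudeSeries, params: BodyParams
) -> SubsystemComSeries:
    """Thigh, lower-leg and combined swing-leg COMs in Q-xyz.

    The thigh COM sits ``L_s1 - l_s1`` below the hip along the thigh -z
    axis (``l`` is measured from the segment bottom); the lower-leg COM
    hangs ``L_s2 - l_s2`` below the knee, which itself is ``L_s1`` below
    the hip along the thigh axis.  The combined COM is the mass-weighted
    mean of the two.
    """
    n1 = att_s1.theta.shape[0]
    if att_s2.theta.shape[0] != n1:
        raise ValueError("thigh and lower-leg attitude series lengths differ")
    T1, T2 = att_s1.T, att_s2.T
    d1 = np.array([0.0, 0.0, -(params.L_s1 - params.l_s1)])
    knee = np.array([0.0, 0.0, -params.L_s1])
    d2 = np.array([0.0, 0.0, -(params.L_s2 - params.l_s2)])
    r_s1 = T1 @ d1
    r_s2 = T1 @ knee + T2 @ d2
    r_s = (params.m_s1 * r_s1 + params.m_s2 * r_s2) / params.m_sub
    return SubsystemComSeries(r_s1=r_s1, r_s2=r_s2, r_s=r_s)


def hip_load(
    att_s1: AttitudeSeries,
    att_s2: AttitudeSeries,
    acc_s1: np.ndarray,
    acc_s2: np.ndarray,
    gyro_s1: np.ndarray,
    gyro_s2: np.ndarray,
    coms: SubsystemComSeries,
    params: BodyParams,
    f_s: float,
    presmooth=None,
) -> HipLoadSeries:
    """Newton–Euler inverse dynamics of the swing leg about the hip Q.

    Parameters
    ----------
    acc_s1, acc_s2 : ndarray (n, 3)
        Gravity-free stationary-frame COM accelerations of thigh and lower
        leg (output of :func:`stancecom.attitude.transform_accel`).
    gyro_s1, gyro_s2 : ndarray (n, 3)
        Sensor-frame angular rates [rad/s]; differentiated numerically
        (central differences) for the Euler-equation term.
    presmooth : callable, optional
        Applied to each gyro channel before differentiation (e.g. the
        3 Hz zero-phase low-pass) — off by default.

    Notes
    -----
    Per segment, the inertial force is ``R_si = -m_si a_si + m_si g_vec``
    and the spin couple ``N_si = T (J w_dot + w x (J w))`` with the inertia
    tensor diagonal in the segment frame.  Taking moments of all external
    forces about the instantaneous hip point gives the couple on the main
    system ``N_s = -N_s1 - N_s2 + r_s1 x R_s1 + r_s2 x R_s2`` — exact
    regardless of hip motion, since the segment accelerations are absolute.
    """
    n = acc_s1.shape[0]
    for name, arr in (("acc_s1", acc_s1), ("acc_s2", acc_s2),
                      ("gyro_s1", gyro_s1), ("gyro_s2", gyro_s2)):
        if np.asarray(arr).shape != (n, 3):
            raise ValueError(f"{name} must have shape ({n}, 3)")

    g_vec = np.array([0.0, 0.0, -params.g])

    def segment(att, acc, gyro, m, J_diag):
        T = att.T
        R = -m * acc + m * g_vec
        w = np.asarray(gyro, float)
        if presmooth is not None:
            w = presmooth(w.T).T
        w_dot = differentiate(w.T, f_s).T
        Jw = w * J_diag
        body = w_dot * J_diag + np.cross(w, Jw)
        N = np.einsum("nij,nj->ni", T, body)
        return R, N

    J1 = np.array([params.J_s1x, params.J_s1y, params.J_s1z])
    J2 = np.array([params.J_s2x, params.J_s2y, params.J_s2z])
    R_s1, N_s1 = segment(att_s1, acc_s1, gyro_s1, params.m_s1, J1)
    R_s2, N_s2 = segment(att_s2, acc_s2, gyro_s2, params.m_s2, J2)

    R_s = R_s1 + R_s2
    N_s = -N_s1 - N_s2 + np.cross(coms.r_s1, R_s1) + np.cross(coms.r_s2, R_s2)
    return HipLoadSeries(R_s=R_s, N_s=N_s, R_s1=R_s1, R_s2=R_s2, N_s1=N_s1, N_s2=N_s2)
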