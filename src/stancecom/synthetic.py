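"""Forward-model generator of synthetic single-leg-stance trials.

Ground-truth segment angle trajectories are prescribed as smooth sinusoids
(with a quintic start-up ramp so every trial begins at rest), the full
nonlinear rigid-body kinematics are evaluated analytically, and perfectly
consistent sensor streams are synthesised from them:

* three IMU streams (head, swing thigh, swing lower leg) — specific force
  and angular rate in the sensor frame, sensors riding at the segment COM
  heights with axes aligned to the segment axes;
* the force-platform channels via whole-body Newton–Euler (exact, no
  linearization);
* the ground-truth whole-body COM and every intermediate quantity an
  estimator stage can be checked against (segment COM accelerations,
  hip load, swing-leg COM).

Three motion presets mirror the experimental conditions: quiet single-leg
stance, 0.75 Hz up-and-down swinging of the raised leg, and 0.75 Hz
reciprocal yaw rotation of the raised leg.  Gaussian sensor noise and a
constant gyro bias can be layered on top; with zero noise every emitted
signal is analytically consistent with the ground truth.

The quiet-stance sway amplitudes (6 mm AP / 4 mm ML, components at 0.3 and
0.7 Hz) are calibrated to produce sway RMS of the order observed in adult
single-leg stance; the swing-leg presets articulate the leg at 0.75 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .anthropometry import BodyParams, SubjectProfile, compute_body_params
from .attitude import ImuSeries, euler_to_matrix
from .main_system import ForcePlateSeries
from .whole_body import ComSeries

CONDITIONS = ("A_quiet", "B_updown", "C_yaw")

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


_KY, _KZ = _skew(_EY), _skew(_EZ)


# ---------------------------------------------------------------------------
# smooth prescribed trajectories

class AngleTraj:
    """An angle trajectory with exact first and second derivatives."""

    def __init__(self, val: np.ndarray, d1: np.ndarray, d2: np.ndarray):
        self.val, self.d1, self.d2 = val, d1, d2

    @classmethod
    def build(cls, t: np.ndarray, offset: float,
              components: list[tuple[float, float, float]],
              ramp: float) -> "AngleTraj":
        """``offset + ramp(t) * sum(A sin(2 pi f t + phase))``.

        The quintic ramp has zero value/slope/curvature at t=0, so the
        trajectory starts exactly at rest in the offset pose.
        """
        s = np.zeros_like(t)
        s1 = np.zeros_like(t)
        s2 = np.zeros_like(t)
        for amp, freq, phase in components:
            om = 2 * np.pi * freq
            ph = om * t + phase
            s += amp * np.sin(ph)
            s1 += amp * om * np.cos(ph)
            s2 += -amp * om * om * np.sin(ph)
        e, e1, e2 = _smootherstep(t, ramp)
        return cls(
            offset + e * s,
            e1 * s + e * s1,
            e2 * s + 2 * e1 * s1 + e * s2,
        )

    @classmethod
    def constant(cls, t: np.ndarray, value: float) -> "AngleTraj":
        z = np.zeros_like(t)
        return cls(np.full_like(t, value), z, z)


def _smootherstep(t: np.ndarray, ramp: float):
    """C2 ramp from 0 to 1 over [0, ramp] seconds, with derivatives."""
    if ramp <= 0:
        return np.ones_like(t), np.zeros_like(t), np.zeros_like(t)
    x = np.clip(t / ramp, 0.0, 1.0)
    e = x**3 * (10 - 15 * x + 6 * x**2)
    e1 = (30 * x**2 - 60 * x**3 + 30 * x**4) / ramp
    e2 = (60 * x - 180 * x**2 + 120 * x**3) / ramp**2
    inside = (t > 0) & (t < ramp)
    return e, np.where(inside, e1, 0.0), np.where(inside, e2, 0.0)


# ---------------------------------------------------------------------------
# exact rigid-body kinematics

class SegmentKin:
    """Orientation, angular velocity and angular acceleration of a segment."""

    def __init__(self, psi: AngleTraj, theta: AngleTraj, phi: AngleTraj):
        self.psi, self.theta, self.phi = psi, theta, phi
        self.T = euler_to_matrix(psi.val, theta.val, phi.val)
        n = psi.val.shape[0]
        cps, sps = np.cos(psi.val), np.sin(psi.val)
        Rz = np.zeros((n, 3, 3))
        Rz[:, 0, 0] = cps
        Rz[:, 0, 1] = -sps
        Rz[:, 1, 0] = sps
        Rz[:, 1, 1] = cps
        Rz[:, 2, 2] = 1.0
        cth, sth = np.cos(theta.val), np.sin(theta.val)
        Ry = np.zeros((n, 3, 3))
        Ry[:, 0, 0] = cth
        Ry[:, 0, 2] = sth
        Ry[:, 2, 0] = -sth
        Ry[:, 2, 2] = cth
        Ry[:, 1, 1] = 1.0

        ey_w = Rz @ _EY            # pitch axis in world
        ex_mid = Ry @ _EX
        ex_w = np.einsum("nij,nj->ni", Rz, ex_mid)  # roll axis in world
        d1 = psi.d1[:, None]
        t1 = theta.d1[:, None]
        p1 = phi.d1[:, None]
        self.omega = d1 * _EZ + t1 * ey_w + p1 * ex_w
        d_ey_w = d1 * (Rz @ (_KZ @ _EY))
        d_ex_w = d1 * np.einsum("nij,nj->ni", Rz @ _KZ, ex_mid) \
            + t1 * np.einsum("nij,nj->ni", Rz, Ry @ (_KY @ _EX))
        self.alpha = (psi.d2[:, None] * _EZ
                      + theta.d2[:, None] * ey_w + t1 * d_ey_w
                      + phi.d2[:, None] * ex_w + p1 * d_ex_w)


class PointKin:
    """Position/velocity/acceleration of a material point, world frame."""

    def __init__(self, p, v, a):
        self.p, self.v, self.a = p, v, a

    @classmethod
    def fixed(cls, n: int, where: np.ndarray) -> "PointKin":
        z = np.zeros((n, 3))
        return cls(np.broadcast_to(where, (n, 3)).copy(), z.copy(), z.copy())

    def offset_world(self, u: np.ndarray) -> "PointKin":
        return PointKin(self.p + u, self.v, self.a)

    def attach(self, seg: SegmentKin, u_body: np.ndarray) -> "PointKin":
        ru = seg.T @ u_body
        w, al = seg.omega, seg.alpha
        return PointKin(
            self.p + ru,
            self.v + np.cross(w, ru),
            self.a + np.cross(al, ru) + np.cross(w, np.cross(w, ru)),
        )


# ---------------------------------------------------------------------------
# presets and noise

@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian sensor-noise model (standard deviations; zero = noiseless).

    ``gyro_bias`` is a constant per-axis bias magnitude; each axis of each
    gyro draws its bias uniformly from ``[-gyro_bias, +gyro_bias]``.
    """

    accel_sigma: float = 0.0       # m/s^2
    gyro_sigma: float = 0.0        # rad/s
    gyro_bias: float = 0.0         # rad/s
    force_sigma: float = 0.0       # N
    moment_sigma: float = 0.0      # N*m

    @property
    def is_zero(self) -> bool:
        return all(v == 0.0 for v in asdict(self).values())


@dataclass(frozen=True)
class MotionPreset:
    """Prescribed-motion preset for one synthetic trial.

    ``condition`` selects the swing-leg behaviour; the quiet-stance sway of
    the main system is common to all three.  Amplitudes are kept small
    enough that the main-system tilt stays within the linearization regime
    (validated, limit 5 deg).  The swing leg is raised in front of the body
    (negative baseline pitch) with the knee slightly flexed.
    """

    condition: str = "A_quiet"
    duration: float = 45.0          # s
    f_s: float = 100.0              # Hz
    ramp: float = 2.0               # start-up ramp [s]
    ap_amp_mm: float = 6.0          # AP sway amplitude of the COM [mm]
    ml_amp_mm: float = 4.0          # ML sway amplitude of the COM [mm]
    sway_freqs: tuple[float, float] = (0.3, 0.7)
    trunk_wobble_frac: float = 0.2  # extra trunk angle, fraction of lean
    swing_freq: float = 0.75        # Hz, leg articulation (presets B and C)
    swing_pitch_amp_deg: float = 12.0   # thigh pitch swing (B)
    knee_pitch_amp_deg: float = 8.0     # shank pitch swing (B)
    yaw_amp_deg: float = 15.0           # leg yaw swing (C)
    thigh_pitch0_deg: float = -30.0
    shank_pitch0_deg: float = -10.0
    thigh_roll0_deg: float = 0.0
    shank_roll0_deg: float = 0.0
    leg_lean0_deg: tuple[float, float] = (0.0, 0.0)    # constant stance-leg
    trunk_lean0_deg: tuple[float, float] = (0.0, 0.0)  # and trunk (pitch,
    # roll) offsets — static tilted fixtures
    stance_side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.duration < 41.0:
            raise ValueError("duration must cover the 10-40 s evaluation window")


@dataclass
class SyntheticTrial:
    """A generated trial: sensor streams plus full ground truth."""

    preset: MotionPreset
    profile: SubjectProfile
    params: BodyParams
    noise: NoiseSpec
    times: np.ndarray
    plate: ForcePlateSeries
    imus: dict
    truth: dict
    emitted_accel_kind: str = "specific_force"

    @property
    def f_s(self) -> float:
        return self.preset.f_s


MAX_MAIN_TILT_RAD = np.deg2rad(5.0)


def generate_trial(
    preset: MotionPreset,
    profile: SubjectProfile,
    noise: NoiseSpec | None = None,
    accel_kind: str = "specific_force",
) -> SyntheticTrial:
    """Generate one fully consistent synthetic trial.

    With ``noise`` zero (default) every emitted signal follows analytically
    from the prescribed kinematics; with noise, Gaussian perturbations and
    gyro biases are drawn from ``numpy.random.default_rng(preset.seed)``,
    so a fixed seed gives bit-identical output.
    """
    noise = noise or NoiseSpec()
    if accel_kind not in ("specific_force", "kinematic"):
        raise ValueError(f"unknown accel_kind {accel_kind!r}")
    if preset.stance_side != profile.stance_side:
        profile = SubjectProfile(profile.height, profile.mass, preset.stance_side)
    params = compute_body_params(profile)
    p = params
    n = int(round(preset.duration * preset.f_s))
    t = np.arange(n) / preset.f_s
    g_vec = np.array([0.0, 0.0, -p.g])

    # --- prescribed angles ------------------------------------------------
    lever = (p.m_m1 * p.l_m1 + p.m_m2 * (p.L_m1 + p.l_m2)) / p.m_main
    f1, f2 = preset.sway_freqs
    amp_ap = preset.ap_amp_mm * 1e-3 / lever
    amp_ml = preset.ml_amp_mm * 1e-3 / lever

    def lean(amp, phases):
        return [(0.6 * amp, f1, phases[0]), (0.4 * amp, f2, phases[1])]

    th0_leg, ph0_leg = np.deg2rad(preset.leg_lean0_deg)
    th0_tr, ph0_tr = np.deg2rad(preset.trunk_lean0_deg)
    th_m1 = AngleTraj.build(t, th0_leg, lean(amp_ap, (0.3, 1.7)), preset.ramp)
    th_m2 = AngleTraj.build(
        t, th0_tr,
        lean(amp_ap, (0.3, 1.7))
        + [(preset.trunk_wobble_frac * amp_ap, 0.5, 1.0)],
        preset.ramp,
    )
    # roll sign: positive roll moves the segment tip toward -Y
    ph_m1 = AngleTraj.build(t, ph0_leg, lean(-amp_ml, (2.1, 0.6)), preset.ramp)
    ph_m2 = AngleTraj.build(
        t, ph0_tr,
        lean(-amp_ml, (2.1, 0.6))
        + [(-preset.trunk_wobble_frac * amp_ml, 0.45, 2.5)],
        preset.ramp,
    )

    for traj in (th_m1, th_m2, ph_m1, ph_m2):
        if np.max(np.abs(traj.val)) > MAX_MAIN_TILT_RAD:
            raise ValueError(
                "preset sway amplitude drives the main-system tilt beyond "
                "the 5 deg linearization regime"
            )

    zero = AngleTraj.constant(t, 0.0)
    th10 = np.deg2rad(preset.thigh_pitch0_deg)
    th20 = np.deg2rad(preset.shank_pitch0_deg)
    fsw = preset.swing_freq
    if preset.condition == "A_quiet":
        th_s1 = AngleTraj.constant(t, th10)
        th_s2 = AngleTraj.constant(t, th20)
        psi_s = zero
    elif preset.condition == "B_updown":
        th_s1 = AngleTraj.build(
            t, th10, [(np.deg2rad(preset.swing_pitch_amp_deg), fsw, 0.0)],
            preset.ramp)
        th_s2 = AngleTraj.build(
            t, th20, [(np.deg2rad(preset.knee_pitch_amp_deg), fsw, 0.5)],
            preset.ramp)
        psi_s = zero
    else:  # C_yaw
        th_s1 = AngleTraj.constant(t, th10)
        th_s2 = AngleTraj.constant(t, th20)
        psi_s = AngleTraj.build(
            t, 0.0, [(np.deg2rad(preset.yaw_amp_deg), fsw, 0.0)], preset.ramp)

    seg_m1 = SegmentKin(zero, th_m1, ph_m1)
    seg_m2 = SegmentKin(zero, th_m2, ph_m2)
    roll_s1 = AngleTraj.constant(t, np.deg2rad(preset.thigh_roll0_deg))
    roll_s2 = AngleTraj.constant(t, np.deg2rad(preset.shank_roll0_deg))
    seg_s1 = SegmentKin(psi_s, th_s1, roll_s1)
    seg_s2 = SegmentKin(psi_s, th_s2, roll_s2)

    # --- kinematic chain --------------------------------------------------
    s_hip = 1.0 if profile.stance_side == "right" else -1.0
    ankle = PointKin.fixed(n, np.array([0.0, 0.0, p.L_f]))
    com_m1 = ankle.attach(seg_m1, np.array([0.0, 0.0, p.l_m1]))
    hip_p = ankle.attach(seg_m1, np.array([0.0, 0.0, p.L_m1]))
    com_m2 = hip_p.attach(seg_m2, np.array([0.0, 0.0, p.l_m2]))
    head = hip_p.attach(seg_m2, np.array([0.0, 0.0, p.L_m2]))
    hip_q = hip_p.offset_world(np.array([0.0, s_hip * p.w, 0.0]))
    com_s1 = hip_q.attach(seg_s1, np.array([0.0, 0.0, -(p.L_s1 - p.l_s1)]))
    knee = hip_q.attach(seg_s1, np.array([0.0, 0.0, -p.L_s1]))
    com_s2 = knee.attach(seg_s2, np.array([0.0, 0.0, -(p.L_s2 - p.l_s2)]))
    com_f = PointKin.fixed(n, np.array([0.0, 0.0, 0.5 * p.L_f]))

    segments = [
        (p.m_f, None, None, com_f),
        (p.m_m1, seg_m1, np.array([p.J_m1x, p.J_m1y, p.J_m1x]), com_m1),
        (p.m_m2, seg_m2, np.array([p.J_m2x, p.J_m2y, p.J_m2x]), com_m2),
        (p.m_s1, seg_s1, np.array([p.J_s1x, p.J_s1y, p.J_s1z]), com_s1),
        (p.m_s2, seg_s2, np.array([p.J_s2x, p.J_s2y, p.J_s2z]), com_s2),
    ]

    # --- plate via whole-body Newton-Euler (exact) ------------------------
    F_react = np.zeros((n, 3))
    M_react = np.zeros((n, 3))
    for m, seg, J, pt in segments:
        F_react += m * (pt.a - g_vec)
        M_react += np.cross(pt.p, m * (pt.a - g_vec))
        if seg is not None:
            M_react += _spin_rate(seg, J)
    R_out = np.column_stack([-F_react[:, 0], -F_react[:, 1], F_react[:, 2]])
    N_out = -M_react

    # --- IMU streams ------------------------------------------------------
    def imu_streams(seg: SegmentKin, pt: PointKin):
        Tt = np.swapaxes(seg.T, 1, 2)
        if accel_kind == "specific_force":
            f = np.einsum("nij,nj->ni", Tt, pt.a - g_vec)
        else:
            f = np.einsum("nij,nj->ni", Tt, pt.a)
        w = np.einsum("nij,nj->ni", Tt, seg.omega)
        return f, w

    f_h, w_h = imu_streams(seg_m2, head)
    f_s1, w_s1 = imu_streams(seg_s1, com_s1)
    f_s2, w_s2 = imu_streams(seg_s2, com_s2)

    # --- noise ------------------------------------------------------------
    rng = np.random.default_rng(preset.seed)
    if not noise.is_zero:
        R_out = R_out + rng.normal(0.0, 1.0, R_out.shape) * noise.force_sigma
        N_out = N_out + rng.normal(0.0, 1.0, N_out.shape) * noise.moment_sigma
        streams = []
        for f, w in ((f_h, w_h), (f_s1, w_s1), (f_s2, w_s2)):
            f = f + rng.normal(0.0, 1.0, f.shape) * noise.accel_sigma
            bias = rng.uniform(-noise.gyro_bias, noise.gyro_bias, 3)
            w = w + bias + rng.normal(0.0, 1.0, w.shape) * noise.gyro_sigma
            streams.append((f, w))
        (f_h, w_h), (f_s1, w_s1), (f_s2, w_s2) = streams

    plate = ForcePlateSeries(times=t, R=R_out, N=N_out)
    imus = {
        "head": ImuSeries(t, f_h, w_h, placement="head"),
        "thigh": ImuSeries(t, f_s1, w_s1, placement="thigh"),
        "lower_leg": ImuSeries(t, f_s2, w_s2, placement="lower_leg"),
    }

    # --- ground truth -----------------------------------------------------
    m_positions = {
        "m1": com_m1.p, "m2": com_m2.p, "s1": com_s1.p, "s2": com_s2.p,
    }
    X_m = (p.m_m1 * com_m1.p[:, 0] + p.m_m2 * com_m2.p[:, 0]) / p.m_main
    Y_m = (p.m_m1 * com_m1.p[:, 1] + p.m_m2 * com_m2.p[:, 1]) / p.m_main
    sub_com_q = ((p.m_s1 * (com_s1.p - hip_q.p)
                  + p.m_s2 * (com_s2.p - hip_q.p)) / p.m_sub)
    R_s1_true = p.m_s1 * (g_vec - com_s1.a)
    R_s2_true = p.m_s2 * (g_vec - com_s2.a)
    rho1 = com_s1.p - hip_q.p
    rho2 = com_s2.p - hip_q.p
    N_s_true = (-_spin_rate(seg_s1, np.array([p.J_s1x, p.J_s1y, p.J_s1z]))
                - _spin_rate(seg_s2, np.array([p.J_s2x, p.J_s2y, p.J_s2z]))
                + np.cross(rho1, R_s1_true) + np.cross(rho2, R_s2_true))

    truth = {
        "positions": m_positions,
        "foot_com": com_f.p,
        "com": _truth_com(m_positions, p),
        "X_m": X_m,
        "Y_m": Y_m,
        "acc_m1": com_m1.a,
        "acc_m2": com_m2.a,
        "acc_head": head.a,
        "acc_s1": com_s1.a,
        "acc_s2": com_s2.a,
        "sub_com_q": sub_com_q,
        "R_s": R_s1_true + R_s2_true,
        "N_s": N_s_true,
        "hip_q": hip_q.p,
        "angles": {
            "theta_m1": th_m1.val, "theta_m2": th_m2.val,
            "phi_m1": ph_m1.val, "phi_m2": ph_m2.val,
            "theta_s1": th_s1.val, "theta_s2": th_s2.val,
            "psi_s": psi_s.val,
        },
    }

    return SyntheticTrial(
        preset=preset, profile=profile, params=params, noise=noise,
        times=t, plate=plate, imus=imus, truth=truth,
        emitted_accel_kind=accel_kind,
    )


def _spin_rate(seg: SegmentKin, J_diag: np.ndarray) -> np.ndarray:
    """World-frame rate of change of a segment's spin angular momentum."""
    Tt = np.swapaxes(seg.T, 1, 2)
    w_b = np.einsum("nij,nj->ni", Tt, seg.omega)
    al_b = np.einsum("nij,nj->ni", Tt, seg.alpha)
    body = al_b * J_diag + np.cross(w_b, w_b * J_diag)
    return np.einsum("nij,nj->ni", seg.T, body)


def _truth_com(positions: dict, p: BodyParams) -> ComSeries:
    masses = {"m1": p.m_m1, "m2": p.m_m2, "s1": p.m_s1, "s2": p.m_s2}
    acc = np.zeros_like(next(iter(positions.values())))
    for key, pos in positions.items():
        acc = acc + masses[key] * pos
    com = acc / p.m_moving
    return ComSeries(X_b=com[:, 0], Y_b=com[:, 1])


def ground_truth_com(trial: SyntheticTrial) -> ComSeries:
    """Exact mass-weighted COM of the four moving segments.

    Same origin convention as the estimator's fusion output: absolute
    horizontal position over the plate origin, including the constant
    inter-hip offset of the raised leg.
    """
    return _truth_com(trial.truth["positions"], trial.params)
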