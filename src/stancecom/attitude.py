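"""IMU attitude estimation: 3-2-1 Euler angles, EKF roll/pitch, yaw integration.

Each IMU orientation is parameterised by yaw-pitch-roll (psi, theta, phi)
Euler angles; the rotation matrix ``T`` maps sensor-frame vectors into the
stationary frame, ``T = Rz(psi) @ Ry(theta) @ Rx(phi)``.

Roll and pitch are observable from the accelerometer (gravity direction)
and the gyroscope, and are fused with a small extended Kalman filter whose
state is just ``(phi, theta)``.  Yaw is not observable without a
magnetometer; for the two swing-leg sensors it is obtained by forward-Euler
integration of a shared vertical angular rate (the thigh and lower-leg
vertical rates are assumed equal, which suppresses independent drift), and
for the head sensor it is pinned at zero (head facing forward).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anthropometry import STANDARD_GRAVITY

PLACEMENTS = ("head", "thigh", "lower_leg")


# ---------------------------------------------------------------------------
# rotation kinematics

def euler_to_matrix(psi, theta, phi) -> np.ndarray:
    """Rotation matrix (sensor -> stationary) for 3-2-1 Euler angles.

    Accepts scalars or broadcastable arrays; returns shape ``(..., 3, 3)``.
    The matrix is ``Rz(psi) @ Ry(theta) @ Rx(phi)`` — yaw about the vertical
    axis first, then pitch, then roll.
    """
    psi, theta, phi = np.broadcast_arrays(
        np.asarray(psi, float), np.asarray(theta, float), np.asarray(phi, float)
    )
    cps, sps = np.cos(psi), np.sin(psi)
    cth, sth = np.cos(theta), np.sin(theta)
    cph, sph = np.cos(phi), np.sin(phi)
    T = np.empty(psi.shape + (3, 3))
    T[..., 0, 0] = cth * cps
    T[..., 0, 1] = sph * sth * cps - cph * sps
    T[..., 0, 2] = cph * sth * cps + sph * sps
    T[..., 1, 0] = cth * sps
    T[..., 1, 1] = cph * cps + sph * sth * sps
    T[..., 1, 2] = -sph * cps + cph * sth * sps
    T[..., 2, 0] = -sth
    T[..., 2, 1] = sph * cth
    T[..., 2, 2] = cph * cth
    return T


# ---------------------------------------------------------------------------
# containers

@dataclass
class ImuSeries:
    """Raw IMU streams in the sensor frame.

    ``specific_force`` is the accelerometer output [m/s^2] (kinematic
    acceleration minus gravity, expressed in the sensor frame);
    ``angular_velocity`` the gyroscope output [rad/s].  Both are ``(n, 3)``.
    """

    times: np.ndarray
    specific_force: np.ndarray
    angular_velocity: np.ndarray
    placement: str = "head"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.specific_force = np.asarray(self.specific_force, float)
        self.angular_velocity = np.asarray(self.angular_velocity, float)
        n = self.times.shape[0]
        if self.specific_force.shape != (n, 3) or self.angular_velocity.shape != (n, 3):
            raise ValueError("specific_force and angular_velocity must be (n, 3)")
        if not (np.all(np.isfinite(self.specific_force))
                and np.all(np.isfinite(self.angular_velocity))):
            raise ValueError("IMU streams contain non-finite values")
        if n >= 2:
            dt = np.diff(self.times)
            if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean():
                raise ValueError("IMU sampling must be uniform and increasing")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")

    @property
    def f_s(self) -> float:
        """Sampling rate [Hz]."""
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return self.times.shape[0]


@dataclass
class AttitudeSeries:
    """Per-sample 3-2-1 Euler angles and the derived rotation matrices."""

    psi: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    low_observability: np.ndarray | None = None

    @property
    def T(self) -> np.ndarray:
        """Rotation matrices sensor -> stationary, shape ``(n, 3, 3)``."""
        return euler_to_matrix(self.psi, self.theta, self.phi)

    def with_yaw(self, psi: np.ndarray) -> "AttitudeSeries":
        return replace(self, psi=np.asarray(psi, float))


# ---------------------------------------------------------------------------
# roll/pitch EKF

@dataclass(frozen=True)
class EkfConfig:
    """Tunables of the roll/pitch extended Kalman filter.

    gyro_noise_density : float
        Gyro rate white-noise density [rad/s/sqrt(Hz)]; sets the process
        covariance growth.
    accel_sigma : float
        Accelerometer measurement sigma [m/s^2].  Deliberately large
        compared with sensor noise: the gravity measurement is corrupted
        mostly by body acceleration, and the filter should lean on the
        gyro during movement.
    p0 : float
        Initial state variance [rad^2].
    innovation_gate : float
        Chi-square gate (3 dof) on the normalised innovation; beyond it the
        measurement covariance is inflated proportionally, so strongly
        accelerated samples barely update the tilt.
    low_accel_fraction : float
        If the specific-force magnitude falls below this fraction of g the
        update is skipped entirely (free-fall-like, gravity unobservable)
        and the sample is flagged.
    """

    gyro_noise_density: float = 0.005
    accel_sigma: float = 1.0
    p0: float = 0.1
    innovation_gate: float = 16.27
    low_accel_fraction: float = 0.25
    g: float = STANDARD_GRAVITY


def _accel_tilt(a: np.ndarray) -> tuple[float, float]:
    """Roll/pitch implied by a static accelerometer sample."""
    ax, ay, az = a
    phi = np.arctan2(ay, az)
    theta = np.arctan2(-ax, np.hypot(ay, az))
    return float(phi), float(theta)


def estimate_roll_pitch(
    imu: ImuSeries, config: EkfConfig | None = None
) -> AttitudeSeries:
    """EKF estimate of per-sample roll and pitch, yaw left at zero.

    Process model: Euler-angle kinematics driven by the gyro rates.
    Measurement: the accelerometer compared against the gravity direction
    predicted from ``(phi, theta)``.  On a stationary stretch the estimate
    converges to the gravity-consistent tilt; during strong accelerations
    the innovation gate makes the filter coast on the gyro.

    Returns an :class:`AttitudeSeries` with ``psi = 0`` and a boolean
    ``low_observability`` flag per sample.
    """
    cfg = config or EkfConfig()
    n = imu.n
    dt = 1.0 / imu.f_s
    g = cfg.g

    q_c = cfg.gyro_noise_density**2  # rad^2/s
    Q = np.eye(2) * q_c * dt
    R_base = np.eye(3) * cfg.accel_sigma**2

    phi_out = np.empty(n)
    theta_out = np.empty(n)
    flags = np.zeros(n, dtype=bool)

    # initialise from the first accelerometer sample (trials start quietly)
    phi, theta = _accel_tilt(imu.specific_force[0])
    P = np.eye(2) * cfg.p0
    I2 = np.eye(2)

    for k in range(n):
        if k > 0:
            p, q, r = imu.angular_velocity[k - 1]
            sph, cph = np.sin(phi), np.cos(phi)
            tth = np.tan(theta)
            phi_dot = p + tth * (q * sph + r * cph)
            theta_dot = q * cph - r * sph
            # Jacobian of the rate vector wrt (phi, theta)
            sec2 = 1.0 + tth * tth
            F = np.array(
                [
                    [tth * (q * cph - r * sph), sec2 * (q * sph + r * cph)],
                    [-q * sph - r * cph, 0.0],
                ]
            )
            phi = phi + phi_dot * dt
            theta = theta + theta_dot * dt
            A = I2 + F * dt
            P = A @ P @ A.T + Q

        a = imu.specific_force[k]
        a_norm = float(np.linalg.norm(a))
        if a_norm < cfg.low_accel_fraction * g:
            flags[k] = True  # gravity unobservable; keep the gyro prediction
        else:
            sph, cph = np.sin(phi), np.cos(phi)
            sth, cth = np.sin(theta), np.cos(theta)
            h = g * np.array([-sth, sph * cth, cph * cth])
            H = g * np.array(
                [
                    [0.0, -cth],
                    [cph * cth, -sph * sth],
                    [-sph * cth, -cph * sth],
                ]
            )
            nu = a - h
            S = H @ P @ H.T + R_base
            d2 = float(nu @ np.linalg.solve(S, nu))
            if d2 > cfg.innovation_gate:
                S = H @ P @ H.T + R_base * (d2 / cfg.innovation_gate)
            K = P @ np.linalg.solve(S.T, H).T  # P H^T S^-1
            dx = K @ nu
            phi += dx[0]
            theta += dx[1]
            P = (I2 - K @ H) @ P

        phi_out[k] = phi
        theta_out[k] = theta

    return AttitudeSeries(
        psi=np.zeros(n), theta=theta_out, phi=phi_out, low_observability=flags
    )


# ---------------------------------------------------------------------------
# yaw

def vertical_rate(imu: ImuSeries, att: AttitudeSeries) -> np.ndarray:
    """Stationary-frame vertical angular rate Omega_z [rad/s] per sample.

    The z-component of ``T @ omega_tilde`` does not depend on yaw, so it is
    computed from roll/pitch alone: ``Omega_z = (Ry(theta) Rx(phi) w)_z``.
    """
    sth, cth = np.sin(att.theta), np.cos(att.theta)
    sph, cph = np.sin(att.phi), np.cos(att.phi)
    w = imu.angular_velocity
    return -sth * w[:, 0] + sph * cth * w[:, 1] + cph * cth * w[:, 2]


def integrate_yaw(
    thigh: ImuSeries,
    lower: ImuSeries,
    thigh_att: AttitudeSeries,
    lower_att: AttitudeSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared yaw of the two swing-leg sensors by forward-Euler integration.

    The vertical rates of thigh and lower leg are assumed equal; the two
    measurements are averaged (symmetric, unbiased) and the mean rate is
    integrated with Euler's method from an initial angle of zero, so the
    two returned series are identical by construction.
    """
    if thigh.n != lower.n:
        raise ValueError(
            f"thigh and lower-leg series lengths differ: {thigh.n} != {lower.n}"
        )
    dt = 1.0 / thigh.f_s
    omega = 0.5 * (vertical_rate(thigh, thigh_att) + vertical_rate(lower, lower_att))
    psi = np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt])
    return psi, psi.copy()


# ---------------------------------------------------------------------------
# acceleration transform

def transform_accel(
    imu: ImuSeries,
    att: AttitudeSeries,
    g: float = STANDARD_GRAVITY,
    accel_kind: str = "specific_force",
) -> np.ndarray:
    """Gravity-free stationary-frame acceleration ``(n, 3)`` [m/s^2].

    For accelerometer (specific-force) input, ``a = T a_tilde - [0,0,g]``:
    a stationary sensor at any attitude yields zero.  If the stream already
    holds kinematic acceleration in the sensor frame (a synthetic-data
    option used to pin down the gravity-handling contract), only the
    rotation is applied.
    """
    T = att.T
    a_world = np.einsum("nij,nj->ni", T, imu.specific_force)
    if accel_kind == "specific_force":
        a_world = a_world - np.array([0.0, 0.0, g])
    elif accel_kind != "kinematic":
        raise ValueError(f"unknown accel_kind {accel_kind!r}")
    return a_world
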