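"""Per-sample linear solves for the main-system COM (double inverted pendulum).

The stance leg and upper body form a planar double inverted pendulum in
each of the sagittal (X-Z) and frontal (Y-Z) planes, pivoting at the ankle
(height ``L_f``) and the stance hip (height ``L_f + L_m1``).  For small
tilt angles, three linear relations hold per sample:

1. horizontal force balance — segment COM accelerations against the
   horizontal plate force and the swing-leg hip force;
2. moment balance about the plate origin — including the hip force/couple
   and the gravity restoring moment, with the stance-hip horizontal
   position approximated by ``(L_m1/l_m) X_m`` (the hip is taken to lie on
   the ankle-to-COM line, as the individual segment displacement is not
   measurable);
3. the head-acceleration constraint — the head rides on top of the upper
   body, so its measured horizontal acceleration pins a combination of the
   two segment COM accelerations.

Solving the resulting 3x3 system per sample yields the segment COM
accelerations and the main-system COM displacement.  Both planes use the
plate channels in the subject-on-plate (action) convention for the
horizontal forces and moments, with ``F_z > 0`` under load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import BodyParams

DEFAULT_COND_LIMIT = 1e10


@dataclass
class ForcePlateSeries:
    """Force-platform channels about the platform origin.

    ``R`` is ``(n, 3)`` [N] and ``N`` is ``(n, 3)`` [N·m].  ``R[:, 2]``
    (vertical load) is positive when the plate is loaded; the horizontal
    forces and all moments follow the subject-on-plate convention with the
    X axis forward, Y left, Z up.
    """

    times: np.ndarray
    R: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.R = np.asarray(self.R, float)
        self.N = np.asarray(self.N, float)
        n = self.times.shape[0]
        if self.R.shape != (n, 3) or self.N.shape != (n, 3):
            raise ValueError("R and N must have shape (n, 3)")
        if n >= 2:
            dt = np.diff(self.times)
            if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean():
                raise ValueError("plate sampling must be uniform and increasing")

    @property
    def f_s(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return self.times.shape[0]


@dataclass
class PlaneSolution:
    """Solution of one plane's 3x3 system, per sample."""

    acc_m1: np.ndarray
    acc_m2: np.ndarray
    com: np.ndarray
    residual: np.ndarray
    flagged: np.ndarray
    coeffs: dict


def _structure_coeffs(params: BodyParams, J1: float, J2: float):
    """Unsigned moment-row magnitudes and the head-row coefficients.

    The sagittal moment row uses the negatives of the first two values
    (A21, A22) while the frontal row uses them as-is (B21, B22).
    """
    p = params
    b21 = (J1 / p.l_m1 + p.m_m1 * (p.L_f + p.l_m1)
           - J2 * p.L_m1 / (p.l_m1 * p.l_m2))
    b22 = J2 / p.l_m2 + p.m_m2 * (p.L_f + p.L_m1 + p.l_m2)
    h1 = p.L_m1 * (p.l_m2 - p.L_m2) / (p.l_m1 * p.l_m2)
    h2 = p.L_m2 / p.l_m2
    return b21, b22, h1, h2


def _solve_plane(
    c21: float,
    c22: float,
    c23: np.ndarray,
    h1: float,
    h2: float,
    rhs: np.ndarray,
    params: BodyParams,
    cond_limit: float,
) -> PlaneSolution:
    n = rhs.shape[0]
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = params.m_m1
    A[:, 0, 1] = params.m_m2
    A[:, 1, 0] = c21
    A[:, 1, 1] = c22
    A[:, 1, 2] = c23
    A[:, 2, 0] = h1
    A[:, 2, 1] = h2

    sv = np.linalg.svd(A, compute_uv=False)
    with np.errstate(divide="ignore"):
        cond = sv[:, 0] / sv[:, -1]
    flagged = ~np.isfinite(cond) | (cond > cond_limit)
    if flagged.all():
        raise ValueError("every per-sample system is singular or ill-conditioned")

    x = np.empty((n, 3))
    ok = ~flagged
    x[ok] = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
    # one-sample hold for flagged samples (first valid sample backfills)
    first_ok = int(np.flatnonzero(ok)[0])
    last = x[first_ok]
    for k in range(n):
        if flagged[k]:
            x[k] = last
        else:
            last = x[k]

    resid = np.linalg.norm(np.einsum("nij,nj->ni", A, x) - rhs, axis=1)
    scale = np.maximum(np.linalg.norm(rhs, axis=1), 1.0)
    return PlaneSolution(
        acc_m1=x[:, 0],
        acc_m2=x[:, 1],
        com=x[:, 2],
        residual=resid / scale,
        flagged=flagged,
        coeffs={"c21": c21, "c22": c22, "c23_first": float(c23[0]),
                "h1": h1, "h2": h2},
    )


def solve_sagittal(
    plate: ForcePlateSeries,
    hip,
    head_acc_x: np.ndarray,
    params: BodyParams,
    cond_limit: float = DEFAULT_COND_LIMIT,
) -> PlaneSolution:
    """Sagittal-plane solve for ``(Xddot_m1, Xddot_m2, X_m)`` per sample.

    Rows: force balance ``m_m1 Xddot_m1 + m_m2 Xddot_m2 = -R_x + R_sx``;
    moment balance with ``A21 = -J_m1y/l_m1 - m_m1(L_f+l_m1)
    + J_m2y L_m1/(l_m1 l_m2)``, ``A22 = -J_m2y/l_m2 - m_m2(L_f+L_m1+l_m2)``,
    ``A23 = (m_m1+m_m2) g - R_sz L_m1/l_m`` and right-hand side
    ``N_y - N_sy - R_sx (L_f + L_m1)``; head constraint equating the
    combined segment acceleration to the measured head acceleration.

    ``plate.R[:, 0]`` is expected to be drift-filtered already.  Samples
    whose 3x3 matrix exceeds ``cond_limit`` are flagged and held at the
    previous valid solution.
    """
    p = params
    b21, b22, h1, h2 = _structure_coeffs(p, p.J_m1y, p.J_m2y)
    a21, a22 = -b21, -b22
    R_sx, R_sz = hip.R_s[:, 0], hip.R_s[:, 2]
    N_sy = hip.N_s[:, 1]
    a23 = p.m_main * p.g - R_sz * (p.L_m1 / p.l_m)
    rhs = np.column_stack([
        -plate.R[:, 0] + R_sx,
        plate.N[:, 1] - N_sy - R_sx * (p.L_f + p.L_m1),
        np.asarray(head_acc_x, float),
    ])
    return _solve_plane(a21, a22, a23, h1, h2, rhs, p, cond_limit)


def solve_frontal(
    plate: ForcePlateSeries,
    hip,
    head_acc_y: np.ndarray,
    params: BodyParams,
    stance_side: str,
    cond_limit: float = DEFAULT_COND_LIMIT,
) -> PlaneSolution:
    """Frontal-plane solve for ``(Yddot_m1, Yddot_m2, Y_m)`` per sample.

    Mirror of :func:`solve_sagittal` with ``B21 = +J_m1x/l_m1
    + m_m1(L_f+l_m1) - J_m2x L_m1/(l_m1 l_m2)``, ``B22 = +J_m2x/l_m2
    + m_m2(L_f+L_m1+l_m2)``, ``B23 = -(m_m1+m_m2) g + R_sz L_m1/l_m``.
    The non-stance hip sits ``w`` to the side of the stance hip, so its
    vertical load contributes ``±R_sz w`` to the moment row: positive when
    the stance leg is the left one.
    """
    if stance_side not in ("right", "left"):
        raise ValueError(f"stance_side must be 'right' or 'left', got {stance_side!r}")
    p = params
    b21, b22, h1, h2 = _structure_coeffs(p, p.J_m1x, p.J_m2x)
    R_sy, R_sz = hip.R_s[:, 1], hip.R_s[:, 2]
    N_sx = hip.N_s[:, 0]
    b23 = -p.m_main * p.g + R_sz * (p.L_m1 / p.l_m)
    sign_w = 1.0 if stance_side == "left" else -1.0
    rhs = np.column_stack([
        -plate.R[:, 1] + R_sy,
        plate.N[:, 0] - N_sx + R_sy * (p.L_f + p.L_m1) + sign_w * R_sz * p.w,
        np.asarray(head_acc_y, float),
    ])
    return _solve_plane(b21, b22, b23, h1, h2, rhs, p, cond_limit)
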