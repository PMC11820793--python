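"""Whole-body COM fusion, center of pressure, and validation metrics.

The whole-body COM is the mass-weighted combination of the main-system COM
(from the per-sample pendulum solves) and the swing-leg COM (from the two
sensor attitudes), over the four moving segments; the static stance foot
is excluded.  The swing-leg COM lives in a frame anchored at the
non-stance hip, which sits ``w`` to the side of the stance hip — positive
toward the stance-left side — so the mediolateral fusion carries a
``±w`` offset (positive when standing on the right leg).  The hip's own
horizontal excursion is ignored, consistent with the pendulum
linearization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .anthropometry import BodyParams
from .main_system import ForcePlateSeries


@dataclass
class ComSeries:
    """Whole-body COM displacement per sample, AP (X) and ML (Y), in metres."""

    X_b: np.ndarray
    Y_b: np.ndarray

    def mean_removed(self) -> "ComSeries":
        return ComSeries(self.X_b - self.X_b.mean(), self.Y_b - self.Y_b.mean())


@dataclass
class CopSeries:
    """Center of pressure on the plate surface [m]; NaN where unloaded."""

    COP_X: np.ndarray
    COP_Y: np.ndarray


@dataclass
class MetricsReport:
    """Agreement between an estimated and a reference sway trace.

    ``r`` is Pearson's correlation over the evaluation window, ``rmse`` the
    root-mean-square error [same units as input], ``rms_ref`` the RMS of
    the mean-removed reference (sway amplitude), and ``rmse_rms_ratio``
    their ratio — the normalised accuracy measure.  ``rms_ref`` is about
    the window mean (the zero level of a sway trace is arbitrary).
    """

    r: float
    rmse: float
    rms_ref: float
    rmse_rms_ratio: float
    window: tuple[int, int]


def combine_com(
    main_com: np.ndarray,
    sub_com,
    params: BodyParams,
    stance_side: str,
    plane: str,
) -> np.ndarray:
    """Fuse one plane's main-system COM with the swing-leg COM.

    Parameters
    ----------
    main_com : ndarray (n,)
        ``X_m`` or ``Y_m`` [m].
    sub_com : SubsystemComSeries
        Swing-leg COM in the hip frame.
    plane : {"sagittal", "frontal"}
        Selects the x or y component of the swing-leg COM; the frontal
        fusion adds the inter-hip offset ``+w`` for right stance, ``-w``
        for left.
    """
    if stance_side not in ("right", "left"):
        raise ValueError(f"stance_side must be 'right' or 'left', got {stance_side!r}")
    p = params
    if plane == "sagittal":
        s = sub_com.r_s[:, 0]
    elif plane == "frontal":
        off = p.w if stance_side == "right" else -p.w
        s = sub_com.r_s[:, 1] + off
    else:
        raise ValueError(f"plane must be 'sagittal' or 'frontal', got {plane!r}")
    return (p.m_main * np.asarray(main_com, float) + p.m_sub * s) / p.m_moving


def compute_cop(
    plate: ForcePlateSeries,
    sensor_depth: float = 0.0,
    min_load: float = 50.0,
) -> CopSeries:
    """Center of pressure from the plate channels.

    With the plate convention used throughout (horizontal forces and
    moments subject-on-plate, vertical load positive):
    ``COP_X = (N_y - h R_x) / R_z`` and ``COP_Y = (-N_x - h R_y) / R_z``,
    where ``h`` is the depth of the sensor plane below the surface
    (``sensor_depth``, default 0).  Samples with vertical load below
    ``min_load`` [N] are masked to NaN.
    """
    Rz = plate.R[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        cop_x = (plate.N[:, 1] - sensor_depth * plate.R[:, 0]) / Rz
        cop_y = (-plate.N[:, 0] - sensor_depth * plate.R[:, 1]) / Rz
    mask = Rz < min_load
    cop_x = np.where(mask, np.nan, cop_x)
    cop_y = np.where(mask, np.nan, cop_y)
    return CopSeries(COP_X=cop_x, COP_Y=cop_y)


def metrics(
    estimate: np.ndarray,
    reference: np.ndarray,
    window: tuple[int, int] = (1000, 4000),
) -> MetricsReport:
    """Pearson correlation and RMSE over an evaluation window.

    ``window`` is a half-open sample range ``[start, stop)``; the default
    covers 10-40 s of a 100 Hz record (3000 samples), keeping start-up
    transients and filter edges out of the score.  A constant reference
    leaves ``r`` undefined (NaN, with a warning); the RMSE is still
    reported.
    """
    e = np.asarray(estimate, float)
    t = np.asarray(reference, float)
    if e.shape != t.shape:
        raise ValueError(f"series lengths differ: {e.shape} vs {t.shape}")
    lo, hi = window
    if not (0 <= lo < hi <= e.shape[0]):
        raise ValueError(f"window {window} outside data of length {e.shape[0]}")
    ew, tw = e[lo:hi], t[lo:hi]
    de, dt_ = ew - ew.mean(), tw - tw.mean()
    denom = np.sqrt((de**2).sum() * (dt_**2).sum())
    if denom == 0.0:
        warnings.warn("reference (or estimate) is constant; r undefined",
                      stacklevel=2)
        r = float("nan")
    else:
        r = float((de * dt_).sum() / denom)
    rmse = float(np.sqrt(np.mean((ew - tw) ** 2)))
    rms_ref = float(np.sqrt(np.mean(dt_**2)))
    ratio = rmse / rms_ref if rms_ref > 0 else float("nan")
    return MetricsReport(r=r, rmse=rmse, rms_ref=rms_ref,
                         rmse_rms_ratio=ratio, window=(lo, hi))
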