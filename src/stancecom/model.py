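"""Model/Results interface tying the estimation pipeline together.

:class:`SingleLegStanceModel` is built from the measured data (plate
channels, three IMU streams, subject profile) plus an estimator
configuration; :meth:`SingleLegStanceModel.fit` runs the full pipeline —

    attitude estimation -> acceleration transform -> swing-leg COM and
    hip load -> drift filtering of the horizontal plate forces ->
    per-sample sagittal/frontal pendulum solves -> whole-body COM fusion ->
    COM/COP smoothing

— and returns a :class:`ComResults` carrying the estimated series,
per-stage intermediates, diagnostics and a text summary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import attitude as _att
from . import main_system as _ms
from . import signal_processing as _sp
from . import swing_leg as _sl
from . import whole_body as _wb
from .anthropometry import BodyParams, SubjectProfile, compute_body_params
from .attitude import AttitudeSeries, EkfConfig, ImuSeries
from .main_system import ForcePlateSeries


@dataclass(frozen=True)
class EstimatorConfig:
    """Every paper-unstated tunable of the pipeline, with defaults.

    ``accel_kind`` declares what the IMU acceleration channels contain —
    raw specific force (real sensors) or gravity-free kinematic
    acceleration (a synthetic-data option used in contract tests).
    """

    ekf: EkfConfig = field(default_factory=EkfConfig)
    force_filter: _sp.FilterSpec = _sp.FORCE_DRIFT_FILTER
    com_filter: _sp.FilterSpec = _sp.COM_SMOOTHING_FILTER
    smooth_output: bool = True
    accel_kind: str = "specific_force"
    cond_limit: float = _ms.DEFAULT_COND_LIMIT
    cop_min_load: float = 50.0
    cop_sensor_depth: float = 0.0
    eval_window_s: tuple[float, float] = (10.0, 40.0)


class SingleLegStanceModel:
    """Whole-body COM estimator for a single-leg-standing trial.

    Parameters
    ----------
    plate : ForcePlateSeries
        Force-platform record (100 Hz typical).
    imus : dict
        Mapping with keys ``"head"``, ``"thigh"``, ``"lower_leg"`` to
        :class:`~stancecom.attitude.ImuSeries`; entries are resolved by
        their declared ``placement``, not by the key, so swapped files
        with correct placement metadata still estimate identically.
    profile : SubjectProfile
    config : EstimatorConfig, optional
    """

    def __init__(
        self,
        plate: ForcePlateSeries,
        imus: dict,
        profile: SubjectProfile,
        config: EstimatorConfig | None = None,
    ):
        self.config = config or EstimatorConfig()
        self.profile = profile
        self.params: BodyParams = compute_body_params(profile)
        self.plate = plate
        resolved: dict[str, ImuSeries] = {}
        for imu in imus.values():
            if imu.placement in resolved:
                raise ValueError(f"duplicate IMU placement {imu.placement!r}")
            resolved[imu.placement] = imu
        missing = set(_att.PLACEMENTS) - set(resolved)
        if missing:
            raise ValueError(f"missing IMU placements: {sorted(missing)}")
        self.imus = resolved
        n = plate.n
        for pl, imu in resolved.items():
            if imu.n != n:
                raise ValueError(
                    f"{pl} IMU has {imu.n} samples but the plate has {n}"
                )

    @classmethod
    def from_trial(cls, trial, config: EstimatorConfig | None = None
                   ) -> "SingleLegStanceModel":
        """Build the model directly from a synthetic trial."""
        cfg = config or EstimatorConfig()
        if trial.emitted_accel_kind != cfg.accel_kind:
            cfg = replace(cfg, accel_kind=trial.emitted_accel_kind)
        return cls(trial.plate, trial.imus, trial.profile, cfg)

    # ------------------------------------------------------------------
    def fit(self) -> "ComResults":
        """Run the estimation pipeline and return the results object."""
        cfg = self.config
        p = self.params
        plate = self.plate
        f_s = plate.f_s
        n = plate.n
        log: list[str] = [f"samples: {n} at {f_s:g} Hz"]

        # sanity: vertical load should be of the order of body weight
        weight = p.total_mass * p.g
        med = float(np.median(plate.R[:, 2]))
        if not (0.5 * weight <= med <= 1.5 * weight):
            log.append(
                f"WARNING: median vertical load {med:.1f} N outside "
                f"0.5-1.5x body weight {weight:.1f} N — check units/axes"
            )

        # 1. attitude
        att: dict[str, AttitudeSeries] = {
            pl: _att.estimate_roll_pitch(self.imus[pl], cfg.ekf)
            for pl in _att.PLACEMENTS
        }
        psi_s1, psi_s2 = _att.integrate_yaw(
            self.imus["thigh"], self.imus["lower_leg"],
            att["thigh"], att["lower_leg"],
        )
        att["thigh"] = att["thigh"].with_yaw(psi_s1)
        att["lower_leg"] = att["lower_leg"].with_yaw(psi_s2)
        n_lowobs = int(sum(a.low_observability.sum() for a in att.values()))
        log.append(f"attitude: EKF done, {n_lowobs} low-observability samples")

        # 2. stationary-frame gravity-free accelerations
        acc = {
            pl: _att.transform_accel(self.imus[pl], att[pl], p.g, cfg.accel_kind)
            for pl in _att.PLACEMENTS
        }

        # 3. swing-leg COM and hip load
        sub_com = _sl.segment_coms(att["thigh"], att["lower_leg"], p)
        hip = _sl.hip_load(
            att["thigh"], att["lower_leg"],
            acc["thigh"], acc["lower_leg"],
            self.imus["thigh"].angular_velocity,
            self.imus["lower_leg"].angular_velocity,
            sub_com, p, f_s,
        )
        log.append("swing leg: COM and hip load computed")

        # 4. drift-filter the small horizontal plate forces
        R_filt = plate.R.copy()
        R_filt[:, 0] = _sp.zero_phase_filter(plate.R[:, 0], cfg.force_filter, f_s)
        R_filt[:, 1] = _sp.zero_phase_filter(plate.R[:, 1], cfg.force_filter, f_s)
        plate_f = ForcePlateSeries(plate.times, R_filt, plate.N)

        # 5. per-sample pendulum solves
        sag = _ms.solve_sagittal(plate_f, hip, acc["head"][:, 0], p,
                                 cfg.cond_limit)
        fro = _ms.solve_frontal(plate_f, hip, acc["head"][:, 1], p,
                                self.profile.stance_side, cfg.cond_limit)
        log.append(
            "main system: sagittal A21={c21:.3f} A22={c22:.3f} A23={c23_first:.1f}"
            .format(**sag.coeffs))
        log.append(
            "main system: frontal B21={c21:.3f} B22={c22:.3f} B23={c23_first:.1f}"
            .format(**fro.coeffs))
        log.append(
            f"main system: flagged samples sagittal={int(sag.flagged.sum())} "
            f"frontal={int(fro.flagged.sum())}")

        # 6. fuse and smooth
        X_b = _wb.combine_com(sag.com, sub_com, p, self.profile.stance_side,
                              "sagittal")
        Y_b = _wb.combine_com(fro.com, sub_com, p, self.profile.stance_side,
                              "frontal")
        cop = _wb.compute_cop(plate, cfg.cop_sensor_depth, cfg.cop_min_load)
        if cfg.smooth_output:
            X_b = _sp.zero_phase_filter(X_b, cfg.com_filter, f_s)
            Y_b = _sp.zero_phase_filter(Y_b, cfg.com_filter, f_s)
            cop = _wb.CopSeries(
                _filter_masked(cop.COP_X, cfg.com_filter, f_s),
                _filter_masked(cop.COP_Y, cfg.com_filter, f_s),
            )
        log.append("fusion: whole-body COM and COP ready")

        return ComResults(
            model=self,
            com=_wb.ComSeries(X_b=X_b, Y_b=Y_b),
            cop=cop,
            sagittal=sag,
            frontal=fro,
            hip_load=hip,
            sub_com=sub_com,
            attitudes=att,
            accelerations=acc,
            log=log,
        )


def _filter_masked(x: np.ndarray, spec, f_s: float) -> np.ndarray:
    """Low-pass a series that may contain NaN-masked (unloaded) stretches."""
    if np.isnan(x).any():
        out = np.full_like(x, np.nan)
        ok = ~np.isnan(x)
        # filter only the leading valid run; masked samples stay NaN
        idx = np.flatnonzero(ok)
        if idx.size:
            seg = x[idx[0]: idx[-1] + 1]
            if not np.isnan(seg).any():
                out[idx[0]: idx[-1] + 1] = _sp.zero_phase_filter(seg, spec, f_s)
            else:
                out[ok] = x[ok]
        return out
    return _sp.zero_phase_filter(x, spec, f_s)


@dataclass
class ComResults:
    """Estimation results for one trial.

    Attributes
    ----------
    com : ComSeries
        Whole-body COM displacement [m], AP (X) and ML (Y).
    cop : CopSeries
        Center of pressure [m].
    sagittal, frontal : PlaneSolution
        Per-plane pendulum solutions (segment accelerations, main COM,
        residuals, flags, first-sample coefficients).
    hip_load : HipLoadSeries
    sub_com : SubsystemComSeries
    attitudes : dict of AttitudeSeries
    accelerations : dict of ndarray
    log : list of str
        Stage-by-stage pipeline log.
    """

    model: SingleLegStanceModel
    com: _wb.ComSeries
    cop: _wb.CopSeries
    sagittal: _ms.PlaneSolution
    frontal: _ms.PlaneSolution
    hip_load: _sl.HipLoadSeries
    sub_com: _sl.SubsystemComSeries
    attitudes: dict
    accelerations: dict
    log: list

    @property
    def times(self) -> np.ndarray:
        return self.model.plate.times

    def eval_window(self) -> tuple[int, int]:
        lo_s, hi_s = self.model.config.eval_window_s
        f_s = self.model.plate.f_s
        return int(round(lo_s * f_s)), int(round(hi_s * f_s))

    # ------------------------------------------------------------------
    def metrics(self, reference: _wb.ComSeries,
                window: tuple[int, int] | None = None) -> dict:
        """Per-plane agreement metrics against a reference COM series."""
        win = window or self.eval_window()
        return {
            "sagittal": _wb.metrics(self.com.X_b, reference.X_b, win),
            "frontal": _wb.metrics(self.com.Y_b, reference.Y_b, win),
        }

    def to_frame(self) -> pd.DataFrame:
        """COM/COP output table in reporting units (mm)."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "COM_X_mm": self.com.X_b * 1e3,
                "COM_Y_mm": self.com.Y_b * 1e3,
                "COP_X_mm": self.cop.COP_X * 1e3,
                "COP_Y_mm": self.cop.COP_Y * 1e3,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        lo, hi = self.eval_window()
        lo = min(lo, len(self.times) - 1)
        buf = _io.StringIO()
        w = buf.write
        w("Single-leg stance COM estimation\n")
        w("=" * 48 + "\n")
        w(f"subject: H={m.profile.height:.3f} m, M={m.profile.mass:.1f} kg, "
          f"stance={m.profile.stance_side}\n")
        w(f"samples: {m.plate.n} at {m.plate.f_s:g} Hz\n")
        w(f"evaluation window: samples {lo}..{hi}\n")
        for plane, sol, series in (
            ("sagittal", self.sagittal, self.com.X_b),
            ("frontal", self.frontal, self.com.Y_b),
        ):
            sw = series[lo:hi] if hi <= len(series) else series
            rms = float(np.sqrt(np.mean((sw - sw.mean()) ** 2)))
            w(f"{plane:9s}: sway RMS {rms * 1e3:6.2f} mm | "
              f"max |residual| {sol.residual.max():.2e} | "
              f"flagged {int(sol.flagged.sum())}\n")
        w("pipeline log:\n")
        for line in self.log:
            w(f"  - {line}\n")
        return buf.getvalue()

    def plot(self, reference: _wb.ComSeries | None = None, show: bool = False):
        """Time-series plot of COM (and COP) per plane; returns the figure."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
        t = self.times
        for ax, est, cop, ref, label in (
            (axes[0], self.com.X_b, self.cop.COP_X,
             None if reference is None else reference.X_b, "AP (X)"),
            (axes[1], self.com.Y_b, self.cop.COP_Y,
             None if reference is None else reference.Y_b, "ML (Y)"),
        ):
            ax.plot(t, (est - np.nanmean(est)) * 1e3, label="COM estimate")
            ax.plot(t, (cop - np.nanmean(cop)) * 1e3, alpha=0.6, label="COP")
            if ref is not None:
                ax.plot(t, (ref - np.nanmean(ref)) * 1e3, "k--", lw=0.8,
                        label="reference")
            ax.set_ylabel(f"{label} [mm]")
            ax.legend(loc="upper right", fontsize=8)
        axes[1].set_xlabel("time [s]")
        fig.tight_layout()
        if show:  # pragma: no cover
            plt.show()
        return fig
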