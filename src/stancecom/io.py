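"""CSV formats, run configuration, and trial-bundle round-tripping.

All CSVs use SI units internally except the COM/COP reporting tables,
which are in millimetres (the field's reporting unit):

* force plate:  ``time_s, Fx, Fy, Fz, Mx, My, Mz``  [N, N·m]
* IMU:          ``time_s, ax, ay, az, gx, gy, gz``  [m/s^2, rad/s]
* COM (truth/reference/output): ``time_s, COM_X_mm, COM_Y_mm`` (+ COP
  columns on the estimator output)

The run configuration is a flat ``KEY = value`` text file; every
paper-unstated tunable of the pipeline lives there with a default, and
``stancecom estimate --dump-config`` prints the full set.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import STANDARD_GRAVITY, SubjectProfile
from .attitude import EkfConfig, ImuSeries, euler_to_matrix
from .main_system import ForcePlateSeries
from .model import EstimatorConfig
from .signal_processing import FilterSpec
from .whole_body import ComSeries

_FLOAT_FMT = "%.10g"


class UserError(Exception):
    """A problem the user can fix (bad file, bad config, bad value)."""


# ---------------------------------------------------------------------------
# CSV readers/writers

def _read_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise UserError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise UserError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise UserError(f"{path}: missing columns {missing} (line 1)")
    bad = df[list(columns)].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        raise UserError(f"{path}: ill-formed value at line {int(bad.idxmax()) + 2}")
    return df


def read_plate_csv(path) -> ForcePlateSeries:
    df = _read_csv(path, ("time_s", "Fx", "Fy", "Fz", "Mx", "My", "Mz"))
    return ForcePlateSeries(
        times=df["time_s"].to_numpy(),
        R=df[["Fx", "Fy", "Fz"]].to_numpy(),
        N=df[["Mx", "My", "Mz"]].to_numpy(),
    )


def write_plate_csv(plate: ForcePlateSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": plate.times,
            "Fx": plate.R[:, 0], "Fy": plate.R[:, 1], "Fz": plate.R[:, 2],
            "Mx": plate.N[:, 0], "My": plate.N[:, 1], "Mz": plate.N[:, 2],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_imu_csv(path, placement: str, mount_rpy_deg=(0.0, 0.0, 0.0)) -> ImuSeries:
    """Read one IMU stream; ``mount_rpy_deg`` is an optional fixed
    sensor-to-segment rotation (yaw, pitch, roll order as usual)."""
    df = _read_csv(path, ("time_s", "ax", "ay", "az", "gx", "gy", "gz"))
    acc = df[["ax", "ay", "az"]].to_numpy()
    gyr = df[["gx", "gy", "gz"]].to_numpy()
    if any(v != 0.0 for v in mount_rpy_deg):
        yaw, pitch, roll = np.deg2rad(mount_rpy_deg)
        R = euler_to_matrix(yaw, pitch, roll)
        acc = acc @ R.T
        gyr = gyr @ R.T
    return ImuSeries(df["time_s"].to_numpy(), acc, gyr, placement=placement)


def write_imu_csv(imu: ImuSeries, path) -> None:
    a, g = imu.specific_force, imu.angular_velocity
    pd.DataFrame(
        {
            "time_s": imu.times,
            "ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2],
            "gx": g[:, 0], "gy": g[:, 1], "gz": g[:, 2],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_com_csv(path) -> tuple[np.ndarray, ComSeries]:
    df = _read_csv(path, ("time_s", "COM_X_mm", "COM_Y_mm"))
    return df["time_s"].to_numpy(), ComSeries(
        X_b=df["COM_X_mm"].to_numpy() * 1e-3,
        Y_b=df["COM_Y_mm"].to_numpy() * 1e-3,
    )


def write_com_csv(times: np.ndarray, com: ComSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": times,
            "COM_X_mm": com.X_b * 1e3,
            "COM_Y_mm": com.Y_b * 1e3,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# synthetic bundle

def write_trial_bundle(trial, outdir) -> dict:
    """Write a synthetic trial as the estimator's CSV bundle plus manifest.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plate_csv(trial.plate, outdir / "plate.csv")
    for pl, imu in trial.imus.items():
        write_imu_csv(imu, outdir / f"imu_{pl}.csv")
    write_com_csv(trial.times, trial.truth["com"], outdir / "com_truth.csv")
    manifest = {
        "condition": trial.preset.condition,
        "seed": trial.preset.seed,
        "duration_s": trial.preset.duration,
        "f_s": trial.preset.f_s,
        "stance_side": trial.profile.stance_side,
        "subject": {"height_m": trial.profile.height,
                    "mass_kg": trial.profile.mass},
        "noise": {
            "accel_sigma": trial.noise.accel_sigma,
            "gyro_sigma": trial.noise.gyro_sigma,
            "gyro_bias": trial.noise.gyro_bias,
            "force_sigma": trial.noise.force_sigma,
            "moment_sigma": trial.noise.moment_sigma,
        },
        "accel_kind": trial.emitted_accel_kind,
        "files": {
            "plate": "plate.csv",
            "imu_head": "imu_head.csv",
            "imu_thigh": "imu_thigh.csv",
            "imu_lower_leg": "imu_lower_leg.csv",
            "com_truth": "com_truth.csv",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config = dict(
        DEFAULT_CONFIG,
        subject_height_m=trial.profile.height,
        subject_mass_kg=trial.profile.mass,
        stance_side=trial.profile.stance_side,
        plate_csv="plate.csv",
        imu1_csv="imu_head.csv", imu1_placement="head",
        imu2_csv="imu_thigh.csv", imu2_placement="thigh",
        imu3_csv="imu_lower_leg.csv", imu3_placement="lower_leg",
        reference_csv="com_truth.csv",
        accel_kind=trial.emitted_accel_kind,
    )
    dump_config(config, outdir / "run.cfg")
    return manifest


# ---------------------------------------------------------------------------
# run configuration (flat KEY = value)

DEFAULT_CONFIG: dict = {
    "subject_height_m": 1.70,
    "subject_mass_kg": 62.0,
    "stance_side": "right",
    "gravity": STANDARD_GRAVITY,
    "plate_csv": "plate.csv",
    "imu1_csv": "imu_head.csv", "imu1_placement": "head",
    "imu1_mount_rpy_deg": "0 0 0",
    "imu2_csv": "imu_thigh.csv", "imu2_placement": "thigh",
    "imu2_mount_rpy_deg": "0 0 0",
    "imu3_csv": "imu_lower_leg.csv", "imu3_placement": "lower_leg",
    "imu3_mount_rpy_deg": "0 0 0",
    "reference_csv": "",
    "accel_kind": "specific_force",
    "force_highpass_hz": 0.1,
    "force_filter_order": 4,
    "com_lowpass_hz": 3.0,
    "com_filter_order": 4,
    "smooth_output": True,
    "ekf_gyro_noise_density": 0.005,
    "ekf_accel_sigma": 1.0,
    "ekf_p0": 0.1,
    "ekf_innovation_gate": 16.27,
    "ekf_low_accel_fraction": 0.25,
    "cond_limit": 1e10,
    "cop_min_load_N": 50.0,
    "cop_sensor_depth_m": 0.0,
    "eval_window_start_s": 10.0,
    "eval_window_end_s": 40.0,
    "output_dir": ".",
    "seed": 0,
}


def parse_config(path) -> dict:
    """Parse a flat ``KEY = value`` config file against the defaults."""
    path = Path(path)
    if not path.exists():
        raise UserError(f"config file not found: {path}")
    cfg = dict(DEFAULT_CONFIG)
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise UserError(f"{path}: line {ln}: expected KEY = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in cfg:
            raise UserError(f"{path}: line {ln}: unknown key {key!r}")
        default = DEFAULT_CONFIG[key]
        try:
            if isinstance(default, bool):
                cfg[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int) and not isinstance(default, bool):
                cfg[key] = int(value)
            elif isinstance(default, float):
                cfg[key] = float(value)
            else:
                cfg[key] = value
        except ValueError as exc:
            raise UserError(f"{path}: line {ln}: bad value for {key}: {value!r}"
                            ) from exc
    return cfg


def dump_config(cfg: dict, path=None) -> str:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def estimator_config_from(cfg: dict) -> EstimatorConfig:
    return EstimatorConfig(
        ekf=EkfConfig(
            gyro_noise_density=cfg["ekf_gyro_noise_density"],
            accel_sigma=cfg["ekf_accel_sigma"],
            p0=cfg["ekf_p0"],
            innovation_gate=cfg["ekf_innovation_gate"],
            low_accel_fraction=cfg["ekf_low_accel_fraction"],
            g=cfg["gravity"],
        ),
        force_filter=FilterSpec("highpass", cfg["force_highpass_hz"],
                                cfg["force_filter_order"]),
        com_filter=FilterSpec("lowpass", cfg["com_lowpass_hz"],
                              cfg["com_filter_order"]),
        smooth_output=cfg["smooth_output"],
        accel_kind=cfg["accel_kind"],
        cond_limit=cfg["cond_limit"],
        cop_min_load=cfg["cop_min_load_N"],
        cop_sensor_depth=cfg["cop_sensor_depth_m"],
        eval_window_s=(cfg["eval_window_start_s"], cfg["eval_window_end_s"]),
    )


def load_run_inputs(cfg: dict, base_dir: Path):
    """Resolve a parsed config into (plate, imus, profile, reference)."""
    base = Path(base_dir)

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        profile = SubjectProfile(cfg["subject_height_m"], cfg["subject_mass_kg"],
                                 cfg["stance_side"])
    except ValueError as exc:
        raise UserError(str(exc)) from exc
    plate = read_plate_csv(resolve(cfg["plate_csv"]))
    imus = {}
    for i in (1, 2, 3):
        placement = cfg[f"imu{i}_placement"]
        mount = tuple(float(x) for x in cfg[f"imu{i}_mount_rpy_deg"].split())
        imus[f"imu{i}"] = read_imu_csv(resolve(cfg[f"imu{i}_csv"]), placement,
                                       mount)
    reference = None
    if cfg["reference_csv"]:
        _, reference = read_com_csv(resolve(cfg["reference_csv"]))
    return plate, imus, profile, reference


# ---------------------------------------------------------------------------
# alignment (synchronization plumbing)

def align_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> int:
    """Lag (samples) maximising the cross-correlation of mean-removed
    ``a`` against ``b``; positive means ``b`` starts later."""
    from scipy import signal as _sig

    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    corr = _sig.correlate(a, b, mode="full")
    lags = _sig.correlation_lags(a.size, b.size, mode="full")
    keep = np.abs(lags) <= max_lag
    return int(lags[keep][np.argmax(corr[keep])])
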