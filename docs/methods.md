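# Methods

## The estimation problem

During single-leg standing the clinically relevant balance variable is the
horizontal displacement of the whole-body center of mass (COM), in the
anteroposterior (AP, X) and mediolateral (ML, Y) directions.  Optical
motion capture measures it accurately but is impractical in a clinic.
`stancecom` estimates it from practical instruments only: a force platform
under the stance foot and three small IMUs — one on the back of the head,
two on the thigh and lower leg of the raised (non-stance) leg.

The body is modelled as five rigid segments:

* **main system** — stance leg (`m1`) and upper body (`m2`), a planar
  double inverted pendulum pivoting at the ankle (height `L_f`) and the
  stance hip `P` (height `L_f + L_m1`), analysed independently in the
  sagittal and frontal planes;
* **subsystem** — the raised leg: thigh (`s1`) and lower leg + foot
  (`s2`), a two-link 3-D chain hanging from the non-stance hip `Q`, which
  sits a distance `w` to the side of `P` (both hips assumed at the same
  height);
* the **stance foot**, static on the plate.

All segment masses, lengths, COM heights and moments of inertia are fixed
regression multiples of subject mass `M` and height `H`
(`anthropometry.py`); the five mass fractions sum to exactly 1.

## Pipeline

1. **Attitude.**  Each IMU's roll and pitch are estimated by a two-state
   extended Kalman filter: Euler-angle kinematics driven by the gyro as
   the process model, the accelerometer compared against the predicted
   gravity direction as the measurement.  Yaw is unobservable without a
   magnetometer; for the two leg sensors it is obtained by forward-Euler
   integration (initial angle zero) of a *shared* vertical angular rate —
   the mean of the two sensors' stationary-frame z-rates, which are
   physically equal for a leg yawing about the vertical — suppressing
   independent drift.  Head yaw is pinned at zero (head facing forward).
2. **Gravity removal.**  Sensor-frame specific force is rotated into the
   stationary frame and gravity subtracted: `a = T a_sensor − [0,0,g]`.
   These are taken as the segment COM accelerations (the sensors ride at
   the segment COM heights).
3. **Swing-leg COM and hip load.**  Segment COMs follow from the two
   attitudes and the link geometry (`r_s1 = T_s1·[0,0,−(L_s1−l_s1)]`,
   etc.); the subsystem COM is their mass-weighted mean.  The force and
   couple the leg applies to the main system at `Q` come from Newton–Euler
   inverse dynamics: `R_si = −m_si a_si + m_si g_vec`, spin couples
   `N_si = T(J ω̇̃ + ω̃×Jω̃)` with the inertia tensor diagonal in the
   segment frame and `ω̇̃` by central differences, and
   `N_s = −N_s1 − N_s2 + r_s1×R_s1 + r_s2×R_s2`.  Because the measured
   accelerations are absolute, this moment balance about the instantaneous
   hip point is exact even while the hip itself sways.
4. **Drift filtering.**  The small horizontal plate forces are high-passed
   at 0.1 Hz (zero-phase) before use.
5. **Main-system solve.**  Per sample and per plane, a 3×3 linear system
   in (`ẍ_m1`, `ẍ_m2`, `X_m`): horizontal force balance, moment balance
   about the plate origin, and the head-acceleration constraint (the head
   rides on top of the upper body, so its measured horizontal acceleration
   pins a combination of the two segment accelerations).  The moment row
   approximates the stance-hip position by `(L_m1/l_m)X_m` — the hip taken
   on the ankle-to-COM line — since the individual segment displacement is
   not measurable.  The gravity-stiffness coefficient
   `(m_m1+m_m2)g − R_sz·L_m1/l_m` depends on the measured vertical hip
   load, so the matrix is assembled fresh each sample.  Ill-conditioned
   samples (condition number > 1e10) are flagged and held at the previous
   valid solution, never interpolated further.
6. **Fusion.**  Whole-body COM over the four moving segments:
   `X_b = [(m_m1+m_m2)X_m + (m_s1+m_s2)x_s]/M_eff`, and in ML the same
   with the inter-hip offset `±w` (positive for right stance).  The hip's
   own horizontal excursion is deliberately ignored, consistent with the
   linearization.  COM and COP are finally low-passed at 3 Hz
   (zero-phase).

Validation metrics (Pearson r, RMSE, RMSE/RMS) are computed over samples
1000–3999 (10–40 s at 100 Hz), keeping start-up transients and filter
edges out of the score.

## Sign conventions

Plate channels are stored in the subject-on-plate (action) convention for
the horizontal forces and all moments, with the vertical channel
sign-flipped so `Fz > 0` under load; X forward, Y left, Z up, moments
about the platform origin.  Under this convention the center of pressure
is `COP_X = (M_y − h F_x)/F_z`, `COP_Y = (−M_x − h F_y)/F_z`, with `h` the
sensor-plane depth (default 0), masked where `Fz < 50 N`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ekf.gyro_noise_density` | 0.005 rad/s/√Hz | process-noise growth of the tilt EKF |
| `ekf.accel_sigma` | 1.0 m/s² | accelerometer measurement sigma |
| `ekf.innovation_gate` | 16.27 | χ² gate (3 dof) for adaptive R inflation |
| `ekf.low_accel_fraction` | 0.25 | ‖f‖/g below which the update is skipped |
| `force_filter` | 0.1 Hz HP, order 4 | plate drift removal (zero-phase Butterworth) |
| `com_filter` | 3 Hz LP, order 4 | output smoothing (zero-phase Butterworth) |
| `cond_limit` | 1e10 | per-sample condition-number flag threshold |
| `cop_min_load` | 50 N | vertical load below which COP is masked |
| `eval_window_s` | (10, 40) | metrics window |
| `g` | 9.80665 m/s² | gravity (config-overridable) |

`ekf.accel_sigma` is deliberately much larger than the sensor's electrical
noise: the gravity measurement is corrupted mainly by body acceleration,
not by sensor noise, and an optimistic value drags body acceleration into
the tilt estimate — which corrupts the head-acceleration channel enough to
cost ~1 mm of COM accuracy at quiet-stance amplitudes.  With 1.0 m/s² the
tilt loop has a ~2 s time constant: slow enough to reject sway-band
acceleration, fast enough to bound gyro random walk.  On top of this, the
normalised innovation is χ²-gated: when it exceeds the gate (vigorous leg
movement), the measurement covariance is inflated proportionally and the
filter coasts on the gyro; a near-zero specific-force magnitude (free-fall
like) skips the update entirely and flags the sample.

## Numerical choices

* **Filter padding.**  Forward-backward filtering uses reflective padding
  of twice the slowest pole's settling length, `3/f_c` seconds — not the
  scipy default, which is proportional to the filter order only.  For the
  0.1 Hz high-pass the default padding leaves multi-second edge
  transients (~0.2 N) that reach well into the evaluation window.
* **Differentiation** is second-order central differences (one-sided at
  the edges) throughout; gyro pre-smoothing before differentiation is
  available but off by default (the spin-couple term is small and the
  3 Hz output filter removes what noise it passes).
* **Per-sample solves** use batched LAPACK with an SVD condition check;
  back-substitution residuals are retained (always < 1e-9 relative).
* **Yaw integration** is plain forward Euler from zero, matching the
  method's definition; the O(dt) quadrature bias at 0.75 Hz leg yaw is
  ~0.8 % of the rate amplitude and immaterial at 100 Hz.

## The synthetic-trial generator

`synthetic.generate_trial` is the package's testing backbone: it
prescribes smooth segment-angle trajectories (sums of sinusoids under a
C² quintic ramp, so every trial starts exactly at rest), evaluates the
full *nonlinear* rigid-body kinematics analytically (exact angular
velocities/accelerations and point accelerations along the kinematic
chain), and synthesises perfectly consistent sensor streams: IMU specific
force `Tᵀ(a − g_vec)` and body rates at the segment COMs, and plate
channels from whole-body Newton–Euler (no linearization).  Gaussian
sensor noise and a constant gyro bias can be layered on deterministically
from the preset seed.

Three presets mirror the experimental conditions: **A** quiet single-leg
stance; **B** 0.75 Hz up-and-down swinging of the raised leg (±12° thigh
pitch, ±8° shank pitch); **C** 0.75 Hz reciprocal yaw of the raised leg
(±15°), both thigh and shank yawing together.  The common quiet-stance
sway is 6 mm AP / 4 mm ML COM amplitude with components at 0.3 and 0.7 Hz
plus a small independent trunk wobble (20 % of the lean) so the two
pendulum links move distinguishably — calibrated once to the sway RMS
scale reported for adult single-leg stance, and validated to keep every
main-system tilt below the 5° linearization bound.  The swing leg's
baseline pose is raised in front (thigh −30°, shank −10° pitch).  The
main-segment z-axis inertias, which the pendulum model never uses, are
set to the corresponding x-axis values in the generator (their effect on
the plate moment is O(θ̇φ̇) at sub-degree tilts — numerically invisible).

What the generator does *not* emulate: physiological balance control
(trajectories are prescribed, not feedback-stabilised), soft-tissue
artefact, sensor mounting misalignment (hook provided, defaults to
identity), foot compliance, and plate drift (the high-pass stage is
exercised spectrally, not against a drift model).  Passing closed-loop
tests therefore demonstrates the estimator's correctness and its
linearization floor, not robustness to every artefact of real recordings.

## Accuracy floor and known limitations

With noiseless synthetic data the closed-loop COM RMSE over 10–40 s is
0.30–0.90 mm depending on condition and plane.  The dominant residual is
not sensor processing but the method's own fusion step: the hip joint's
horizontal excursion is ignored when the subsystem COM (expressed
relative to the hip) is combined with the main-system COM, which removes
`(m_s1+m_s2)/M_eff ≈ 17 %` of the hip displacement — effectively a ~13 %
gain deficit on the sway carried through the hip.  Two smaller,
structurally related approximations: the moment row's hip-on-line
substitution (first-order in the leg/trunk angle difference) and the
plain linearization (whose leading error is cubic, odd symmetry
cancelling the quadratic terms).  Consequences worth knowing:

* static absolute agreement between the fused COM and the COP is limited
  to ~1 % of the displacement (moving-segment COM vs all-mass COP) plus
  ~13 % of any hip excursion, so statics checks here compare
  *displacements* between poses whose hip stays put;
* correlations with ground truth remain ≥ 0.99 — the error is mostly a
  gain, not noise;
* realistic sensor noise (0.02 m/s² accel, 0.2 °/s gyro, 0.5 N force)
  adds almost nothing after the 3 Hz output filter (≤ 0.07 mm RMSE).

Other limitations inherited from the model: knee-extended stance only,
small main-system tilt, anthropometric-table body geometry, IMUs assumed
at segment COM height with axes aligned to the segment, and a head that
moves with the trunk.
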