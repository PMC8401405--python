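"""Benchmark evaluations of the two sensor paths against ground truth.

These helpers run the full estimation chain on simulated motions where
the true kinematics are known exactly, and report error and effect-size
measures.  They back both the test suite and the reproduction script.
"""
from __future__ import annotations

import numpy as np

from . import kinematics as kin
from .calibration import SegmentRotation
from .exposure import summarize
from .orientation import KalmanConfig, acc_lowpass_orientation, kalman_orientation
from .synthetic import Bout, MotionScript, SensorNoiseModel, cohort_scripts, \
    simulate_recording


def _rmse(est: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def arm_swing_rmse(
    seed: int = 1,
    duration_s: float = 120.0,
    sample_rate: float = 25.0,
    amplitude_deg: float = 90.0,
    period_s: float = 4.0,
    lever_arm_m: float = 0.25,
    warmup_s: float = 5.0,
    trim_end_s: float = 1.0,
) -> dict:
    """Angle and velocity RMSE of both sensor paths on a simple arm swing.

    Simulates sinusoidal 0-90 deg arm swings (4 s period, 0.25 m lever
    arm, default sensor noise, 120 s at 25 Hz), runs the
    accelerometer-only and the Kalman-fusion estimators with an identity
    mounting, and scores the inclination angle and inclination velocity
    against the exact ground truth.  The filter convergence interval at
    the start and the resampling edge at the end are excluded.
    """
    script = MotionScript(
        duration=duration_s, sample_rate=sample_rate,
        bouts=[Bout("inclination_swing", 0.0, duration_s,
                    amplitude=amplitude_deg, period=period_s)],
        lever_arm=lever_arm_m, tremor_amplitude_deg=0.0, seed=seed,
    )
    rec, truth = simulate_recording(script, SensorNoiseModel())
    rot = SegmentRotation(np.eye(3))
    keep = (rec.time >= warmup_s) & (rec.time <= duration_s - trim_end_s)

    out: dict = {"n_samples": int(keep.sum()), "seed": seed}
    for name, series in (
        ("acc", acc_lowpass_orientation(rec, rot)),
        ("acc_gyro", kalman_orientation(rec, rot, KalmanConfig())),
    ):
        angle = kin.arm_inclination(series)
        vel = kin.inclination_velocity(angle, series.sample_rate)
        out[f"{name}_angle_rmse_deg"] = _rmse(
            angle[keep], truth.inclination_deg[keep])
        out[f"{name}_velocity_rmse_dps"] = _rmse(
            vel[keep], truth.inclination_velocity_dps[keep])
    return out


def cohort_median_velocities(
    n_subjects: int = 6,
    seed: int = 7,
    duration_s: float = 150.0,
    lever_arm_m: float = 0.25,
    warmup_s: float = 2.0,
) -> dict:
    """Group-mean 50th-percentile arm velocities for the four variants.

    Simulates a cohort of fast manual-handling recordings and returns the
    group means of the per-subject median velocities for each combination
    of sensor path (acc / acc+gyro) and velocity definition
    (inclination / generalized).
    """
    scripts = cohort_scripts(n_subjects, seed=seed, duration=duration_s,
                             lever_arm=lever_arm_m, segment="arm")
    rot = SegmentRotation(np.eye(3))
    p50 = {key: [] for key in (("acc", "inclination"), ("acc", "generalized"),
                               ("acc_gyro", "inclination"),
                               ("acc_gyro", "generalized"))}
    for i, script in enumerate(scripts):
        rec, _ = simulate_recording(script, SensorNoiseModel())
        for g in (acc_lowpass_orientation(rec, rot),
                  kalman_orientation(rec, rot)):
            for kind in ("inclination", "generalized"):
                series = kin.arm_series(g, kind)
                summ = summarize(series, subject=f"s{i}", warmup_s=warmup_s)
                p50[(g.method, kind)].append(summ.velocity_percentiles[50])
    return {f"{m}_{k}_p50": float(np.mean(v)) for (m, k), v in p50.items()}
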