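"""Angles and angular velocities from a gravity-direction series.

The arm posture is the inclination angle — the great-circle angle between
the current gravity direction and the calibrated reference direction,
computed by the chord formula ``2*arcsin(|g_i - g_ref| / 2)``, which is
identical to ``arccos(g_i . g_ref)`` for unit vectors.  The trunk posture
is the signed sagittal inclination: the angle of the gravity vector's
projection onto the body sagittal plane relative to the body vertical,
forward bend positive.

Two angular-velocity definitions are supported:

* inclination velocity — absolute backward difference of the inclination
  angle times the sample rate; blind to any rotation that leaves the
  inclination unchanged (e.g. axial arm rotation);
* generalized velocity — the angle travelled by the gravity vector on the
  unit sphere per unit time, ``2*arcsin(|g_i - g_{i-1}| / 2) * fs``, which
  additionally captures rotation components perpendicular to gravity and
  therefore dominates the inclination velocity sample by sample.

All velocities are reported as absolute values in degrees per second.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .orientation import GravitySeries

_UNIT_TOL = 1e-6
#: samples with gravity closer than this to the lateral axis have an
#: undefined sagittal angle and are flagged invalid
LATERAL_GUARD_DEG = 1.0


@dataclass
class KinematicSeries:
    """Per-sample angle (deg) and velocity (deg/s) for one segment/method."""

    time: np.ndarray
    angle_deg: np.ndarray
    velocity_dps: np.ndarray
    segment: str               # "arm" | "trunk"
    method: str                # "acc" | "acc_gyro"
    velocity_kind: str         # "inclination" | "generalized"
    sample_rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.time.shape[0], dtype=bool)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        header = (f"# segment={self.segment} method={self.method} "
                  f"velocity_kind={self.velocity_kind} "
                  f"sample_rate={self.sample_rate}\n")
        frame = pd.DataFrame({
            "time_s": self.time, "angle_deg": self.angle_deg,
            "velocity_dps": self.velocity_dps, "valid": self.valid.astype(int),
        })
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KinematicSeries":
        with open(path) as fh:
            tags = dict(item.split("=") for item in fh.readline()[1:].split())
            frame = pd.read_csv(fh)
        return cls(
            time=frame["time_s"].to_numpy(float),
            angle_deg=frame["angle_deg"].to_numpy(float),
            velocity_dps=frame["velocity_dps"].to_numpy(float),
            segment=tags["segment"], method=tags["method"],
            velocity_kind=tags["velocity_kind"],
            sample_rate=float(tags["sample_rate"]),
            valid=frame["valid"].to_numpy(bool),
        )


def _check_unit(v: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(np.atleast_2d(v), axis=-1)
    if not np.allclose(norms, 1.0, atol=_UNIT_TOL):
        raise ValueError(f"{what} must be unit vectors")


def chord_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Great-circle angle between unit vectors via 2*arcsin(chord/2)."""
    chord = np.linalg.norm(u - v, axis=-1)
    return np.degrees(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))


def arm_inclination(g: GravitySeries, g_ref: np.ndarray | None = None) -> np.ndarray:
    """Arm inclination angle (deg, in [0, 180]) from the reference direction.

    With a body-frame series the reference is the body vertical (0, 0, 1);
    pass ``g_ref`` to measure from another direction.
    """
    ref = np.array([0.0, 0.0, 1.0]) if g_ref is None else np.asarray(g_ref, float)
    _check_unit(ref, "g_ref")
    _check_unit(g.g_hat, "gravity series")
    return chord_angle_deg(g.g_hat, ref)


def trunk_sagittal_inclination(g: GravitySeries) -> tuple[np.ndarray, np.ndarray]:
    """Signed sagittal trunk angle (deg), forward positive, plus a valid mask.

    The angle is ``atan2(forward, vertical)`` of the body-frame gravity
    vector, continuous through deep bows (> 90 deg).  Samples with gravity
    within 1 deg of the lateral axis (projection nearly zero) are flagged.
    """
    _check_unit(g.g_hat, "gravity series")
    fwd, vert = g.g_hat[:, 0], g.g_hat[:, 2]
    angle = np.degrees(np.arctan2(fwd, vert))
    valid = np.hypot(fwd, vert) >= np.sin(np.radians(LATERAL_GUARD_DEG))
    angle = np.where(valid, angle, np.nan)
    return angle, valid


def inclination_velocity(angle_deg: np.ndarray, sample_rate: float,
                         scheme: str = "backward") -> np.ndarray:
    """Absolute angular velocity (deg/s) of an angle series.

    The default backward difference matches the pairwise construction of
    the generalized angle; a central scheme is available for sensitivity
    analysis.  The first sample (and last, for central) carries 0.
    """
    angle = np.asarray(angle_deg, dtype=float)
    v = np.zeros_like(angle)
    if scheme == "backward":
        v[1:] = np.abs(np.diff(angle)) * sample_rate
    elif scheme == "central":
        v[1:-1] = np.abs(angle[2:] - angle[:-2]) * sample_rate / 2.0
    else:
        raise ValueError("scheme must be 'backward' or 'central'")
    return v


def generalized_velocity(g: GravitySeries) -> np.ndarray:
    """Generalized angular velocity (deg/s): per-sample sphere arc * rate.

    Pure rotation about the gravity axis leaves the gravity vector fixed
    in the sensor frame and therefore contributes zero, even though the
    gyroscope would sense it.
    """
    _check_unit(g.g_hat, "gravity series")
    v = np.zeros(g.g_hat.shape[0])
    v[1:] = chord_angle_deg(g.g_hat[1:], g.g_hat[:-1]) * g.sample_rate
    return v


def arm_series(g: GravitySeries, velocity_kind: str,
               scheme: str = "backward") -> KinematicSeries:
    """Bundle arm angle + chosen velocity definition into a series."""
    angle = arm_inclination(g)
    if velocity_kind == "inclination":
        vel = inclination_velocity(angle, g.sample_rate, scheme)
    elif velocity_kind == "generalized":
        vel = generalized_velocity(g)
    else:
        raise ValueError("velocity_kind must be 'inclination' or 'generalized'")
    return KinematicSeries(g.time, angle, vel, "arm", g.method,
                           velocity_kind, g.sample_rate)


def trunk_series(g: GravitySeries, scheme: str = "backward") -> KinematicSeries:
    """Signed sagittal trunk angle with its (absolute) inclination velocity."""
    angle, valid = trunk_sagittal_inclination(g)
    filled = np.where(valid, angle, 0.0)  # flagged samples excluded downstream
    vel = inclination_velocity(filled, g.sample_rate, scheme)
    vel[~valid] = np.nan
    return KinematicSeries(g.time, angle, vel, "trunk", g.method,
                           "inclination", g.sample_rate, valid=valid)
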