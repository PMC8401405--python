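"""Sensor-to-segment calibration from reference postures.

Two scripted captures define the body frame of a segment: a reference
posture giving the segment's vertical (arm hanging with a hand weight, or
standing upright for the trunk) and a direction posture giving the
forward/abduction axis (90 deg arm abduction, or a forward bow).  From
the accelerometer vectors of these two postures a proper rotation ``R``
is built such that ``v_body = R @ v_sensor``, with the body frame
right-handed, vertical axis up (+z) and forward axis (+x) toward the
direction posture.

``R`` is constructed directly by Gram-Schmidt orthogonalization of the
two measured vectors; the equivalent Euler-angle factorization
``R = Rz(tz) @ Ry(ty) @ Rx(tx)`` is available for reporting.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .recording import RawImuRecording

#: minimum angular separation between reference and direction vectors
MIN_SEPARATION_DEG = 5.0
MIN_WINDOW_S = 3.0


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass
class CalibrationSet:
    """The two unit vectors (sensor frame) defining a segment's body frame."""

    segment: str
    ref_gravity_sensor: np.ndarray
    direction_vector_sensor: np.ndarray

    def __post_init__(self) -> None:
        self.ref_gravity_sensor = _unit(self.ref_gravity_sensor)
        self.direction_vector_sensor = _unit(self.direction_vector_sensor)
        cosang = float(np.clip(
            self.ref_gravity_sensor @ self.direction_vector_sensor, -1.0, 1.0
        ))
        if np.degrees(np.arccos(cosang)) < MIN_SEPARATION_DEG:
            raise ValueError(
                "reference and direction vectors are nearly parallel "
                f"(< {MIN_SEPARATION_DEG} deg apart): calibration failure"
            )


@dataclass
class SegmentRotation:
    """Proper rotation mapping sensor coordinates to body coordinates."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthonormal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("R must have determinant +1")

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate sensor-frame row vectors into the body frame."""
        return np.asarray(vectors, dtype=float) @ self.R.T

    @property
    def euler_zyx_deg(self) -> np.ndarray:
        """Euler angles (tz, ty, tx) of the Rz*Ry*Rx factorization, degrees."""
        return Rotation.from_matrix(self.R).as_euler("ZYX", degrees=True)

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"rotation_row_major": [float(x) for x in self.R.ravel()]}
        ))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentRotation":
        data = yaml.safe_load(Path(path).read_text())
        return cls(np.asarray(data["rotation_row_major"], float).reshape(3, 3))


def extract_reference_vector(
    recording: RawImuRecording,
    window: tuple[float, float],
    statistic: str = "median",
) -> np.ndarray:
    """Per-axis median/mean of the accelerometer over a window, unit-normalized.

    The window must span at least 3 s and lie inside the recording.  A
    resultant shorter than 0.5 g signals an invalid posture capture (the
    sensor was moving or the window mislabelled).
    """
    start, end = window
    if end - start < MIN_WINDOW_S:
        raise ValueError(f"calibration window must span >= {MIN_WINDOW_S} s")
    if start < recording.time[0] - 1e-9 or end > recording.time[-1] + 1e-9:
        raise ValueError("calibration window lies outside the recording")
    m = (recording.time >= start) & (recording.time <= end)
    if statistic == "median":
        vec = np.median(recording.acc[m], axis=0)
    elif statistic == "mean":
        vec = np.mean(recording.acc[m], axis=0)
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    norm = float(np.linalg.norm(vec))
    if norm < 0.5:
        raise ValueError(
            f"posture resultant {norm:.2f} g < 0.5 g: invalid capture"
        )
    return vec / norm


def stable_window(
    recording: RawImuRecording,
    interval: tuple[float, float],
    length_s: float = MIN_WINDOW_S,
) -> tuple[float, float]:
    """The sub-window of ``interval`` minimizing accelerometer variance.

    Operationalizes the 'stable 3-s window' of a held posture: slide a
    ``length_s`` window across the labelled interval and pick the position
    with the smallest total per-axis variance.
    """
    fs = recording.sample_rate
    i0 = int(np.searchsorted(recording.time, interval[0]))
    i1 = int(np.searchsorted(recording.time, interval[1], side="right"))
    w = int(round(length_s * fs))
    if i1 - i0 < w:
        raise ValueError("labelled interval shorter than the stable window")
    acc = recording.acc[i0:i1]
    best, best_var = 0, np.inf
    for k in range(0, acc.shape[0] - w + 1):
        v = float(acc[k:k + w].var(axis=0).sum())
        if v < best_var:
            best, best_var = k, v
    t0 = recording.time[i0 + best]
    return float(t0), float(t0 + length_s)


def build_segment_rotation(
    ref_gravity: np.ndarray,
    direction: np.ndarray,
    segment: str = "arm",
) -> SegmentRotation:
    """Build the sensor-to-body rotation from the two posture vectors.

    The body vertical is ``ref_gravity``; the body forward axis is the
    component of ``direction`` orthogonal to it (any vertical component of
    the direction posture — an arbitrary-angle bow, an imperfect 90 deg
    abduction — is projected away).
    """
    cal = CalibrationSet(segment, ref_gravity, direction)
    e3 = cal.ref_gravity_sensor
    d = cal.direction_vector_sensor
    e1 = _unit(d - (d @ e3) * e3)
    e2 = np.cross(e3, e1)
    return SegmentRotation(np.vstack([e1, e2, e3]))


def calibrate_segment(
    recording: RawImuRecording,
    segment: str,
    windows: dict[str, tuple[float, float]] | None = None,
) -> tuple[CalibrationSet, SegmentRotation]:
    """Run the full calibration for one segment from a posture recording.

    ``windows`` maps posture labels (``arm_ref``/``arm_direction`` or
    ``trunk_ref``/``trunk_direction``) to time intervals; if omitted they
    are taken from the recording's sidecar metadata.  Statistics follow
    the capture protocol: the arm reference and both direction postures
    use the median of a stable 3-s window, the trunk reference the mean.
    """
    windows = windows if windows is not None else recording.meta.get("windows")
    if not windows:
        raise ValueError("no calibration windows supplied or found in metadata")
    ref_label, dir_label = f"{segment}_ref", f"{segment}_direction"
    for label in (ref_label, dir_label):
        if label not in windows:
            raise ValueError(f"missing calibration posture window {label!r}")
    ref_stat = "mean" if segment == "trunk" else "median"
    ref = extract_reference_vector(recording, tuple(windows[ref_label]), ref_stat)
    direction = extract_reference_vector(
        recording, stable_window(recording, tuple(windows[dir_label])), "median"
    )
    cal = CalibrationSet(segment, ref, direction)
    return cal, build_segment_rotation(ref, direction, segment)
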