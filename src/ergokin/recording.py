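"""Raw IMU recording container and plain-text I/O.

A recording holds synchronized triaxial accelerometer (units of g) and
triaxial gyroscope (degrees per second) channels sampled at a nominal rate
(default 25 Hz).  On disk a recording is a CSV with a fixed header

    time_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps

plus an optional YAML sidecar (same stem, ``.yaml``) carrying the sampling
rate, sensor placement, the seed used to synthesize the file (if any), and
labelled calibration windows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

CSV_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]

#: maximum NaN gap (seconds) that is bridged by linear interpolation
MAX_BRIDGE_GAP_S = 1.0


@dataclass
class RawImuRecording:
    """Timestamped accelerometer + gyroscope samples from one sensor.

    Parameters
    ----------
    time : array of shape (n,)
        Sample times in seconds, strictly increasing.
    acc : array of shape (n, 3)
        Accelerometer specific force in units of g.
    gyro : array of shape (n, 3)
        Angular rate in degrees per second.
    sample_rate : float
        Nominal sampling rate in Hz.
    placement : str
        Body-segment tag, ``"arm"`` or ``"trunk"``.
    meta : dict
        Free-form metadata (seed, calibration windows, lever arm, ...).
    """

    time: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate: float
    placement: str = "arm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.time.shape[0]
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("acc and gyro must have shape (n, 3) matching time")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_samples else 0.0

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the recording as CSV plus a YAML sidecar with metadata."""
        path = Path(path)
        frame = pd.DataFrame(
            np.column_stack([self.time, self.acc, self.gyro]), columns=CSV_COLUMNS
        )
        frame.to_csv(path, index=False)
        if sidecar:
            side = {
                "sample_rate": float(self.sample_rate),
                "placement": self.placement,
                **{k: _plain(v) for k, v in self.meta.items()},
            }
            path.with_suffix(".yaml").write_text(yaml.safe_dump(side))


def _plain(value):
    """Coerce numpy scalars/arrays to YAML-safe builtins."""
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def read_recording(path: str | Path) -> RawImuRecording:
    """Read and validate a recording from CSV (+ optional YAML sidecar).

    NaN runs shorter than :data:`MAX_BRIDGE_GAP_S` are bridged by linear
    interpolation (and logged); longer runs reject the file.  Non-monotone
    time stamps reject the file.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if list(frame.columns) != CSV_COLUMNS:
        raise ValueError(
            f"malformed header in {path.name}: expected {CSV_COLUMNS}, "
            f"got {list(frame.columns)}"
        )
    time = frame["time_s"].to_numpy(float)
    if np.any(np.isnan(time)):
        raise ValueError(f"{path.name}: NaN in the time column")
    if time.size >= 2 and np.any(np.diff(time) <= 0):
        raise ValueError(f"{path.name}: non-monotone time stamps")

    meta: dict = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    sample_rate = float(meta.pop("sample_rate", _infer_rate(time)))
    placement = str(meta.pop("placement", "arm"))

    data = frame[CSV_COLUMNS[1:]].to_numpy(float)
    bad = np.isnan(data).any(axis=1)
    if bad.any():
        dt = 1.0 / sample_rate
        for start, stop in _runs(bad):
            gap_s = (stop - start) * dt
            if gap_s > MAX_BRIDGE_GAP_S:
                raise ValueError(
                    f"{path.name}: NaN gap of {gap_s:.2f} s exceeds "
                    f"{MAX_BRIDGE_GAP_S} s"
                )
            log.info("%s: bridged %.2f s NaN gap at sample %d", path.name, gap_s, start)
        for j in range(data.shape[1]):
            col = data[:, j]
            nan = np.isnan(col)
            col[nan] = np.interp(time[nan], time[~nan], col[~nan])

    return RawImuRecording(
        time=time, acc=data[:, :3], gyro=data[:, 3:], sample_rate=sample_rate,
        placement=placement, meta=meta,
    )


def _infer_rate(time: np.ndarray) -> float:
    if time.size < 2:
        raise ValueError("cannot infer sample rate from fewer than 2 samples")
    return 1.0 / float(np.median(np.diff(time)))


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return zip(idx[::2], idx[1::2])
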