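"""Gravity-direction estimation: accelerometer-only and Kalman fusion.

Both estimators output a :class:`GravitySeries` — per-sample unit vectors
pointing "up" in body coordinates at the recording's nominal 25 Hz.

*Accelerometer-only (``acc``)*: the accelerometer channels are low-pass
filtered by a linear-phase FIR built from a Blackman window (5 Hz cutoff,
25 taps at 25 Hz), rotated to the body frame and normalized per sample.
The filter's group delay is compensated so the output stays aligned with
the input time stamps.  During fast movement the centripetal and
tangential acceleration of the sensor fall inside the passband, which is
precisely the error source the fused path removes.

*Kalman fusion (``acc+gyro``)*: signals are resampled to 128 Hz and a
linear Kalman filter with state (gravity direction in sensor frame,
3-axis gyroscope bias) runs predict — rotate the gravity estimate by
``-(gyro - bias) * dt`` — and update — correct toward the normalized
accelerometer vector.  Process noise derives from the gyroscope white
noise (0.005 rad/s) and bias noise (0.0005 rad/s^2), measurement noise
from the accelerometer white noise (0.1 m/s^2, normalized by 9.81).  The
gravity estimate is renormalized each step, rotated to the body frame and
resampled back to 25 Hz with per-sample renormalization.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .calibration import SegmentRotation
from .recording import RawImuRecording
from .synthetic import GRAVITY

#: seconds of filter warm-up flagged for exclusion from exposure metrics
WARMUP_S = 2.0


@dataclass
class KalmanConfig:
    """Kalman filter noise design, defined at ``filter_rate`` Hz."""

    gyro_white_noise: float = 0.005   # rad/s
    gyro_bias_noise: float = 0.0005   # rad/s^2
    acc_white_noise: float = 0.1      # m/s^2
    filter_rate: float = 128.0        # Hz

    def __post_init__(self) -> None:
        for name in ("gyro_white_noise", "gyro_bias_noise",
                     "acc_white_noise", "filter_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GravitySeries:
    """Unit gravity-direction vectors in body coordinates over time."""

    time: np.ndarray
    g_hat: np.ndarray
    method: str                # "acc" | "acc_gyro"
    sample_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.g_hat = np.asarray(self.g_hat, dtype=float)
        if self.g_hat.shape != (self.time.shape[0], 3):
            raise ValueError("g_hat must have shape (n, 3)")
        norms = np.linalg.norm(self.g_hat, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gravity vectors must have unit norm")


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def design_lowpass(cutoff_hz: float = 5.0, numtaps: int = 25,
                   fs: float = 25.0) -> np.ndarray:
    """Linear-phase Blackman-window FIR low-pass (-6 dB at the cutoff)."""
    if numtaps % 2 == 0:
        raise ValueError("numtaps must be odd for integer group delay")
    return signal.firwin(numtaps, cutoff_hz, window="blackman", fs=fs)


def acc_lowpass_orientation(
    recording: RawImuRecording,
    rotation: SegmentRotation,
    cutoff_hz: float = 5.0,
    numtaps: int = 25,
) -> GravitySeries:
    """Accelerometer-only gravity estimation via Blackman FIR low-pass."""
    taps = design_lowpass(cutoff_hz, numtaps, recording.sample_rate)
    if recording.n_samples <= numtaps:
        raise ValueError("recording shorter than the low-pass filter")
    half = numtaps // 2
    padded = np.pad(recording.acc, ((half, half), (0, 0)), mode="reflect")
    filtered = np.column_stack([
        np.convolve(padded[:, j], taps, mode="valid") for j in range(3)
    ])
    g_body = _normalize_rows(rotation.apply(filtered))
    return GravitySeries(recording.time, g_body, "acc", recording.sample_rate)


def _resample(x: np.ndarray, fs_in: float, fs_out: float, n_out: int,
              kind: str = "polyphase") -> np.ndarray:
    """Resample columns of ``x`` from ``fs_in`` to ``fs_out`` Hz."""
    if kind == "polyphase":
        ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
        y = signal.resample_poly(x, ratio.numerator, ratio.denominator,
                                 axis=0, padtype="line", window=("kaiser", 8.0))
    elif kind == "linear":
        t_in = np.arange(x.shape[0]) / fs_in
        t_out = np.arange(n_out) / fs_out
        y = np.column_stack([
            np.interp(t_out, t_in, x[:, j]) for j in range(x.shape[1])
        ])
    else:
        raise ValueError("resampler must be 'polyphase' or 'linear'")
    if y.shape[0] < n_out:
        y = np.vstack([y, np.repeat(y[-1:], n_out - y.shape[0], axis=0)])
    return y[:n_out]


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def kalman_orientation(
    recording: RawImuRecording,
    rotation: SegmentRotation,
    config: KalmanConfig | None = None,
    resampler: str = "polyphase",
    return_state: bool = False,
):
    """Accelerometer + gyroscope gravity estimation by linear Kalman fusion.

    State: gravity direction (sensor frame) and per-axis gyroscope bias.
    Initial gravity from the first accelerometer sample, initial bias zero
    with a loose prior.  The bias component parallel to gravity is only
    weakly observable from gravity measurements; the filter keeps it at
    its prior.
    """
    cfg = config if config is not None else KalmanConfig()
    if not np.all(np.isfinite(recording.acc)) or not np.all(np.isfinite(recording.gyro)):
        raise ValueError("recording contains non-finite samples")
    fs0 = recording.sample_rate
    n0 = recording.n_samples
    n_hi = int(np.ceil(n0 * cfg.filter_rate / fs0))
    acc = _resample(recording.acc, fs0, cfg.filter_rate, n_hi, resampler)
    gyr = np.radians(_resample(recording.gyro, fs0, cfg.filter_rate, n_hi, resampler))

    dt = 1.0 / cfg.filter_rate
    q_g = (cfg.gyro_white_noise * dt) ** 2
    q_b = (cfg.gyro_bias_noise * dt) ** 2
    r_m = (cfg.acc_white_noise / GRAVITY) ** 2

    g = acc[0] / np.linalg.norm(acc[0])
    b = np.zeros(3)
    P = np.diag([1e-2] * 3 + [1e-4] * 3)  # loose prior, ~10x steady state
    Q = np.diag([q_g] * 3 + [q_b] * 3)
    I6 = np.eye(6)
    H = np.zeros((3, 6))
    H[:, :3] = np.eye(3)
    out = np.empty((n_hi, 3))
    bias_hist = np.empty((n_hi, 3)) if return_state else None
    for k in range(n_hi):
        # trapezoidal gyro over the step avoids a half-sample phase lag
        w = (0.5 * (gyr[k] + gyr[k - 1]) if k else gyr[0]) - b
        # predict: rotate the gravity estimate against the sensed rotation
        # (exact Rodrigues rotation; the covariance uses the linearization)
        ang = np.linalg.norm(w) * dt
        if ang > 1e-12:
            axis = w / np.linalg.norm(w)
            g = (g * np.cos(ang) - np.cross(axis, g) * np.sin(ang)
                 + axis * (axis @ g) * (1.0 - np.cos(ang)))
        g = g / np.linalg.norm(g)
        F = I6.copy()
        F[:3, :3] -= dt * _skew(w)
        F[:3, 3:] = -dt * _skew(g)
        P = F @ P @ F.T + Q
        # update toward the normalized accelerometer direction
        z = acc[k] / np.linalg.norm(acc[k])
        S = P[:3, :3] + r_m * np.eye(3)
        K = np.linalg.solve(S.T, P[:, :3].T).T     # P H^T S^-1
        innov = z - g
        g = g + K[:3] @ innov
        b = b + K[3:] @ innov
        P = (I6 - K @ H) @ P
        g = g / np.linalg.norm(g)
        out[k] = g
        if return_state:
            bias_hist[k] = b

    g_sensor = _resample(out, cfg.filter_rate, fs0, n0, resampler)
    g_body = _normalize_rows(rotation.apply(g_sensor))
    series = GravitySeries(recording.time, g_body, "acc_gyro", fs0)
    if return_state:
        state = {"time": np.arange(n_hi) / cfg.filter_rate,
                 "gravity_sensor": out, "bias": bias_hist}
        return series, state
    return series
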