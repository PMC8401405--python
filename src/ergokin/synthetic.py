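"""Synthetic IMU generator with rigid-body ground truth.

The generator scripts the motion of a body segment (upper arm or trunk)
that rotates about a fixed joint, and synthesizes the triaxial
accelerometer and gyroscope channels a sensor strapped to that segment
would record.  Every recording comes with exact ground-truth kinematics,
so each downstream processing stage can be validated without field data.

Kinematic model
---------------
The segment orientation is parameterized by two scripted angles:

* the inclination ``theta(t)`` — the tilt of the segment long axis away
  from the vertical, scripted as raised-cosine swings
  ``theta = A/2 * (1 - cos(2*pi*(t - t0)/T))`` so that each bout starts
  and ends at 0 with zero velocity, and
* the axial rotation ``psi(t)`` — a constant-rate spin about the segment
  long axis.

The rotation from segment to lab frame is ``R = Ry(-theta) @ Rz(psi)``.
The sensor sits on the segment axis at ``lever_arm`` metres from the
joint, so its linear acceleration contains the centripetal term
(omega^2 * r) and the tangential term (alpha * r) that contaminate
accelerometer-only tilt estimation during fast movement.  The
accelerometer channel is the specific force (gravity minus linear
acceleration) expressed in the sensor frame and in units of g; the
gyroscope channel is the body-frame angular velocity plus a constant (or
slowly walking) bias plus white noise.

Closed-form ground truth: the gravity (upward) direction in the segment
frame is ``(cos(psi) sin(theta), -sin(psi) sin(theta), cos(theta))``, the
inclination velocity is ``|dtheta/dt|`` and the generalized velocity —
the speed of the gravity vector on the unit sphere — is
``sqrt(dtheta^2 + (dpsi * sin(theta))^2)``, which dominates the
inclination velocity at every instant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .recording import RawImuRecording

#: standard gravity used to convert between m/s^2 and g
GRAVITY = 9.81

BOUT_KINDS = ("rest", "inclination_swing", "axial_rotation", "combined",
              "trunk_flexion_bout")
_INCLINING = ("inclination_swing", "combined", "trunk_flexion_bout")
_SPINNING = ("axial_rotation", "combined")


@dataclass
class Bout:
    """One scripted motion bout.

    ``amplitude`` (degrees) and ``period`` (seconds) shape the raised-cosine
    inclination swing; ``axial_rate`` (deg/s) is the constant spin rate about
    the segment long axis.  Fields irrelevant to the bout kind are ignored.
    """

    kind: str
    start: float
    end: float
    amplitude: float = 0.0
    period: float = 2.0
    axial_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in BOUT_KINDS:
            raise ValueError(f"unknown bout kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("bout end must exceed start")
        if not 0.0 <= self.amplitude <= 180.0:
            raise ValueError("amplitude must lie in [0, 180] degrees")
        if self.kind in _INCLINING and self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class MotionScript:
    """A full scripted recording: duration, rate, bouts, geometry, seed.

    ``tremor_amplitude_deg`` sets the RMS of a band-limited inclination
    jitter (a sum of random sinusoids in ``tremor_band_hz``) superimposed
    on the scripted bouts.  It stands in for the postural tremor and
    small rapid corrections that give real work-life movement its
    spectral content above the bout fundamentals; set it to 0 for
    idealized simple movements.
    """

    duration: float
    sample_rate: float = 25.0
    bouts: Sequence[Bout] = field(default_factory=list)
    lever_arm: float = 0.25
    tremor_amplitude_deg: float = 0.25
    tremor_band_hz: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.lever_arm < 0:
            raise ValueError("lever_arm must be non-negative")
        if self.tremor_amplitude_deg < 0:
            raise ValueError("tremor_amplitude_deg must be non-negative")
        bouts = sorted(self.bouts, key=lambda b: b.start)
        for b in bouts:
            if b.start < 0 or b.end > self.duration + 1e-9:
                raise ValueError("bouts must lie within [0, duration]")
        for prev, nxt in zip(bouts, bouts[1:]):
            if nxt.start < prev.end - 1e-9:
                raise ValueError("bouts must not overlap")
        self.bouts = list(bouts)


@dataclass
class SensorNoiseModel:
    """Additive sensor imperfections.

    Defaults mirror the Kalman design values (0.1 m/s^2 accelerometer
    white noise, 0.005 rad/s gyroscope white noise) plus a 0.01 rad/s
    constant gyroscope bias per axis.
    """

    acc_white_sd: float = 0.1          # m/s^2
    gyro_white_sd: float = 0.005       # rad/s
    gyro_bias: float | Sequence[float] = 0.01   # rad/s, scalar or per-axis
    gyro_bias_walk_sd: float = 0.0     # rad/s^2 (random-walk density)

    def __post_init__(self) -> None:
        if self.acc_white_sd < 0 or self.gyro_white_sd < 0 or self.gyro_bias_walk_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        self.gyro_bias = np.broadcast_to(
            np.asarray(self.gyro_bias, dtype=float), (3,)
        ).copy()


ZERO_NOISE = SensorNoiseModel(acc_white_sd=0.0, gyro_white_sd=0.0,
                              gyro_bias=0.0, gyro_bias_walk_sd=0.0)


@dataclass
class GroundTruth:
    """Exact kinematics underlying a synthetic recording."""

    time: np.ndarray                     # s
    gravity_body: np.ndarray             # (n, 3) unit upward vectors, body frame
    inclination_deg: np.ndarray          # [0, 180]
    inclination_velocity_dps: np.ndarray  # |d(inclination)/dt|
    generalized_velocity_dps: np.ndarray  # arc speed of gravity on the sphere
    angular_velocity_body: np.ndarray    # (n, 3) rad/s


# --------------------------------------------------------------------------
# scripted angle profiles
# --------------------------------------------------------------------------

def _profiles(script: MotionScript):
    """Per-sample (theta, dtheta, ddtheta, psi, dpsi) in radians from bouts."""
    n = int(round(script.duration * script.sample_rate))
    t = np.arange(n) / script.sample_rate
    theta = np.zeros(n)
    dtheta = np.zeros(n)
    ddtheta = np.zeros(n)
    dpsi = np.zeros(n)
    psi = np.zeros(n)
    for b in script.bouts:
        m = (t >= b.start) & (t < b.end)
        if b.kind in _INCLINING and b.amplitude > 0:
            w = 2.0 * np.pi / b.period
            half = 0.5 * np.radians(b.amplitude)
            ph = w * (t[m] - b.start)
            theta[m] = half * (1.0 - np.cos(ph))
            dtheta[m] = half * w * np.sin(ph)
            ddtheta[m] = half * w * w * np.cos(ph)
        if b.kind in _SPINNING and b.axial_rate != 0.0:
            rate = np.radians(b.axial_rate)
            dpsi[m] = rate
            psi += rate * np.clip(t - b.start, 0.0, b.end - b.start)
    if script.tremor_amplitude_deg > 0:
        # band-limited inclination jitter: K random sinusoids at the
        # requested RMS, drawn from a stream independent of sensor noise
        rng = np.random.default_rng([script.seed, 2**16 + 1])
        k = 6
        amp = np.radians(script.tremor_amplitude_deg) * np.sqrt(2.0 / k)
        freqs = rng.uniform(*script.tremor_band_hz, k)
        phases = rng.uniform(0.0, 2.0 * np.pi, k)
        for f, ph in zip(freqs, phases):
            w = 2.0 * np.pi * f
            theta += amp * np.sin(w * t + ph)
            dtheta += amp * w * np.cos(w * t + ph)
            ddtheta -= amp * w * w * np.sin(w * t + ph)
    return t, theta, dtheta, ddtheta, psi, dpsi


# --------------------------------------------------------------------------
# rigid-body synthesis
# --------------------------------------------------------------------------

def _synthesize(t, theta, dtheta, ddtheta, psi, dpsi, ddpsi, *,
                sample_rate, lever_arm, noise, rng, misalignment=None):
    """Turn angle profiles into noisy IMU channels plus ground truth.

    ``misalignment`` (3x3 proper rotation) maps segment-frame vectors into
    the sensor frame, modelling an imperfect mounting; ``None`` means the
    sensor axes coincide with the segment axes.
    """
    n = t.shape[0]
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(psi), np.cos(psi)

    g_body = np.column_stack([cp * st, -sp * st, ct])
    omega_body = np.column_stack([-dtheta * sp, -dtheta * cp, dpsi])

    # lab-frame angular velocity/acceleration of the segment
    omega_lab = np.column_stack([-dpsi * st, -dtheta, dpsi * ct])
    alpha_lab = np.column_stack([
        -ddpsi * st - dpsi * dtheta * ct,
        -ddtheta,
        ddpsi * ct - dpsi * dtheta * st,
    ])
    # sensor point on the segment axis, lever_arm below the joint
    p_lab = np.column_stack([lever_arm * st, np.zeros(n), -lever_arm * ct])
    a_lab = np.cross(alpha_lab, p_lab) + np.cross(
        omega_lab, np.cross(omega_lab, p_lab)
    )

    # specific force = gravity reaction minus linear acceleration, lab frame
    f_lab = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, GRAVITY)]) - a_lab
    seg_to_lab = Rotation.from_euler("zy", np.column_stack([psi, -theta]))
    f_seg = seg_to_lab.apply(f_lab, inverse=True)

    acc = f_seg / GRAVITY
    gyro_rad = omega_body.copy()
    if misalignment is not None:
        Q = np.asarray(misalignment, dtype=float)
        acc = acc @ Q.T
        gyro_rad = gyro_rad @ Q.T

    bias = np.broadcast_to(noise.gyro_bias, (n, 3)).copy()
    if noise.gyro_bias_walk_sd > 0:
        dt = 1.0 / sample_rate
        bias = bias + np.cumsum(
            rng.normal(0.0, noise.gyro_bias_walk_sd * np.sqrt(dt), (n, 3)), axis=0
        )
    if noise.acc_white_sd > 0:
        acc = acc + rng.normal(0.0, noise.acc_white_sd / GRAVITY, (n, 3))
    gyro_rad = gyro_rad + bias
    if noise.gyro_white_sd > 0:
        gyro_rad = gyro_rad + rng.normal(0.0, noise.gyro_white_sd, (n, 3))

    truth = GroundTruth(
        time=t,
        gravity_body=g_body,
        inclination_deg=np.degrees(np.abs(theta)),
        inclination_velocity_dps=np.abs(np.degrees(dtheta)),
        generalized_velocity_dps=np.degrees(
            np.sqrt(dtheta**2 + (dpsi * st) ** 2)
        ),
        angular_velocity_body=omega_body,
    )
    return acc, np.degrees(gyro_rad), truth


def simulate_recording(
    script: MotionScript,
    noise: SensorNoiseModel | None = None,
    *,
    placement: str = "arm",
    misalignment: np.ndarray | None = None,
    gyro_saturation_dps: float = 1000.0,
) -> tuple[RawImuRecording, GroundTruth]:
    """Simulate one work recording from a motion script.

    Returns the noisy recording and the exact ground truth.  Scripts whose
    true angular rate exceeds ``gyro_saturation_dps`` on any axis are
    rejected (the hardware range setting).  Deterministic given
    ``script.seed``.
    """
    noise = noise if noise is not None else SensorNoiseModel()
    t, theta, dtheta, ddtheta, psi, dpsi = _profiles(script)
    rng = np.random.default_rng(script.seed)
    acc, gyro, truth = _synthesize(
        t, theta, dtheta, ddtheta, psi, dpsi, np.zeros_like(dpsi),
        sample_rate=script.sample_rate, lever_arm=script.lever_arm,
        noise=noise, rng=rng, misalignment=misalignment,
    )
    peak = np.max(np.abs(np.degrees(truth.angular_velocity_body)), initial=0.0)
    if peak > gyro_saturation_dps:
        raise ValueError(
            f"scripted angular rate {peak:.0f} deg/s exceeds the "
            f"{gyro_saturation_dps:.0f} deg/s gyroscope range"
        )
    rec = RawImuRecording(
        time=t, acc=acc, gyro=gyro, sample_rate=script.sample_rate,
        placement=placement,
        meta={"seed": script.seed, "lever_arm": script.lever_arm},
    )
    return rec, truth


# --------------------------------------------------------------------------
# reference postures
# --------------------------------------------------------------------------

#: posture label -> (hold angle deg, stable window), per segment
_POSTURE_PLAN = {
    "arm": [("arm_ref", 0.0, 6.0, 0.0), ("arm_direction", 8.0, 18.0, 90.0)],
    "trunk": [("trunk_ref", 0.0, 6.0, 0.0), ("trunk_direction", 8.0, 14.0, 30.0)],
}
_RAMP_S = 2.0


def simulate_reference_postures(
    segment: str,
    noise: SensorNoiseModel | None = None,
    misalignment: np.ndarray | None = None,
    *,
    sample_rate: float = 25.0,
    seed: int = 0,
) -> RawImuRecording:
    """Simulate the scripted calibration captures for one segment.

    Produces a hanging/upright reference hold followed by a direction
    posture (90 deg abduction for the arm, a forward bow for the trunk),
    joined by smooth ramps.  Labelled stable windows (>= 3 s each) are
    stored in ``meta['windows']`` for the calibration stage.  The sensor is
    mounted at the given ``misalignment`` (segment -> sensor rotation).
    """
    if segment not in _POSTURE_PLAN:
        raise ValueError("segment must be 'arm' or 'trunk'")
    if misalignment is not None:
        Q = np.asarray(misalignment, dtype=float)
        if not (np.allclose(Q @ Q.T, np.eye(3), atol=1e-8)
                and np.isclose(np.linalg.det(Q), 1.0, atol=1e-8)):
            raise ValueError("misalignment must be a proper rotation")
    noise = noise if noise is not None else SensorNoiseModel()

    plan = _POSTURE_PLAN[segment]
    duration = plan[-1][2]
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    theta = np.zeros(n)
    dtheta = np.zeros(n)
    ddtheta = np.zeros(n)
    windows: dict[str, list[float]] = {}
    prev_angle = 0.0
    for label, start, end, angle_deg in plan:
        hold = (t >= start) & (t < end)
        theta[hold] = np.radians(angle_deg)
        # cosine ramp from the previous hold into this one
        if start > 0:
            ramp = (t >= start - _RAMP_S) & (t < start)
            u = (t[ramp] - (start - _RAMP_S)) / _RAMP_S
            a0, a1 = np.radians(prev_angle), np.radians(angle_deg)
            theta[ramp] = a0 + (a1 - a0) * 0.5 * (1 - np.cos(np.pi * u))
            dtheta[ramp] = (a1 - a0) * 0.5 * np.pi / _RAMP_S * np.sin(np.pi * u)
            ddtheta[ramp] = (a1 - a0) * 0.5 * (np.pi / _RAMP_S) ** 2 * np.cos(np.pi * u)
        prev_angle = angle_deg
        margin = 0.25 * (end - start)
        windows[label] = [round(start + margin, 3), round(end - margin, 3)]

    rng = np.random.default_rng(seed)
    zeros = np.zeros(n)
    acc, gyro, _ = _synthesize(
        t, theta, dtheta, ddtheta, zeros, zeros, zeros,
        sample_rate=sample_rate, lever_arm=0.0, noise=noise, rng=rng,
        misalignment=misalignment,
    )
    return RawImuRecording(
        time=t, acc=acc, gyro=gyro, sample_rate=sample_rate, placement=segment,
        meta={"seed": seed, "windows": windows},
    )


# --------------------------------------------------------------------------
# study cohort
# --------------------------------------------------------------------------

def cohort_scripts(
    n_subjects: int,
    seed: int = 0,
    *,
    duration: float = 150.0,
    sample_rate: float = 25.0,
    lever_arm: float = 0.25,
    segment: str = "arm",
) -> list[MotionScript]:
    """Scripts emulating a cohort of manual-handling work recordings.

    Each subject alternates rest pauses with swing bouts of variable
    amplitude (40-100 deg) and speed (1.8-3.5 s period); 60 % of the arm
    movement bouts carry a concurrent 30-90 deg/s axial rotation —
    mimicking the reach/lift/turn/place repertoire of order picking and
    palletizing.  A 0.5 deg RMS postural jitter in 1.5-4 Hz supplies the
    broadband movement content of real work (without it the accelerometer
    path shows none of its characteristic velocity inflation).  Trunk
    scripts use lower amplitudes (15-60 deg) and no axial component.
    Each subject gets an independent seed derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    scripts = []
    for s in range(n_subjects):
        bouts: list[Bout] = []
        cursor = float(rng.uniform(2.0, 6.0))
        while cursor < duration - 10.0:
            period = float(rng.uniform(1.8, 3.5))
            cycles = int(rng.integers(3, 8))
            length = min(period * cycles, duration - cursor - 1.0)
            length = period * max(1, int(length / period))  # whole periods
            if segment == "arm":
                amplitude = float(rng.uniform(40.0, 100.0))
                spin = rng.random() < 0.6
                bouts.append(Bout(
                    kind="combined" if spin else "inclination_swing",
                    start=cursor, end=cursor + length, amplitude=amplitude,
                    period=period,
                    axial_rate=float(rng.uniform(30.0, 90.0)) if spin else 0.0,
                ))
            else:
                amplitude = float(rng.uniform(15.0, 60.0))
                bouts.append(Bout(
                    kind="trunk_flexion_bout", start=cursor,
                    end=cursor + length, amplitude=amplitude, period=period,
                ))
            cursor += length + float(rng.uniform(3.0, 10.0))  # rest pause
        scripts.append(MotionScript(
            duration=duration, sample_rate=sample_rate, bouts=bouts,
            lever_arm=lever_arm, tremor_amplitude_deg=0.5,
            tremor_band_hz=(1.5, 4.0), seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return scripts
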