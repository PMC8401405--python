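"""End-to-end study pipeline: simulate -> calibrate -> orient -> summarize -> compare.

The pipeline reproduces the study design on synthetic cohorts: for each
subject a work recording (and reference-posture captures with a random
mounting misalignment) is simulated, the sensor-to-segment rotation is
calibrated, the gravity direction is estimated by both sensor paths, arm
kinematics are computed for both velocity definitions (plus the trunk
sagittal series), each series is summarized into exposure measures, and
the group-level comparisons, agreement fits, conversion factors, and
percentile-matched threshold conversions are derived.

Every numeric artifact is deterministic given the configured seed, and
each written table carries the configuration hash in its metadata line.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from . import exposure as expo
from . import kinematics as kin
from . import stats as gstats
from .calibration import calibrate_segment
from .orientation import KalmanConfig, acc_lowpass_orientation, kalman_orientation
from .synthetic import SensorNoiseModel, cohort_scripts, simulate_recording, \
    simulate_reference_postures

log = logging.getLogger(__name__)

ARM_VARIANTS = (("acc", "inclination"), ("acc", "generalized"),
                ("acc_gyro", "inclination"), ("acc_gyro", "generalized"))


@dataclass
class PipelineConfig:
    """Study configuration with the field-protocol defaults.

    Defaults: 25 Hz sampling, +/-1000 deg/s gyroscope range, 60 deg/s
    threshold limit value for the conversion step, 2 s filter warm-up
    exclusion, 0.25 m joint-to-sensor lever arm.
    """

    n_subjects: int = 6
    duration_s: float = 150.0
    sample_rate: float = 25.0
    seed: int = 0
    segments: tuple[str, ...] = ("arm", "trunk")
    lever_arm_m: float = 0.25
    gyro_range_dps: float = 1000.0
    threshold_dps: float = 60.0
    warmup_s: float = 2.0
    lowpass_cutoff_hz: float = 5.0
    lowpass_numtaps: int = 25
    max_misalignment_deg: float = 10.0
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    noise: SensorNoiseModel = field(default_factory=SensorNoiseModel)
    outdir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.kalman, dict):
            self.kalman = KalmanConfig(**self.kalman)
        if isinstance(self.noise, dict):
            self.noise = SensorNoiseModel(**self.noise)
        if self.sample_rate <= 0 or self.n_subjects < 1 or self.duration_s <= 0:
            raise ValueError("invalid pipeline configuration")
        if self.threshold_dps <= 0 or self.gyro_range_dps <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "segments" in data:
            data["segments"] = tuple(data["segments"])
        return cls(**data)

    def to_yaml_str(self) -> str:
        data = asdict(self)
        data["noise"]["gyro_bias"] = list(map(float, data["noise"]["gyro_bias"]))
        data["segments"] = list(self.segments)
        return yaml.safe_dump(data, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml_str().encode()).hexdigest()[:12]


def _random_misalignment(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_deg))
    return Rotation.from_rotvec(axis * angle).as_matrix()


def process_subject(subject_id, script, config, misalignment, cal_seed):
    """Simulate, calibrate and summarize one subject for one segment.

    Returns ``(series_by_variant, summaries)`` where the variant key is
    ``(method, velocity_kind)`` for the arm and ``(method, "inclination")``
    for the trunk.
    """
    segment = "trunk" if any(
        b.kind == "trunk_flexion_bout" for b in script.bouts) else "arm"
    rec, _truth = simulate_recording(
        script, config.noise, placement=segment, misalignment=misalignment,
        gyro_saturation_dps=config.gyro_range_dps,
    )
    ref = simulate_reference_postures(
        segment, config.noise, misalignment,
        sample_rate=config.sample_rate, seed=cal_seed,
    )
    _cal, rot = calibrate_segment(ref, segment)
    g_acc = acc_lowpass_orientation(rec, rot, config.lowpass_cutoff_hz,
                                    config.lowpass_numtaps)
    g_fus = kalman_orientation(rec, rot, config.kalman)
    series = {}
    if segment == "arm":
        for g in (g_acc, g_fus):
            for kind in ("inclination", "generalized"):
                series[(g.method, kind)] = kin.arm_series(g, kind)
    else:
        for g in (g_acc, g_fus):
            series[(g.method, "inclination")] = kin.trunk_series(g)
    summaries = {
        key: expo.summarize(s, subject=subject_id, warmup_s=config.warmup_s)
        for key, s in series.items()
    }
    return series, summaries


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study on a synthetic cohort; optionally write tables.

    Returns a bundle with the per-subject exposure table, group paired
    comparisons, agreement fits at the 10th/50th/90th percentiles, the
    chained conversion factors, and the percentile-matched threshold
    conversions.
    """
    rng = np.random.default_rng(config.seed)
    all_series: dict[str, dict] = {}
    all_summaries: list[expo.ExposureSummary] = []
    by_variant: dict[tuple, list[expo.ExposureSummary]] = {}

    for segment in config.segments:
        scripts = cohort_scripts(
            config.n_subjects, seed=int(rng.integers(0, 2**31 - 1)),
            duration=config.duration_s, sample_rate=config.sample_rate,
            lever_arm=config.lever_arm_m, segment=segment,
        )
        for i, script in enumerate(scripts):
            sid = f"s{i:02d}"
            mis = _random_misalignment(rng, config.max_misalignment_deg)
            series, summaries = process_subject(
                sid, script, config, mis, cal_seed=int(rng.integers(0, 2**31 - 1)))
            all_series.setdefault(sid, {}).update(
                {(segment,) + k: v for k, v in series.items()})
            for key, summ in summaries.items():
                by_variant.setdefault((segment,) + key, []).append(summ)
                all_summaries.append(summ)
            log.info("processed %s/%s (%d samples)", sid, segment,
                     script.duration * script.sample_rate)

    comparisons = _group_comparisons(by_variant)
    agreements, factors = _agreement_and_factors(by_variant)
    thresholds = _threshold_conversions(all_series, config.threshold_dps)

    bundle = {
        "config_hash": config.config_hash,
        "summaries": expo.summaries_to_frame(all_summaries),
        "comparisons": comparisons,
        "agreements": agreements,
        "conversion_factors": factors,
        "thresholds": thresholds,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _p50(summ: expo.ExposureSummary) -> float:
    return summ.velocity_percentiles[50]


_ARM_PAIRS = [
    ("arm vel p50: acc vs acc_gyro (incl)",
     ("arm", "acc", "inclination"), ("arm", "acc_gyro", "inclination")),
    ("arm vel p50: acc vs acc_gyro (gen)",
     ("arm", "acc", "generalized"), ("arm", "acc_gyro", "generalized")),
    ("arm vel p50: gen vs incl (acc)",
     ("arm", "acc", "generalized"), ("arm", "acc", "inclination")),
    ("arm vel p50: gen vs incl (acc_gyro)",
     ("arm", "acc_gyro", "generalized"), ("arm", "acc_gyro", "inclination")),
    ("arm vel p50: acc gen vs acc_gyro incl",
     ("arm", "acc", "generalized"), ("arm", "acc_gyro", "inclination")),
]
_TRUNK_PAIR = ("trunk vel p50: acc vs acc_gyro",
               ("trunk", "acc", "inclination"), ("trunk", "acc_gyro", "inclination"))


def _group_comparisons(by_variant) -> pd.DataFrame:
    rows = []
    pairs = [p for p in _ARM_PAIRS if p[1] in by_variant and p[2] in by_variant]
    if _TRUNK_PAIR[1] in by_variant:
        pairs.append(_TRUNK_PAIR)
    for label, ka, kb in pairs:
        a = np.array([_p50(s) for s in by_variant[ka]])
        b = np.array([_p50(s) for s in by_variant[kb]])
        cmp = gstats.paired_compare(a, b, label=label)
        rows.append({
            "label": label, "n": cmp.n, "mean_a": a.mean(), "mean_b": b.mean(),
            "mean_diff": cmp.mean_diff, "sd_diff": cmp.sd_diff,
            "test": cmp.test, "p_value": cmp.p_value,
            "significant": cmp.significant,
        })
    return pd.DataFrame(rows)


def _agreement_and_factors(by_variant):
    """Zero-intercept agreement fits per rank and the chained factors."""
    rows = []
    slopes = {}
    pairs = [p for p in _ARM_PAIRS if p[1] in by_variant and p[2] in by_variant]
    if _TRUNK_PAIR[1] in by_variant:
        pairs.append(_TRUNK_PAIR)
    for label, ka, kb in pairs:
        for rank in (10, 50, 90):
            a = np.array([s.velocity_percentiles[rank] for s in by_variant[ka]])
            b = np.array([s.velocity_percentiles[rank] for s in by_variant[kb]])
            if a.size < 3:
                log.warning("skipping agreement fit %s @p%d: fewer than "
                            "3 subjects", label, rank)
                continue
            # predictor is the fused/inclination side (b); slope converts b -> a
            model = gstats.fit_agreement(b, a, zero_intercept=True,
                                         label=f"{label} @p{rank}")
            rows.append({
                "label": label, "rank": rank, "r": model.r,
                "slope_b_to_a": model.slope, "bias": -model.bias,
                "loa_low": -model.loa_high, "loa_high": -model.loa_low,
            })
            if rank == 50:
                slopes[label] = model.slope
    factors = {}
    k1 = "arm vel p50: acc vs acc_gyro (incl)"
    k2 = "arm vel p50: gen vs incl (acc)"
    k3 = "arm vel p50: acc gen vs acc_gyro incl"
    if k1 in slopes and k2 in slopes:
        factors = {
            "fused_incl_to_acc_incl": round(slopes[k1], 2),
            "acc_incl_to_acc_gen": round(slopes[k2], 2),
            "chained_total": gstats.conversion_chain(slopes[k1], slopes[k2]),
        }
        if k3 in slopes:
            factors["measured_one_step"] = round(slopes[k3], 2)
    return pd.DataFrame(rows), factors


def _threshold_conversions(all_series, threshold: float) -> pd.DataFrame:
    """Map the acc generalized-velocity limit onto the other three conventions."""
    rows = []
    targets = [("arm", "acc", "inclination"), ("arm", "acc_gyro", "generalized"),
               ("arm", "acc_gyro", "inclination")]
    for sid, series in sorted(all_series.items()):
        src = series.get(("arm", "acc", "generalized"))
        if src is None:
            continue
        row = {"subject": sid, "acc_generalized": threshold}
        for key in targets:
            if key in series:
                row[f"{key[1]}_{key[2]}"] = expo.convert_threshold(
                    src, series[key], threshold)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        mean_row = frame.drop(columns="subject").mean().to_dict()
        frame = pd.concat(
            [frame, pd.DataFrame([{"subject": "group_mean", **mean_row}])],
            ignore_index=True)
    return frame


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml_str())
    stamp = f"# config_hash={bundle['config_hash']} seed={config.seed}\n"
    for name in ("summaries", "comparisons", "agreements", "thresholds"):
        frame = bundle[name]
        with open(outdir / f"{name}.csv", "w") as fh:
            fh.write(stamp)
            frame.to_csv(fh, index=False)
    (outdir / "conversion_factors.yaml").write_text(
        yaml.safe_dump({"config_hash": bundle["config_hash"],
                        **bundle["conversion_factors"]}))
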