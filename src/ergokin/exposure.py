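"""Per-subject exposure summaries and percentile-matched threshold conversion.

A half-workday kinematic series is condensed into APDF-style measures:
the mean, percentiles at fixed ranks, the 10th-90th percentile range, and
proportions of time meeting angle, velocity and combined criteria (e.g.
arm inclination < 20 deg together with velocity < 5 deg/s, a resting-arm
indicator).  Percentiles use the linearly interpolated empirical quantile
(numpy's "linear" method) unless configured otherwise; threshold
inequalities are strict, matching the criterion labels.

``convert_threshold`` maps a threshold limit value between two velocity
conventions by equating within-subject percentile ranks: the rank of the
threshold in the source series (fractional, by linear interpolation) is
looked up in the target series.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematics import KinematicSeries

PERCENTILE_RANKS = (1, 5, 10, 25, 50, 75, 90, 99)

#: angle criteria (deg) per segment; labels mirror the exposure-table rows
ARM_ANGLE_CRITERIA = ("<20", ">30", ">45", ">60", ">90")
TRUNK_ANGLE_CRITERIA = ("-10to20", "<20", ">30", ">45", ">60", ">90")
VELOCITY_CRITERIA = ("<5", ">90")
ARM_COMBINED = (("<15", "<5"), ("<20", "<5"))
TRUNK_COMBINED = (("-10to20", "<5"), ("<15", "<5"), ("<20", "<5"))


def _angle_mask(angle: np.ndarray, label: str) -> np.ndarray:
    if label == "-10to20":
        return (angle > -10.0) & (angle < 20.0)
    op, value = label[0], float(label[1:])
    return angle < value if op == "<" else angle > value


def _vel_mask(vel: np.ndarray, label: str) -> np.ndarray:
    op, value = label[0], float(label[1:])
    return vel < value if op == "<" else vel > value


@dataclass
class ExposureSummary:
    """APDF-style summary of one subject x segment x method x velocity kind."""

    subject: str
    segment: str
    method: str
    velocity_kind: str
    angle_mean: float
    angle_percentiles: dict[int, float]
    angle_range_10_90: float
    velocity_mean: float
    velocity_percentiles: dict[int, float]
    velocity_range_10_90: float
    proportions: dict[str, float]       # label -> % of time
    flags: list[str] = field(default_factory=list)

    @property
    def tags(self) -> tuple[str, str, str]:
        return (self.segment, self.method, self.velocity_kind)

    def as_row(self) -> dict:
        row = {
            "subject": self.subject, "segment": self.segment,
            "method": self.method, "velocity_kind": self.velocity_kind,
            "angle_mean": self.angle_mean,
            "angle_range_10_90": self.angle_range_10_90,
            "velocity_mean": self.velocity_mean,
            "velocity_range_10_90": self.velocity_range_10_90,
        }
        row.update({f"angle_p{r}": v for r, v in self.angle_percentiles.items()})
        row.update({f"velocity_p{r}": v for r, v in self.velocity_percentiles.items()})
        row.update({f"prop_{k}": v for k, v in self.proportions.items()})
        return row


def summarize(
    series: KinematicSeries,
    subject: str = "s0",
    warmup_s: float = 2.0,
    ranks: Sequence[int] = PERCENTILE_RANKS,
    quantile_method: str = "linear",
) -> ExposureSummary:
    """Condense a kinematic series into its exposure summary.

    The filter warm-up (first ``warmup_s`` seconds) and any flagged-invalid
    samples are excluded before computing statistics.
    """
    keep = series.valid & (series.time >= series.time[0] + warmup_s)
    angle = series.angle_deg[keep]
    vel = series.velocity_dps[keep]
    if angle.size == 0:
        raise ValueError("series is empty after warm-up exclusion")

    flags: list[str] = []

    def pct(x):
        return {int(r): float(np.percentile(x, r, method=quantile_method))
                for r in ranks}

    a_pct, v_pct = pct(angle), pct(vel)
    props: dict[str, float] = {}
    angle_labels = (ARM_ANGLE_CRITERIA if series.segment == "arm"
                    else TRUNK_ANGLE_CRITERIA)
    for label in angle_labels:
        mask = _angle_mask(angle, label)
        props[f"angle{label}"] = 100.0 * mask.mean()
        if not mask.any():
            flags.append(f"empty:angle{label}")
    for label in VELOCITY_CRITERIA:
        props[f"vel{label}"] = 100.0 * _vel_mask(vel, label).mean()
    combined = ARM_COMBINED if series.segment == "arm" else TRUNK_COMBINED
    for a_label, v_label in combined:
        mask = _angle_mask(angle, a_label) & _vel_mask(vel, v_label)
        props[f"angle{a_label}&vel{v_label}"] = 100.0 * mask.mean()

    return ExposureSummary(
        subject=subject, segment=series.segment, method=series.method,
        velocity_kind=series.velocity_kind,
        angle_mean=float(angle.mean()), angle_percentiles=a_pct,
        angle_range_10_90=a_pct[90] - a_pct[10],
        velocity_mean=float(vel.mean()), velocity_percentiles=v_pct,
        velocity_range_10_90=v_pct[90] - v_pct[10],
        proportions=props, flags=flags,
    )


def convert_threshold(source, target, threshold: float,
                      quantile_method: str = "linear") -> float:
    """Percentile-matched threshold conversion between two velocity series.

    Finds the fractional percentile rank of ``threshold`` in ``source``
    (linear interpolation on the sorted sample) and returns that same rank's
    percentile of ``target``.  Both series must come from the same subject
    and recording for the matching to be meaningful.  Thresholds outside
    the observed source range are clamped to its extremes with a warning.
    """
    src = np.sort(_values(source))
    tgt = _values(target)
    if threshold < src[0] or threshold > src[-1]:
        warnings.warn("threshold outside the observed source range; "
                      "clamping to the empirical extremes", stacklevel=2)
    rank = float(np.interp(threshold, src, np.linspace(0.0, 100.0, src.size)))
    return float(np.percentile(tgt, rank, method=quantile_method))


def _values(x) -> np.ndarray:
    if isinstance(x, KinematicSeries):
        return x.velocity_dps[x.valid]
    return np.asarray(x, dtype=float)


def summaries_to_frame(summaries: Iterable[ExposureSummary]) -> pd.DataFrame:
    """Tidy table: one row per subject, one column per metric."""
    return pd.DataFrame([s.as_row() for s in summaries])


def group_aggregate(summaries: Sequence[ExposureSummary]) -> pd.DataFrame:
    """Group-level mean and SD of every summary field across subjects.

    All summaries must share the same segment/method/velocity-kind tags;
    the result has one row per metric with columns ``mean`` and ``sd``
    (sample SD, ddof=1).
    """
    if len(summaries) < 2:
        raise ValueError("group aggregation needs at least 2 subjects")
    tags = {s.tags for s in summaries}
    if len(tags) > 1:
        raise ValueError(f"mixed segment/method/velocity tags: {sorted(tags)}")
    frame = summaries_to_frame(summaries).drop(
        columns=["subject", "segment", "method", "velocity_kind"]
    )
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})
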