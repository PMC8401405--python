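"""Exposure summaries, threshold conversion and group aggregation."""
import numpy as np
import pytest

from ergokin import (KinematicSeries, convert_threshold, group_aggregate,
                     summaries_to_frame, summarize)


def make_series(angle, velocity, segment="arm", fs=25.0, subject=None):
    angle = np.asarray(angle, float)
    velocity = np.asarray(velocity, float)
    return KinematicSeries(np.arange(angle.size) / fs, angle, velocity,
                           segment, "acc", "inclination", fs)


class TestSummarize:
    def test_constant_angle(self):
        n = 2000
        s = summarize(make_series(np.full(n, 10.0), np.zeros(n)), warmup_s=2)
        assert all(np.isclose(v, 10.0) for v in s.angle_percentiles.values())
        assert s.proportions["angle<20"] == 100.0
        assert s.angle_range_10_90 == 0.0
        assert s.proportions["vel<5"] == 100.0

    def test_uniform_angles_analytic_quantiles(self):
        rng = np.random.default_rng(0)
        n = 100_000
        angles = rng.uniform(0.0, 100.0, n)
        s = summarize(make_series(angles, np.zeros(n)), warmup_s=0)
        assert abs(s.angle_percentiles[50] - 50.0) < 0.5
        assert abs(s.proportions["angle>45"] - 55.0) < 0.5

    def test_two_level_velocity(self):
        n = 1000
        vel = np.concatenate([np.zeros(n), np.full(n, 100.0)])
        rng = np.random.default_rng(1)
        rng.shuffle(vel)
        s = summarize(make_series(np.zeros(2 * n), vel), warmup_s=0)
        assert s.proportions["vel<5"] == 50.0
        assert s.proportions["vel>90"] == 50.0

    def test_duplication_invariance(self):
        rng = np.random.default_rng(2)
        angle = rng.uniform(0, 120, 4001)
        vel = rng.lognormal(3, 1, 4001)
        one = summarize(make_series(angle, vel), warmup_s=0)
        two = summarize(make_series(np.concatenate([angle, angle]),
                                    np.concatenate([vel, vel])), warmup_s=0)
        for r in one.angle_percentiles:
            assert np.isclose(one.angle_percentiles[r],
                              two.angle_percentiles[r], atol=0.1)
        for k in one.proportions:
            assert np.isclose(one.proportions[k], two.proportions[k], atol=1e-9)

    def test_percentiles_non_decreasing_and_props_bounded(self):
        rng = np.random.default_rng(3)
        s = summarize(make_series(rng.uniform(-20, 150, 5000),
                                  rng.lognormal(2.5, 1.2, 5000),
                                  segment="trunk"), warmup_s=0)
        ranks = sorted(s.angle_percentiles)
        assert all(s.angle_percentiles[a] <= s.angle_percentiles[b]
                   for a, b in zip(ranks, ranks[1:]))
        assert all(0.0 <= v <= 100.0 for v in s.proportions.values())

    def test_complementary_proportions_sum(self):
        rng = np.random.default_rng(4)
        angle = rng.uniform(0, 60, 3000)
        angle = angle[angle != 20.0]
        s = summarize(make_series(angle, np.zeros(angle.size)), warmup_s=0)
        above = 100.0 * np.mean(angle > 20.0)
        assert np.isclose(s.proportions["angle<20"] + above, 100.0)

    def test_warmup_excluded(self):
        n = 250
        angle = np.concatenate([np.full(50, 170.0), np.full(n - 50, 10.0)])
        s = summarize(make_series(angle, np.zeros(n)), warmup_s=2.0)
        assert s.angle_mean == 10.0

    def test_empty_after_warmup_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize(make_series(np.zeros(10), np.zeros(10)), warmup_s=5.0)

    def test_trunk_empty_criterion_flagged(self):
        n = 1000
        s = summarize(make_series(np.full(n, 5.0), np.zeros(n),
                                  segment="trunk"), warmup_s=0)
        assert s.proportions["angle>90"] == 0.0
        assert "empty:angle>90" in s.flags


class TestConvertThreshold:
    def test_identity_mapping(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(3.5, 0.8, 10_000)
        assert np.isclose(convert_threshold(v, v, 60.0), 60.0, atol=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(3.5, 0.8, 10_000)
        assert np.isclose(convert_threshold(v, v / 2.0, 60.0), 30.0, atol=1e-9)

    def test_against_brute_force_oracle(self):
        # sort-and-index oracle: position of the threshold in the sorted
        # source indexes the sorted target directly
        rng = np.random.default_rng(2)
        src = rng.lognormal(3.5, 0.8, 100_000)
        tgt = src ** 0.9
        result = convert_threshold(src, tgt, 60.0)
        s = np.sort(src)
        idx = np.searchsorted(s, 60.0)
        oracle = np.sort(tgt)[idx]
        assert abs(result - oracle) < 0.1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        src = rng.lognormal(3.0, 0.7, 5000)
        tgt = rng.lognormal(2.5, 0.6, 5000)
        out = [convert_threshold(src, tgt, th) for th in (10, 30, 60, 90)]
        assert np.all(np.diff(out) >= 0)

    def test_out_of_range_clamps_with_warning(self):
        v = np.linspace(1, 10, 100)
        with pytest.warns(UserWarning, match="clamping"):
            res = convert_threshold(v, v, 100.0)
        assert res == 10.0


class TestGroupAggregate:
    @staticmethod
    def _summary(subject, p50):
        n = 500
        rng = np.random.default_rng(hash(subject) % 2**31)
        return summarize(make_series(rng.uniform(0, 40, n),
                                     np.full(n, p50), subject=subject),
                         subject=subject, warmup_s=0)

    def test_two_subject_mean_and_sd(self):
        agg = group_aggregate([self._summary("a", 10.0),
                               self._summary("b", 20.0)])
        assert np.isclose(agg.loc["velocity_p50", "mean"], 15.0)
        assert np.isclose(agg.loc["velocity_p50", "sd"], np.sqrt(50.0))

    def test_identical_summaries_zero_sd(self):
        s = self._summary("a", 30.0)
        agg = group_aggregate([s, s, s])
        assert np.allclose(agg["sd"].to_numpy(), 0.0)

    def test_38_subject_spreadsheet_oracle(self):
        summaries = [self._summary(f"s{i}", 5.0 + i) for i in range(38)]
        agg = group_aggregate(summaries)
        frame = summaries_to_frame(summaries)
        for metric in ("velocity_p50", "angle_mean", "prop_vel<5"):
            col = frame[metric].to_numpy()
            assert np.isclose(agg.loc[metric, "mean"], col.mean(), atol=1e-12)
            assert np.isclose(agg.loc[metric, "sd"], col.std(ddof=1),
                              atol=1e-12)

    def test_mixed_tags_rejected(self):
        a = self._summary("a", 10.0)
        b = self._summary("b", 10.0)
        b.method = "acc_gyro"
        with pytest.raises(ValueError, match="mixed"):
            group_aggregate([a, b])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_aggregate([self._summary("a", 10.0)])
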