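"""Simulator physics: static cases, closed-form artifacts, reproducibility."""
import numpy as np
import pytest

from ergokin import (Bout, MotionScript, SensorNoiseModel, ZERO_NOISE,
                     simulate_recording, simulate_reference_postures)
from ergokin.synthetic import GRAVITY, _synthesize, cohort_scripts


def quiet_script(**kw):
    kw.setdefault("tremor_amplitude_deg", 0.0)
    return MotionScript(**kw)


class TestScriptValidation:
    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MotionScript(duration=10, bouts=[
                Bout("inclination_swing", 0, 6, amplitude=30),
                Bout("rest", 5, 8),
            ])

    def test_bout_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="within"):
            MotionScript(duration=5, bouts=[Bout("rest", 2, 8)])

    @pytest.mark.parametrize("amplitude", [-1.0, 181.0])
    def test_amplitude_bounds(self, amplitude):
        with pytest.raises(ValueError, match="amplitude"):
            Bout("inclination_swing", 0, 4, amplitude=amplitude)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            SensorNoiseModel(acc_white_sd=-0.1)


class TestStaticAndClosedForm:
    def test_rest_only_zero_noise(self):
        rec, truth = simulate_recording(
            quiet_script(duration=10, bouts=[], seed=0), ZERO_NOISE)
        assert np.allclose(np.linalg.norm(rec.acc, axis=1), 1.0, atol=1e-12)
        assert np.allclose(rec.gyro, 0.0)
        assert np.allclose(truth.inclination_deg, 0.0)

    def test_constant_rate_rotation_centripetal_magnitude(self):
        # constant-rate inclination sweep: the non-gravitational component
        # of the specific force has magnitude w^2 * r exactly
        fs, w, r = 100.0, 2.0, 0.3
        n = 500
        t = np.arange(n) / fs
        theta = w * t
        zeros = np.zeros(n)
        acc, gyro, truth = _synthesize(
            t, theta, np.full(n, w), zeros, zeros, zeros, zeros,
            sample_rate=fs, lever_arm=r, noise=ZERO_NOISE,
            rng=np.random.default_rng(0))
        nongrav = (acc - truth.gravity_body) * GRAVITY
        assert np.allclose(np.linalg.norm(nongrav, axis=1), w * w * r, atol=1e-9)

    def test_zero_noise_zero_lever_acc_equals_gravity(self):
        script = quiet_script(
            duration=20, lever_arm=0.0, seed=3,
            bouts=[Bout("combined", 0, 20, amplitude=60, period=2.5,
                        axial_rate=45)])
        rec, truth = simulate_recording(script, ZERO_NOISE)
        unit = rec.acc / np.linalg.norm(rec.acc, axis=1, keepdims=True)
        assert np.allclose(unit, truth.gravity_body, atol=1e-9)

    def test_axial_rotation_at_vertical_gives_zero_generalized(self):
        script = quiet_script(
            duration=10, seed=0,
            bouts=[Bout("axial_rotation", 0, 10, axial_rate=90)])
        _, truth = simulate_recording(script, ZERO_NOISE)
        assert np.allclose(truth.generalized_velocity_dps, 0.0, atol=1e-12)
        assert np.allclose(truth.gravity_body, [0, 0, 1], atol=1e-12)


class TestGroundTruthInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_generalized_dominates_inclination(self, seed):
        rng = np.random.default_rng(seed)
        script = MotionScript(
            duration=30, seed=seed,
            bouts=[Bout("combined", 0, 30,
                        amplitude=float(rng.uniform(10, 120)),
                        period=float(rng.uniform(1.5, 5)),
                        axial_rate=float(rng.uniform(-90, 90)))])
        _, truth = simulate_recording(script)
        assert np.all(truth.generalized_velocity_dps
                      >= truth.inclination_velocity_dps - 1e-9)

    def test_gravity_unit_norm(self):
        _, truth = simulate_recording(
            MotionScript(duration=20, seed=1, bouts=[
                Bout("inclination_swing", 0, 20, amplitude=100, period=3)]))
        assert np.allclose(np.linalg.norm(truth.gravity_body, axis=1), 1.0,
                           atol=1e-9)
        assert np.all((truth.inclination_deg >= 0)
                      & (truth.inclination_deg <= 180))


class TestReproducibilityAndErrors:
    def test_same_seed_bitwise_identical(self):
        script = MotionScript(duration=15, seed=42, bouts=[
            Bout("inclination_swing", 0, 12, amplitude=80, period=2)])
        rec1, _ = simulate_recording(script)
        rec2, _ = simulate_recording(script)
        assert np.array_equal(rec1.acc, rec2.acc)
        assert np.array_equal(rec1.gyro, rec2.gyro)

    def test_gyro_saturation_rejects_script(self):
        script = quiet_script(duration=8, seed=0, bouts=[
            Bout("inclination_swing", 0, 8, amplitude=180, period=0.5)])
        with pytest.raises(ValueError, match="gyroscope range"):
            simulate_recording(script, ZERO_NOISE)


class TestReferencePostures:
    def test_identity_mount_zero_noise_windows(self):
        rec = simulate_reference_postures("arm", ZERO_NOISE)
        windows = rec.meta["windows"]
        for label, (start, end) in windows.items():
            assert end - start >= 3.0
            m = (rec.time >= start) & (rec.time <= end)
            assert np.allclose(np.linalg.norm(rec.acc[m], axis=1), 1.0,
                               atol=1e-12)
        ref = (rec.time >= windows["arm_ref"][0]) & \
              (rec.time <= windows["arm_ref"][1])
        assert np.allclose(rec.acc[ref], [0, 0, 1], atol=1e-12)

    def test_arbitrary_mount_unit_norm(self):
        from scipy.spatial.transform import Rotation
        Q = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        rec = simulate_reference_postures("trunk", ZERO_NOISE, Q)
        for start, end in rec.meta["windows"].values():
            m = (rec.time >= start) & (rec.time <= end)
            assert np.allclose(np.linalg.norm(rec.acc[m], axis=1), 1.0,
                               atol=1e-12)

    def test_improper_misalignment_rejected(self):
        with pytest.raises(ValueError, match="proper rotation"):
            simulate_reference_postures("arm", ZERO_NOISE, -np.eye(3))


class TestCohortScripts:
    def test_cohort_structure_and_determinism(self):
        a = cohort_scripts(3, seed=5, duration=60.0)
        b = cohort_scripts(3, seed=5, duration=60.0)
        assert len(a) == 3
        assert [s.seed for s in a] == [s.seed for s in b]
        for script in a:
            assert script.bouts  # every subject moves
            assert all(x.end <= 60.0 for x in script.bouts)
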