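"""Cycle detection, feature extraction, gear classification, CL/CR."""

import numpy as np
import pandas as pd
import pytest

from skimass import cycles, pipeline, synthesize
from skimass.streams import SensorStream
from skimass.synthesize import _gear_bouts


def _sine_stream(freq=0.5, duration=60.0, rate=256.0, amp=2.0):
    t = np.arange(int(duration * rate)) / rate
    return SensorStream(
        "imu", rate, 0.0,
        {"acc_x": np.zeros_like(t), "acc_y": amp * np.sin(2 * np.pi * freq * t),
         "acc_z": np.zeros_like(t)},
    )


def _single_bout(gear="G3", duration=120, seed=0, noise=None):
    sched = pd.DataFrame(
        {"t": np.arange(duration), "phase": "ip", "lap": 1, "segment": "S1",
         "speed_kmh": 18.0, "incline_pct": 5.0, "gear": gear}
    )
    noise = noise or synthesize.NoiseConfig.zero()
    return synthesize.generate_imu(sched, noise, seed)


class TestDetectCycles:
    def test_pure_half_hz_sinusoid_gives_two_second_cycles(self):
        det = cycles.detect_cycles(_sine_stream())
        # 30 minima over 60 s (t = 1.5, 3.5, ..., 59.5) delimit 29 cycles
        assert len(det) == 29
        durs = np.array([b - a for a, b in det])
        assert np.allclose(durs, 2.0, atol=1 / 256)

    def test_constant_signal_yields_no_cycles(self):
        t = np.zeros(int(60 * 256))
        s = SensorStream("imu", 256, 0.0, {"acc_y": t})
        assert cycles.detect_cycles(s) == []

    def test_short_stream_yields_no_cycles(self):
        s = _sine_stream(duration=1.5)
        assert cycles.detect_cycles(s) == []

    def test_missing_channel_rejected(self):
        s = SensorStream("imu", 256, 0.0, {"acc_x": np.zeros(256 * 5)})
        with pytest.raises(KeyError):
            cycles.detect_cycles(s)

    def test_noiseless_bout_boundaries_within_one_sample(self):
        """Interior ground-truth boundaries are recovered to the sample."""
        imu, truth = _single_bout()
        det = cycles.detect_cycles(imu)
        starts = np.array([a for a, _ in det])
        interior = truth["t_start"].to_numpy()[1:-1]
        errs = [np.min(np.abs(starts - ts)) for ts in interior]
        assert max(errs) <= 1 / 256 + 1e-9

    def test_cycle_count_within_one_per_bout_at_default_noise(self, noisy_trial):
        _, streams, truth = noisy_trial
        det = cycles.detect_cycles(streams["imu"])
        mids = np.array([(a + b) / 2 for a, b in det])
        for b0, b1, gear in _gear_bouts(truth.schedule):
            n_true = ((truth.cycles["t_start"] >= b0) & (truth.cycles["t_end"] <= b1)).sum()
            n_det = ((mids >= b0) & (mids < b1)).sum()
            assert abs(int(n_det) - int(n_true)) <= 1


class TestFeatures:
    def test_vector_length_and_determinism(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(400, 3))
        f1 = cycles.extract_features(w, 256.0)
        f2 = cycles.extract_features(w.copy(), 256.0)
        assert f1.shape == (cycles.FEATURE_LENGTH,)
        assert np.array_equal(f1, f2)

    def test_amplitude_doubling_scales_variance_only(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(400, 3))
        f1 = cycles.extract_features(w, 256.0)
        f2 = cycles.extract_features(2 * w, 256.0)
        shape = slice(0, 3 * cycles.N_SHAPE_POINTS)
        assert np.allclose(f1[shape], f2[shape])
        assert np.allclose(f2[-3:], 4 * f1[-3:])
        assert f1[-4] == f2[-4]  # duration unchanged

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            cycles.extract_features(np.zeros((1, 3)), 256.0)


class TestGearModel:
    def _features_and_labels(self, seed):
        imu_parts = []
        for gear in ("G2", "G3", "G4"):
            imu, truth = _single_bout(gear, duration=80, seed=seed,
                                      noise=synthesize.NoiseConfig())
            det = cycles.detect_cycles(imu)
            feats = cycles.features_for_cycles(imu, det)
            labels = np.full(len(det), gear)
            imu_parts.append((feats, labels))
        X = np.vstack([f for f, _ in imu_parts])
        y = np.concatenate([l for _, l in imu_parts])
        return X, y

    def test_train_set_accuracy_at_least_99(self):
        X, y = self._features_and_labels(seed=3)
        model = cycles.train_gear_model(X, y)
        assert (cycles.classify(model, X) == y).mean() >= 0.99

    def test_held_out_seed_accuracy_at_least_95(self):
        X, y = self._features_and_labels(seed=3)
        model = cycles.train_gear_model(X, y)
        X2, y2 = self._features_and_labels(seed=4)
        assert (cycles.classify(model, X2) == y2).mean() >= 0.95

    def test_training_order_invariance(self):
        X, y = self._features_and_labels(seed=3)
        m1 = cycles.train_gear_model(X, y)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        m2 = cycles.train_gear_model(X[perm], y[perm])
        probe, _ = self._features_and_labels(seed=5)
        assert np.array_equal(cycles.classify(m1, probe), cycles.classify(m2, probe))

    def test_single_class_rejected(self):
        X = np.zeros((5, cycles.FEATURE_LENGTH))
        with pytest.raises(ValueError):
            cycles.train_gear_model(X, ["G3"] * 5)

    def test_wrong_feature_length_rejected(self):
        X, y = self._features_and_labels(seed=3)
        model = cycles.train_gear_model(X, y)
        with pytest.raises(ValueError):
            cycles.classify(model, np.zeros((2, 10)))

    def test_model_serialization_round_trip(self, tmp_path):
        X, y = self._features_and_labels(seed=3)
        model = cycles.train_gear_model(X, y)
        path = tmp_path / "gear_model.joblib"
        model.save(path)
        loaded = cycles.GearModel.load(path)
        assert np.array_equal(cycles.classify(loaded, X), cycles.classify(model, X))


class TestCycleKinematics:
    def test_definition(self):
        [(cl, cr)] = cycles.cycle_kinematics([(0.0, 2.0)], lambda t: 5.0)
        assert cl == pytest.approx(10.0)
        assert cr == pytest.approx(30.0)

    def test_halved_duration(self):
        [(cl1, cr1)] = cycles.cycle_kinematics([(0.0, 2.0)], lambda t: 5.0)
        [(cl2, cr2)] = cycles.cycle_kinematics([(0.0, 1.0)], lambda t: 5.0)
        assert cl2 == pytest.approx(cl1 / 2)
        assert cr2 == pytest.approx(2 * cr1)

    def test_product_identity_holds_exactly(self):
        rng = np.random.default_rng(2)
        bounds = []
        t = 0.0
        for _ in range(40):
            d = rng.uniform(1.2, 2.5)
            bounds.append((t, t + d))
            t += d
        speed = rng.uniform(3, 7, int(np.ceil(t)) + 1)
        out = cycles.cycle_kinematics(bounds, speed, speed_t0=0.0)
        for (t0, t1), (cl, cr) in zip(bounds, out):
            i0, i1 = int(np.floor(t0)), max(int(np.floor(t0)) + 1, int(np.ceil(t1)))
            v_mean = speed[i0:i1].mean()
            assert cl * cr == pytest.approx(60.0 * v_mean, rel=1e-12)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            cycles.cycle_kinematics([(1.0, 1.0)], lambda t: 5.0)


class TestBreakWindows:
    def test_break_seconds_classified_other(self, spec, noisy_trial):
        profile, streams, truth = noisy_trial
        res = pipeline.process_trial(
            spec, streams, truth, hrmax=profile.hrmax, vo2max=profile.vo2max
        )
        bt = profile.break_times[0]
        window = res.master[(res.master.t >= bt) & (res.master.t < bt + 30)]
        assert (window["gear"] == "Other").mean() >= 0.95
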