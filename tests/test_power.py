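"""Filtering, CoM, pole force geometry, power decomposition."""

import numpy as np
import pytest

from skimass import pipeline, power
from skimass.streams import SensorStream


class TestLowpass:
    def test_dc_unchanged(self):
        x = np.full(2000, 3.7)
        assert np.allclose(power.lowpass(x, 200.0), 3.7)

    def test_stopband_attenuation(self):
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = power.lowpass(x, 200.0)
        core = y[500:-500]
        assert np.abs(core).max() < 0.01  # >= 40 dB down

    def test_zero_phase_impulse_symmetry(self):
        x = np.zeros(1001)
        x[500] = 1.0
        y = power.lowpass(x, 200.0)
        assert np.allclose(y[400:500], y[600:500:-1], atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            power.lowpass(np.zeros(100), 20.0, cutoff=15.0)


class TestComputeCom:
    def _coincident(self, p):
        names = {n for seg in power.DE_LEVA_ADJUSTED_MALE for n in (seg[1], seg[2])}
        out = {}
        for n in names:
            if n.endswith("_mid"):
                base = n[:-4]
                out[f"{base}_l"] = np.tile(p, (10, 1))
                out[f"{base}_r"] = np.tile(p, (10, 1))
            else:
                out[n] = np.tile(p, (10, 1))
        return out

    def test_coincident_markers(self):
        p = np.array([1.0, 2.0, 3.0])
        com = power.compute_com(self._coincident(p), mass=80.0)
        assert np.allclose(com, p)

    def test_rigid_translation(self):
        markers = self._coincident(np.array([0.0, 0.0, 0.0]))
        com0 = power.compute_com(markers, 80.0)
        d = np.array([1.0, -2.0, 0.5])
        shifted = {k: v + d for k, v in markers.items()}
        assert np.allclose(power.compute_com(shifted, 80.0), com0 + d)

    def test_two_segment_toy_body(self):
        """Hand-computed weighted mean for a custom two-segment table."""
        table = (
            ("upper", "a", "b", 0.6, 0.5),
            ("lower", "b", "c", 0.4, 0.5),
        )
        markers = {
            "a": np.array([[0.0, 0, 0]]),
            "b": np.array([[1.0, 0, 0]]),
            "c": np.array([[2.0, 0, 0]]),
        }
        com = power.compute_com(markers, 70.0, segment_table=table)
        # segment CoMs at 0.5 and 1.5; weighted 0.6/0.4 -> 0.9
        assert com[0, 0] == pytest.approx(0.9)

    def test_missing_marker_named_in_error(self):
        with pytest.raises(KeyError, match="hip"):
            power.compute_com({"shoulder_l": np.zeros((5, 3)),
                               "shoulder_r": np.zeros((5, 3))}, 80.0)


class TestComVelocity:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / 200.0
        com = np.column_stack([3.0 * t, np.zeros_like(t), np.zeros_like(t)])
        v = power.com_velocity(com, 200.0)
        assert np.allclose(v[:, 0], 3.0)
        assert np.allclose(v[:, 1:], 0.0)

    def test_second_order_accuracy_on_sine(self):
        """Central-difference error shrinks ~4x when the rate doubles."""
        errs = []
        for rate in (100.0, 200.0):
            t = np.arange(int(rate)) / rate
            com = np.column_stack([np.sin(2 * np.pi * t)] * 3)
            v = power.com_velocity(com, rate)
            truth = 2 * np.pi * np.cos(2 * np.pi * t)
            errs.append(np.abs(v[5:-5, 0] - truth[5:-5]).max())
        assert errs[1] < errs[0] / 3.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            power.com_velocity(np.zeros((2, 3)), 200.0)


class TestPoleForceVector:
    def test_vertical_pole(self):
        handle = np.array([[0.0, 0, 1.5]])
        tip = np.array([[0.0, 0, 0.0]])
        f = power.pole_force_vector(np.array([100.0]), handle, tip)
        assert np.allclose(f, [[0, 0, -100.0]])

    def test_45_degree_pole(self):
        handle = np.array([[0.0, 0, 1.0]])
        tip = np.array([[1.0, 0, 0.0]])
        f = power.pole_force_vector(np.array([100.0]), handle, tip)
        assert np.allclose(f, [[70.71, 0, -70.71]], atol=0.01)

    def test_zero_force_any_orientation(self):
        handle = np.array([[0.2, 0.3, 1.4]])
        tip = np.array([[0.5, 0.1, 0.0]])
        f = power.pole_force_vector(np.array([0.0]), handle, tip)
        assert np.allclose(f, 0.0)

    def test_zero_length_pole_rejected(self):
        p = np.array([[1.0, 1.0, 1.0]])
        with pytest.raises(ValueError):
            power.pole_force_vector(np.array([10.0]), p, p)


class TestPolePower:
    def test_dot_product(self):
        f = np.array([[50.0, 0, 0]])
        v = np.array([[3.0, 0, 0]])
        assert power.pole_power(f, v)[0] == pytest.approx(150.0)

    def test_orthogonal_force_velocity(self):
        f = np.array([[0.0, 0, -100.0]])
        v = np.array([[3.0, 0, 0]])
        assert power.pole_power(f, v)[0] == 0.0

    def test_bilinearity_and_sign(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(50, 3))
        v = rng.normal(size=(50, 3))
        p = power.pole_power(f, v)
        assert np.allclose(power.pole_power(3 * f, v), 3 * p)
        assert np.allclose(power.pole_power(f, -v), -p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            power.pole_power(np.zeros((5, 3)), np.zeros((4, 3)))


class TestAlignStreams:
    def _force(self, onset_s, rate=100.0, duration=6.0):
        n = int(duration * rate)
        f = np.zeros(n)
        i0 = int(onset_s * rate)
        f[i0 : i0 + 40] = 200 * np.sin(np.pi * np.arange(40) / 40)
        return SensorStream("pole_force", rate, 0.0, {"force_l": f})

    def _tip_z(self, touchdown_s, rate=200.0, duration=6.0):
        t = np.arange(int(duration * rate)) / rate
        return 0.1 + 0.3 * np.abs(t - touchdown_s)

    def test_known_offset_recovered(self):
        force = self._force(1.30)
        tip_z = self._tip_z(1.42)
        offset, aligned = power.align_streams(force, tip_z, 200.0, 0.0)
        assert offset == pytest.approx(0.12, abs=0.02)
        assert aligned.rate == 200.0

    def test_already_aligned_offset_zero(self):
        force = self._force(2.0)
        tip_z = self._tip_z(2.0)
        offset, _ = power.align_streams(force, tip_z, 200.0, 0.0)
        assert offset == pytest.approx(0.0, abs=0.02)

    def test_all_zero_force_rejected(self):
        force = SensorStream("pole_force", 100.0, 0.0, {"force_l": np.zeros(600)})
        with pytest.raises(ValueError):
            power.align_streams(force, self._tip_z(1.0), 200.0, 0.0)


class TestDecomposeCycle:
    def test_percentages_sum_to_100(self):
        rate, t0 = 200.0, 0.0
        pl = np.full(400, 90.0)
        pr = np.full(400, 90.0)
        d = power.decompose_cycle(0.0, 2.0, pl, pr, rate, t0, p_cycle=300.0)
        assert d.pct_pole == pytest.approx(60.0)
        assert d.pct_pole + d.pct_ski == pytest.approx(100.0)
        assert d.pct_pole_left + d.pct_pole_right == pytest.approx(100.0)

    def test_zero_pole_power_means_all_ski(self):
        d = power.decompose_cycle(
            0.0, 2.0, np.zeros(400), np.zeros(400), 200.0, 0.0, p_cycle=300.0
        )
        assert d.pct_ski == pytest.approx(100.0)

    def test_nonpositive_work_rate_flagged(self):
        d = power.decompose_cycle(
            0.0, 2.0, np.full(400, 50.0), np.zeros(400), 200.0, 0.0, p_cycle=-5.0
        )
        assert d.flag
        assert np.isnan(d.pct_pole)


class TestFullPipelineRecovery:
    def test_noiseless_trial_recovers_truth(self, short_spec, clean_trial):
        """Trial-level pole fraction within 1 pp and left share within 2 pp."""
        profile, streams, truth = clean_trial
        res = pipeline.process_trial(
            short_spec, streams, truth,
            hrmax=profile.hrmax, vo2max=profile.vo2max, mass=profile.mass,
        )
        d = [x for x in res.decompositions if x is not None and not x.flag]
        assert len(d) > 100
        pct = np.array([x.pct_pole for x in d])
        left = np.array([x.pct_pole_left for x in d])
        assert pct.mean() == pytest.approx(100 * profile.pole_fraction, abs=1.0)
        assert left.mean() == pytest.approx(100 * profile.pole_left_share, abs=2.0)
        for x in d:
            assert x.pct_pole + x.pct_ski == pytest.approx(100.0, abs=1e-9)

    def test_missing_force_stream_propagates_missing(self, short_spec, clean_trial):
        profile, streams, truth = clean_trial
        reduced = {k: v for k, v in streams.items() if k != "pole_force"}
        res = pipeline.process_trial(
            short_spec, reduced, truth,
            hrmax=profile.hrmax, vo2max=profile.vo2max, mass=profile.mass,
        )
        assert res.decompositions is None
        assert res.master["pct_pole"].isna().all()
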