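"""Readout statistics against closed-form and constructed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import iv

from cardiopatch import analysis, synthetic
from cardiopatch.analysis import ActivationMap, BeatSeries


class TestDetectActivations:
    def test_sine_wave_counts_each_cycle(self):
        # 50 mV amplitude around -20 mV: crosses 0 upward once per cycle
        t = np.arange(0, 10_000.0, 1.0)
        v = -20.0 + 50.0 * np.sin(2 * np.pi * t / 1000.0)
        ev = analysis.detect_activations(t, v, refractory=100.0)
        assert len(ev) == 10

    def test_constant_trace_has_no_events(self):
        t = np.arange(0, 1000.0, 1.0)
        assert len(analysis.detect_activations(t, np.full_like(t, -70.0))) == 0

    def test_recovers_synthetic_event_times(self):
        spec = synthetic.GeneratorSpec(kind="ap_trace", seed=3, n_beats=6,
                                       cycle_length=800.0, apd=250.0)
        t, v, _ = synthetic.gen_ap_trace(spec, dt=0.5)
        ev = analysis.detect_activations(t, v, refractory=100.0)
        assert len(ev) == 6
        # upstrokes start 10 ms into each cycle; 0 mV crossed mid-upstroke
        expected = np.arange(6) * 800.0 + 10.0
        assert np.all(np.abs(ev - expected) < 2.5)

    def test_refractory_suppresses_double_counts(self):
        t = np.arange(0, 300.0, 1.0)
        v = np.full_like(t, -70.0)
        v[50:52] = 10.0
        v[60:62] = 10.0   # second spike inside the refractory window
        ev = analysis.detect_activations(t, v, refractory=50.0)
        assert len(ev) == 1

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="uniform"):
            analysis.detect_activations(t, np.zeros(4))

    def test_matrix_detection_matches_single_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 5000.0, 2.0)
        frames = np.stack([
            -20.0 + 50.0 * np.sin(2 * np.pi * (t - ph) / 900.0)
            for ph in rng.uniform(0, 900, size=6)
        ], axis=1)
        amap = analysis.detect_activations_matrix(frames, t, (2, 3), refractory=100.0)
        for i in range(6):
            single = analysis.detect_activations(t, frames[:, i], refractory=100.0)
            np.testing.assert_allclose(amap.events[i], single, atol=1e-9)


class TestBeatIrregularity:
    def test_periodic_series_is_zero(self):
        res = analysis.beat_irregularity(BeatSeries(np.arange(10) * 777.0 + 5))
        assert res.irregularity == 0.0

    def test_hand_computed_rates_60_70_80(self):
        # rates {60, 70, 80} / min -> sample SD 10, mean 70 -> 14.2857 %
        ivals = 60_000.0 / np.array([60.0, 70.0, 80.0])
        events = np.concatenate([[0.0], np.cumsum(ivals)])
        res = analysis.beat_irregularity(BeatSeries(events))
        assert res.irregularity == pytest.approx(10.0 / 70.0 * 100.0, rel=1e-12)
        assert res.mean_rate == pytest.approx(70.0)

    def test_generator_cv_recovered(self):
        spec = synthetic.GeneratorSpec(kind="beat_series", seed=11, n=200,
                                       mean_rate=60.0, rate_cv=25.0)
        res = analysis.beat_irregularity(synthetic.gen_beat_series(spec))
        assert 20.0 <= res.irregularity <= 30.0

    def test_insufficient_beats_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            analysis.beat_irregularity(BeatSeries(np.array([0.0, 500.0])))

    @settings(max_examples=30, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 2**20),
    )
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        ivals = rng.gamma(20.0, 50.0, size=12) + 1.0
        ev = np.cumsum(ivals)
        r1 = analysis.beat_irregularity(BeatSeries(ev))
        r2 = analysis.beat_irregularity(BeatSeries(ev * scale))
        assert r1.irregularity == pytest.approx(r2.irregularity, rel=1e-9)


class TestTissueIrregularity:
    def _map(self, events_list, shape):
        return ActivationMap(shape=shape, events=events_list)

    def test_identical_periodic_elements_zero(self):
        ev = np.arange(8) * 900.0 + 10
        amap = self._map([ev.copy() for _ in range(4)], (2, 2))
        assert analysis.tissue_irregularity(amap).irregularity == 0.0

    def test_median_between_two_groups(self):
        half1, half2 = [], []
        for seed in range(8):
            s0 = synthetic.GeneratorSpec(kind="beat_series", seed=seed, n=40,
                                         mean_rate=60, rate_cv=0.0)
            s20 = synthetic.GeneratorSpec(kind="beat_series", seed=seed + 100, n=40,
                                          mean_rate=60, rate_cv=20.0)
            half1.append(synthetic.gen_beat_series(s0).events)
            half2.append(synthetic.gen_beat_series(s20).events)
        amap = self._map(half1 + half2, (4, 4))
        res = analysis.tissue_irregularity(amap, aggregation="median")
        per = [analysis.beat_irregularity(BeatSeries(e)).irregularity
               for e in half1 + half2]
        lo = np.median([p for p in per[:8]])
        hi = np.median([p for p in per[8:]])
        assert lo < res.irregularity < hi

    def test_single_element_equals_beat_irregularity(self):
        ev = synthetic.gen_beat_series(
            synthetic.GeneratorSpec(kind="beat_series", seed=5, n=30,
                                    mean_rate=50, rate_cv=10.0)
        ).events
        amap = self._map([ev], (1, 1))
        res = analysis.tissue_irregularity(amap)
        assert res.irregularity == pytest.approx(
            analysis.beat_irregularity(BeatSeries(ev)).irregularity
        )

    def test_all_excluded_raises(self):
        amap = self._map([np.array([1.0, 2.0])] * 4, (2, 2))
        with pytest.raises(ValueError, match="excluded"):
            analysis.tissue_irregularity(amap)


class TestConductionField:
    def test_planar_wave_closed_form(self):
        spec = synthetic.GeneratorSpec(kind="activation_map", seed=0, nx=20,
                                       ny=20, wave_speed=45.0, n_beats=2)
        amap = synthetic.gen_activation_map(spec)
        field = analysis.conduction_field(amap, 0, spec.dx)
        interior = field.valid[1:-1, 1:-1]
        assert interior.all()
        np.testing.assert_allclose(field.speed[1:-1, 1:-1], 45.0, rtol=1e-6)
        np.testing.assert_allclose(field.ux[1:-1, 1:-1], 1.0, atol=1e-9)
        np.testing.assert_allclose(field.uy[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_focal_wave_radial_directions_and_speed(self):
        spec = synthetic.GeneratorSpec(kind="activation_map", seed=0, nx=31,
                                       ny=31, wave_speed=50.0,
                                       geometry="focal", n_beats=1)
        amap = synthetic.gen_activation_map(spec)
        field = analysis.conduction_field(amap, 0, spec.dx)
        cx = cy = 15
        yy, xx = np.mgrid[0:31, 0:31]
        r = np.hypot(xx - cx, yy - cy)
        far = (r > 5) & (xx > 1) & (xx < 29) & (yy > 1) & (yy < 29)
        assert np.all(np.abs(field.speed[far] - 50.0) / 50.0 < 0.05)
        # unit vectors point away from the source
        rx = (xx - cx)[far] / r[far]
        ry = (yy - cy)[far] / r[far]
        dot = rx * field.ux[far] + ry * field.uy[far]
        assert dot.min() > 0.99

    def test_simultaneous_activation_all_invalid(self):
        ev = [np.array([100.0]) for _ in range(25)]
        amap = ActivationMap(shape=(5, 5), events=ev)
        field = analysis.conduction_field(amap, 0, 0.025)
        assert not field.valid.any()


class TestHeterogeneityIndex:
    def _field(self, angles):
        ang = np.asarray(angles, dtype=float)
        n = ang.size
        return analysis.ConductionField(
            vx=np.cos(ang), vy=np.sin(ang), speed=np.ones(n),
            ux=np.cos(ang), uy=np.sin(ang), valid=np.ones(n, dtype=bool),
        )

    def test_identical_vectors_zero(self):
        assert analysis.heterogeneity_index(self._field([0.7] * 50)) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_quadruple_is_one(self):
        f = self._field([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert analysis.heterogeneity_index(f) == pytest.approx(1.0, abs=1e-12)

    def test_von_mises_closed_form(self):
        kappa = 4.0
        spec = synthetic.GeneratorSpec(kind="vector_field", seed=42, n=1000,
                                       kappa=kappa)
        f = synthetic.gen_vector_field(spec)
        expected = 1.0 - iv(1, kappa) / iv(0, kappa)
        assert analysis.heterogeneity_index(f) == pytest.approx(expected, abs=0.02)

    @settings(max_examples=25, deadline=None)
    @given(rot=st.floats(-np.pi, np.pi), seed=st.integers(0, 2**20))
    def test_rotation_invariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        ang = rng.uniform(-np.pi, np.pi, size=40)
        h1 = analysis.heterogeneity_index(self._field(ang))
        h2 = analysis.heterogeneity_index(self._field(ang + rot))
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_planar_wave_composition_is_zero(self):
        spec = synthetic.GeneratorSpec(kind="activation_map", seed=0, nx=15,
                                       ny=15, n_beats=1)
        amap = synthetic.gen_activation_map(spec)
        field = analysis.conduction_field(amap, 0, spec.dx)
        assert analysis.heterogeneity_index(field) < 1e-9

    def test_too_few_vectors_raises(self):
        f = self._field([0.0])
        with pytest.raises(ValueError):
            analysis.heterogeneity_index(f)


class TestAPMetrics:
    def test_identical_aps_zero_variance(self):
        spec = synthetic.GeneratorSpec(kind="ap_trace", seed=0, n_beats=6,
                                       apd=300.0, cycle_length=1000.0)
        t, v, _ = synthetic.gen_ap_trace(spec, dt=0.5)
        m = analysis.ap_metrics(t, v)
        assert m.apd90_variance == pytest.approx(0.0, abs=0.5)
        assert m.auc90_variance == pytest.approx(0.0, abs=0.5)

    def test_alternans_apds_recovered(self):
        spec = synthetic.GeneratorSpec(kind="ap_trace", seed=0, n_beats=8,
                                       apd=250.0, cycle_length=1000.0,
                                       alternans_ratio=1.3)
        t, v, true_apds = synthetic.gen_ap_trace(spec, dt=0.25)
        m = analysis.ap_metrics(t, v)
        ratio = m.apd90[1::2].mean() / m.apd90[0::2].mean()
        assert ratio == pytest.approx(1.3, rel=0.02)

    def test_amplitude_recovered(self):
        spec = synthetic.GeneratorSpec(kind="ap_trace", seed=0, n_beats=4,
                                       amplitude=100.0)
        t, v, _ = synthetic.gen_ap_trace(spec, dt=0.25)
        m = analysis.ap_metrics(t, v)
        np.testing.assert_allclose(m.amplitude, 100.0, atol=1.0)

    def test_triangular_pulse_closed_form(self):
        # rise 20 ms, fall 180 ms, amplitude 100 mV from -80 mV baseline
        dt = 0.1
        rise, fall, amp, base = 20.0, 180.0, 100.0, -80.0
        t = np.arange(0, 2500.0, dt)
        v = np.full_like(t, base)
        for t0 in (100.0, 1100.0):
            up = (t >= t0) & (t < t0 + rise)
            dn = (t >= t0 + rise) & (t <= t0 + rise + fall)
            v[up] = base + amp * (t[up] - t0) / rise
            v[dn] = base + amp * (1 - (t[dn] - t0 - rise) / fall)
        m = analysis.ap_metrics(t, v)
        # APD90: rise (past max-dV/dt point) + 90 % of the fall
        assert np.all(np.abs(m.apd90 - (rise + 0.9 * fall)) < 1.0)
        # AUC90: two similar triangles above the V90 level
        expected = 0.5 * (0.9 * amp) * (0.9 * rise) + 0.5 * (0.9 * amp) * (0.9 * fall)
        np.testing.assert_allclose(m.auc90, expected, rtol=0.02)

    def test_unrepolarized_final_ap_dropped(self):
        spec = synthetic.GeneratorSpec(kind="ap_trace", seed=0, n_beats=4,
                                       apd=300.0, cycle_length=1000.0)
        t, v, _ = synthetic.gen_ap_trace(spec, dt=0.5)
        cut = int(3 * 1000 / 0.5) + int(100 / 0.5)   # truncate mid-plateau
        with pytest.warns(UserWarning, match="repolarize"):
            m = analysis.ap_metrics(t[:cut], v[:cut])
        assert len(m.apd90) == 3


class TestSustainedActivity:
    def _periodic_map(self, n_elements, t_end, extra=None):
        ev = [np.arange(100.0, 3000.0, 700.0) for _ in range(n_elements)]
        if extra is not None:
            for i in extra:
                ev[i] = np.concatenate([ev[i], np.arange(3200.0, 5200.0, 150.0)])
        return ActivationMap(shape=(1, n_elements), events=ev)

    def test_captured_control_not_sustained(self):
        amap = self._periodic_map(16, 5200.0)
        sustained, counts = analysis.detect_sustained_activity(
            amap, last_stimulus=2900.0, window=2000.0, sim_end=5200.0)
        assert not sustained
        assert counts.max() == 0

    def test_reentrant_reactivation_sustained(self):
        amap = self._periodic_map(16, 5200.0, extra=range(8))
        sustained, counts = analysis.detect_sustained_activity(
            amap, last_stimulus=2900.0, window=2000.0, sim_end=5200.0)
        assert sustained
        assert counts.max() >= 2

    def test_zero_window_rejected(self):
        amap = self._periodic_map(4, 3000.0)
        with pytest.raises(ValueError):
            analysis.detect_sustained_activity(amap, 2900.0, window=0.0)

    def test_short_simulation_rejected(self):
        amap = self._periodic_map(4, 3000.0)
        with pytest.raises(ValueError, match="before"):
            analysis.detect_sustained_activity(
                amap, 2900.0, window=2000.0, sim_end=3000.0)
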