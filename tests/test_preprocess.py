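import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pursuitlab.design import StimulusGeometry, TrialCondition, VisualCondition
from pursuitlab.preprocess import (
    EyeTrace,
    QCResult,
    SaccadeEvent,
    SaccadeTrigger,
    average_traces,
    desaccade,
    design_fir,
    detect_blinks,
    detect_saccades,
    differentiate_central,
    fir_lowpass,
    qc_trial,
)


# ---------------------------------------------------------------- helpers


def make_trace(x, t0=-500.0, valid=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(t0, t0 + len(x))
    if valid is None:
        valid = np.isfinite(x)
    return EyeTrace(t=t, x=x, y=np.zeros_like(x), valid=valid)


def oracle_saccade_spans(t, v, a, v_thr, a_thr, merge_gap_ms):
    """Sample-by-sample threshold oracle (independent scan-and-merge)."""
    flags = []
    for vi, ai in zip(v, a):
        hit_v = np.isfinite(vi) and abs(vi) >= v_thr
        hit_a = np.isfinite(ai) and abs(ai) >= a_thr
        flags.append(hit_v or hit_a)
    spans = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            spans.append([i, j])
            i = j + 1
        else:
            i += 1
    dt = t[1] - t[0]
    merged = []
    for s in spans:
        gap_samples = s[0] - merged[-1][1] - 1 if merged else None
        if merged and gap_samples * dt < merge_gap_ms:
            merged[-1][1] = s[1]
        else:
            merged.append(s)
    return [(t[i], t[j] + dt) for i, j in merged]


# ---------------------------------------------------------------- differentiation


class TestDifferentiate:
    def test_linear_ramp(self):
        t_s = np.arange(100) / 1000.0
        v = differentiate_central(3.0 * t_s, dt_ms=1.0)
        assert np.allclose(v[1:-1], 3.0)

    def test_constant(self):
        v = differentiate_central(np.full(50, 2.5), dt_ms=1.0)
        assert np.allclose(v, 0.0)

    def test_sine_matches_analytic(self):
        t_s = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 2.0 * t_s)
        v = differentiate_central(x, dt_ms=1.0)
        expected = 4 * np.pi * np.cos(2 * np.pi * 2.0 * t_s)
        err = np.abs(v[1:-1] - expected[1:-1])
        assert np.max(err) < 1e-3 * np.max(np.abs(expected))

    def test_nan_propagates(self):
        x = np.arange(10.0)
        x[4] = np.nan
        v = differentiate_central(x, dt_ms=1.0)
        assert np.isnan(v[3]) and np.isnan(v[5])

    def test_too_short(self):
        with pytest.raises(ValueError):
            differentiate_central(np.array([1.0, 2.0]))


# ---------------------------------------------------------------- FIR filter


class TestFirLowpass:
    def test_dc_gain_unity(self):
        x = np.full(1000, 7.3)
        y = fir_lowpass(x)
        assert np.allclose(y, 7.3, atol=1e-9)

    def test_taps_sum_to_one(self):
        assert np.sum(design_fir()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "freq_hz, check",
        [(10.0, lambda g: g > 0.95), (100.0, lambda g: g < 0.10)],
    )
    def test_frequency_response(self, freq_hz, check):
        t_s = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * freq_hz * t_s)
        y = fir_lowpass(x)
        core = slice(500, 3500)
        gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert check(gain)

    def test_impulse_support_80_single_pass(self):
        x = np.zeros(1001)
        x[500] = 1.0
        y = fir_lowpass(x, zero_phase=False)
        assert np.count_nonzero(np.abs(y) > 1e-12) == 80

    def test_nan_spans_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=600)
        x[200:300] = np.nan
        y = fir_lowpass(x)
        assert np.all(np.isnan(y[200:300]))
        assert np.all(np.isfinite(y[:200])) and np.all(np.isfinite(y[300:]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fir_lowpass(np.zeros(80))


# ---------------------------------------------------------------- saccade detection


class TestDetectSaccades:
    def test_constant_pursuit_below_threshold(self):
        t = np.arange(500.0)
        v = np.full(500, 20.0)
        a = np.zeros(500)
        assert detect_saccades(t, v, a) == []

    def test_single_pulse(self):
        t = np.arange(500.0)
        v = np.full(500, 3.0)
        v[200:230] = 40.0
        a = np.zeros(500)
        events = detect_saccades(t, v, a)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_ms == 200.0 and ev.offset_ms == 230.0
        assert ev.trigger is SaccadeTrigger.VELOCITY
        assert ev.peak_velocity == pytest.approx(40.0)

    def test_acceleration_only_trigger(self):
        t = np.arange(500.0)
        v = np.full(500, 25.0)  # below velocity threshold
        a = np.zeros(500)
        a[100:110] = 1500.0
        events = detect_saccades(t, v, a)
        assert len(events) == 1
        assert events[0].trigger is SaccadeTrigger.ACCELERATION

    def test_or_criterion_both(self):
        t = np.arange(300.0)
        v = np.zeros(300)
        a = np.zeros(300)
        v[50:70] = 35.0
        a[50:70] = 2000.0
        assert detect_saccades(t, v, a)[0].trigger is SaccadeTrigger.BOTH

    def test_nearby_runs_merged(self):
        t = np.arange(500.0)
        v = np.zeros(500)
        v[100:110] = 40.0
        v[120:130] = 40.0  # 10-ms gap < 20-ms merge gap
        events = detect_saccades(t, v, np.zeros(500))
        assert len(events) == 1
        assert events[0].onset_ms == 100.0 and events[0].offset_ms == 130.0

    def test_distant_runs_kept_separate(self):
        t = np.arange(500.0)
        v = np.zeros(500)
        v[100:110] = 40.0
        v[200:210] = 40.0
        assert len(detect_saccades(t, v, np.zeros(500))) == 2

    def test_matches_threshold_oracle_on_random_traces(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = 400
            t = np.arange(float(n))
            v = rng.normal(0, 10, n)
            a = rng.normal(0, 300, n)
            for _ in range(rng.integers(0, 4)):
                i = rng.integers(0, n - 30)
                v[i : i + 15] += rng.choice([-1, 1]) * rng.uniform(30, 120)
            events = detect_saccades(t, v, a)
            expected = oracle_saccade_spans(t, v, a, 30.0, 1000.0, 20.0)
            assert [(e.onset_ms, e.offset_ms) for e in events] == expected

    def test_landing_position_recorded(self):
        t = np.arange(300.0)
        v = np.zeros(300)
        v[50:80] = 50.0
        x = np.linspace(-3, -1, 300)
        ev = detect_saccades(t, v, np.zeros(300), position=x)[0]
        assert ev.landing_position == pytest.approx(x[79])


# ---------------------------------------------------------------- desaccading


class TestDesaccade:
    def test_no_events_identity(self):
        t = np.arange(100.0)
        v = np.sin(t)
        out = desaccade(t, v, [])
        assert np.array_equal(out, v)

    def test_padded_span(self):
        t = np.arange(500.0)
        v = np.ones(500)
        ev = SaccadeEvent(200.0, 230.0, SaccadeTrigger.VELOCITY, 50.0, 0.0)
        out = desaccade(t, v, [ev], pad_ms=10.0)
        assert np.all(np.isnan(out[(t >= 190) & (t <= 240)]))
        assert np.all(np.isfinite(out[t < 190])) and np.all(np.isfinite(out[t > 240]))

    @given(
        spans=hst.lists(
            hst.tuples(
                hst.integers(min_value=0, max_value=460),
                hst.integers(min_value=1, max_value=39),
            ),
            min_size=0,
            max_size=6,
        ),
        pad=hst.integers(min_value=0, max_value=15),
    )
    @settings(max_examples=60, deadline=None)
    def test_nan_set_equals_padded_interval_union(self, spans, pad):
        t = np.arange(500.0)
        v = np.ones(500)
        events = [
            SaccadeEvent(float(s), float(s + d), SaccadeTrigger.VELOCITY, 50.0, 0.0)
            for s, d in spans
        ]
        out = desaccade(t, v, events, pad_ms=float(pad))
        expected = np.zeros(500, dtype=bool)
        for s, d in spans:
            expected |= (t >= s - pad) & (t <= s + d + pad)
        assert np.array_equal(np.isnan(out), expected)


# ---------------------------------------------------------------- blinks


class TestDetectBlinks:
    def test_fully_valid(self):
        trace = make_trace(np.zeros(500))
        assert detect_blinks(trace) == []

    def test_single_invalid_span_contained(self):
        x = np.zeros(1000)
        x[300:450] = np.nan
        trace = make_trace(x)
        spans = detect_blinks(trace, guard_ms=20.0)
        assert len(spans) == 1
        lo, hi = spans[0]
        assert lo <= trace.t[300] and hi >= trace.t[449]

    def test_separate_spans(self):
        x = np.zeros(1000)
        x[100:150] = np.nan
        x[500:560] = np.nan
        trace = make_trace(x)
        assert len(detect_blinks(trace, guard_ms=20.0)) == 2

    def test_close_spans_merged_by_guard(self):
        x = np.zeros(1000)
        x[100:150] = np.nan
        x[170:200] = np.nan  # 20-ms gap, guards touch
        trace = make_trace(x)
        assert len(detect_blinks(trace, guard_ms=20.0)) == 1


# ---------------------------------------------------------------- QC


class TestQC:
    def fixation_cond(self):
        return TrialCondition(VisualCondition.FIXATION, 3.0)

    def pursuit_cond(self):
        return TrialCondition(VisualCondition.PURSUIT_FIRST_ORDER, 3.0)

    def test_fixation_excursion_excluded(self, geometry):
        x = np.full(1200, -3.0)
        x[700:800] = 0.5  # 3.5 deg from the gazed object, inside presentation
        trace = make_trace(x, t0=-500.0)
        res = qc_trial(trace, [], [], self.fixation_cond(), geometry)
        assert not res.keep and res.reasons == {"fixation_excursion"}

    def test_fixation_small_excursion_kept(self, geometry):
        x = np.full(1200, -3.0)
        x[700:800] = -1.5  # 1.5 deg < 2 deg limit
        trace = make_trace(x, t0=-500.0)
        assert qc_trial(trace, [], [], self.fixation_cond(), geometry).keep

    def test_saccade_to_target_excluded(self, geometry):
        x = np.full(1200, -3.0)
        x[600:] = 2.7  # lands 0.3 deg from the stationary object at +3
        trace = make_trace(x, t0=-500.0)
        ev = SaccadeEvent(90.0, 130.0, SaccadeTrigger.VELOCITY, 200.0, 2.7)
        res = qc_trial(trace, [ev], [], self.pursuit_cond(), geometry)
        assert not res.keep and res.reasons == {"saccade_to_target"}

    def test_catchup_saccade_kept(self, geometry):
        x = np.full(1200, -3.0)
        trace = make_trace(x, t0=-500.0)
        ev = SaccadeEvent(200.0, 230.0, SaccadeTrigger.VELOCITY, 60.0, -2.0)
        assert qc_trial(trace, [ev], [], self.pursuit_cond(), geometry).keep

    def test_blink_in_presentation_excluded(self, geometry):
        trace = make_trace(np.full(1200, -3.0), t0=-500.0)
        res = qc_trial(trace, [], [(100.0, 250.0)], self.pursuit_cond(), geometry)
        assert not res.keep and res.reasons == {"blink"}

    def test_blink_outside_presentation_kept(self, geometry):
        trace = make_trace(np.full(1200, -3.0), t0=-500.0)
        assert qc_trial(trace, [], [(-400.0, -200.0)], self.fixation_cond(), geometry).keep

    def test_clean_trial_kept(self, geometry):
        trace = make_trace(np.full(1200, -3.0), t0=-500.0)
        res = qc_trial(trace, [], [], self.fixation_cond(), geometry)
        assert res.keep and res.reasons == frozenset()

    def test_qcresult_consistency_enforced(self):
        with pytest.raises(ValueError):
            QCResult(keep=True, reasons=frozenset({"blink"}))


# ---------------------------------------------------------------- averaging


class TestAverageTraces:
    def test_nan_sample_uses_other_trace(self):
        a = np.array([1.0, 2.0, np.nan, 4.0])
        b = np.array([3.0, 2.0, 6.0, 4.0])
        mean, _, count = average_traces([a, b])
        assert mean[2] == pytest.approx(6.0)
        assert count[2] == 1

    def test_identical_traces_zero_sd(self):
        a = np.arange(10.0)
        _, sd, _ = average_traces([a, a.copy(), a.copy()])
        assert np.allclose(sd, 0.0)

    def test_all_nan_sample(self):
        a = np.array([1.0, np.nan])
        b = np.array([2.0, np.nan])
        mean, _, count = average_traces([a, b])
        assert np.isnan(mean[1]) and count[1] == 0

    def test_min_count_masks(self):
        a = np.array([1.0, np.nan, 3.0])
        b = np.array([2.0, 5.0, 4.0])
        mean, _, _ = average_traces([a, b], min_count=2)
        assert np.isnan(mean[1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_traces([])


def test_eyetrace_validation():
    with pytest.raises(ValueError):
        EyeTrace(
            t=np.array([0.0, 1.0, 3.0]),
            x=np.zeros(3),
            y=np.zeros(3),
            valid=np.ones(3, dtype=bool),
        )
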