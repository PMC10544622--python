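"""Peak gate, cutoff removal and per-patient normalization contracts."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mepkit
from mepkit.preprocess import (
    Peak,
    PreselectedTrace,
    Rejection,
    detect_peaks,
    normalize_patient,
    preselect_cohort,
    preselect_trace,
)
from mepkit.synthetic import MuscleClass, RawTrace
from conftest import brute_force_peaks


def _raw(samples, pid=1, tid="t", muscle=MuscleClass.EXT):
    return RawTrace(samples=np.asarray(samples, float), muscle=muscle,
                    patient_id=pid, trace_id=tid)


def _smooth_noise(rng, sigma, n=2000, k=15):
    w = np.convolve(rng.normal(0, 1, n + 200), np.ones(k) / k, mode="same")[:n]
    return w * (sigma / w.std())


def _triangle(x, center, half_width, height):
    for k in range(-half_width, half_width + 1):
        x[center + k] += height * (1 - abs(k) / (half_width + 1))
    return x


class TestDetectPeaks:
    def test_constant_traces_have_no_peaks(self):
        assert detect_peaks(_raw(np.zeros(2000))) == []
        assert detect_peaks(_raw(np.full(2000, 3.3))) == []

    def test_single_pulse_on_noise_is_one_peak_at_25ms(self):
        # band-limited baseline noise, as produced by a real recording chain
        x = _smooth_noise(np.random.default_rng(42), sigma=0.1)
        x = _triangle(x, 500, 120, 1.0)  # 10-sigma pulse at 25 ms
        peaks = detect_peaks(_raw(x))
        assert len(peaks) == 1
        assert peaks[0].time_ms == pytest.approx(25.0, abs=1.0)
        # detection agrees with the brute-force prominence oracle
        rect = np.abs(x)
        thresh = 2.0 * np.std(rect[350:])
        oracle = brute_force_peaks(x, 350, thresh)
        assert [(p.index, pytest.approx(p.prominence)) for p in peaks] == \
            [(i, pytest.approx(pr)) for i, pr in oracle]

    def test_pulse_before_cutoff_is_ignored(self):
        x = np.zeros(2000)
        x = _triangle(x, 200, 8, 5.0)  # 10 ms, before the 17.5 ms cutoff
        # a monotone post-cutoff ramp keeps the SD positive without creating
        # any local maximum
        x[350:] = np.linspace(0.0, 1e-6, 1650)
        assert detect_peaks(_raw(x)) == []

    def test_negative_pulses_count_via_rectification(self):
        x = _smooth_noise(np.random.default_rng(1), sigma=0.05)
        x = _triangle(x, 700, 120, -1.0)
        peaks = detect_peaks(_raw(x))
        assert len(peaks) == 1
        assert peaks[0].index == pytest.approx(700, abs=20)

    def test_peak_times_follow_index_over_rate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.02, 2000)
        x = _triangle(x, 800, 5, 1.0)
        (p,) = detect_peaks(_raw(x))
        assert p.time_ms == p.index / 20.0
        assert p.time_ms >= 17.5
        assert p.prominence > 0


class TestGateEquivalence:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False, width=32),
                    min_size=8, max_size=64),
           st.integers(0, 6))
    def test_gate_matches_brute_force_on_short_traces(self, values, cut):
        x = np.asarray(values, float)
        fs = 20000.0
        cutoff_ms = cut / fs * 1000.0
        rect = np.abs(x)
        sd = float(np.std(rect[cut:]))
        impl = detect_peaks(x, cutoff_ms=cutoff_ms, sampling_rate=fs)
        if sd == 0.0:
            assert impl == []
            return
        oracle = brute_force_peaks(x, cut, 2.0 * sd)
        assert [(p.index, p.prominence) for p in impl] == pytest.approx(oracle)

    def test_subthreshold_bump_never_changes_acceptance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.01, 2000)
        x = _triangle(x, 600, 10, 1.0)
        base = preselect_trace(_raw(x))
        assert isinstance(base, PreselectedTrace)
        thresh = 2.0 * np.std(np.abs(x)[350:])
        y = x.copy()
        y = _triangle(y, 1200, 3, 0.2 * thresh)  # well below prominence bar
        bumped = preselect_trace(_raw(y))
        assert isinstance(bumped, PreselectedTrace)
        assert len(bumped.peaks) == len(base.peaks)


class TestPreselectTrace:
    def test_zero_peaks_is_rejected(self):
        res = preselect_trace(_raw(np.zeros(2000)))
        assert isinstance(res, Rejection)
        assert res.reason == "no_peaks"

    def test_eleven_pulses_are_rejected(self):
        x = np.zeros(2000)
        for j in range(11):
            x = _triangle(x, 400 + 120 * j, 5, 1.0)
        res = preselect_trace(_raw(x))
        assert isinstance(res, Rejection)
        assert res.reason == "too_many_peaks"
        assert res.n_peaks == 11

    def test_accepted_trace_keeps_1650_samples(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.01, 2000)
        x = _triangle(x, 700, 10, 1.0)
        res = preselect_trace(_raw(x))
        assert isinstance(res, PreselectedTrace)
        assert len(res.samples) == 1650
        assert np.array_equal(res.samples, x[350:])
        assert 1 <= len(res.peaks) <= 10

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            preselect_trace(_raw(np.zeros(1999)))

    def test_determinism(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.01, 2000)
        x = _triangle(x, 900, 8, 0.7)
        a = preselect_trace(_raw(x))
        b = preselect_trace(_raw(x))
        assert np.array_equal(a.samples, b.samples)
        assert a.peaks == b.peaks


def _pre(samples, pid=1, tid="t"):
    return PreselectedTrace(samples=np.asarray(samples, float),
                            muscle=MuscleClass.TA, patient_id=pid, trace_id=tid,
                            peaks=(Peak(500, 25.0, 1.0),))


class TestNormalizePatient:
    def test_division_by_patient_peak_value(self):
        t = _pre([0.0, -2.0, 1.0, 0.0])
        (out,) = normalize_patient([t])
        assert out.samples.min() == -1.0
        assert out.samples.max() == 0.5

    def test_patient_already_at_unit_peak_is_unchanged(self):
        t = _pre([0.2, 1.0, -0.5])
        (out,) = normalize_patient([t])
        assert np.array_equal(out.samples, t.samples)

    def test_two_traces_share_the_patient_denominator(self):
        a = _pre([0.5, 0.0], tid="a")
        b = _pre([2.0, -1.0], tid="b")
        na, nb = normalize_patient([a, b])
        assert na.samples.max() == pytest.approx(0.25)
        assert nb.samples.max() == pytest.approx(1.0)

    def test_normalized_patient_maximum_is_exactly_one(self):
        rng = np.random.default_rng(6)
        traces = [_pre(rng.normal(0, s, 50), tid=f"t{i}")
                  for i, s in enumerate([0.3, 1.7, 0.9])]
        out = normalize_patient(traces)
        assert max(np.max(np.abs(t.samples)) for t in out) == 1.0

    def test_mixed_patients_and_degenerate_denominator_raise(self):
        with pytest.raises(ValueError):
            normalize_patient([_pre([1.0], pid=1), _pre([1.0], pid=2)])
        with pytest.raises(ValueError):
            normalize_patient([_pre([0.0, 0.0])])
        with pytest.raises(ValueError):
            normalize_patient([])


class TestPreselectCohort:
    def test_cohort_gate_counts_and_normalization(self, small_cohort):
        accepted, rejections = preselect_cohort(small_cohort)
        assert len(accepted) + len(rejections) == len(small_cohort)
        assert all(len(t.samples) == 1650 for t in accepted)
        assert all(t.normalized for t in accepted)
        by_patient = {}
        for t in accepted:
            by_patient.setdefault(t.patient_id, []).append(t)
        for pid, traces in by_patient.items():
            assert max(np.max(np.abs(t.samples)) for t in traces) == 1.0
        reasons = {r.reason for r in rejections}
        assert reasons <= {"no_peaks", "too_many_peaks"}
        # synthetic blanks are overwhelmingly rejected
        blank_ids = {t.trace_id for t in small_cohort if t.truth_has_mep is False}
        accepted_blanks = [t for t in accepted if t.trace_id in blank_ids]
        assert len(accepted_blanks) == 0
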