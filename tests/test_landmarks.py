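"""Segmentation: envelopes, derivative traces, landmark search, ISIs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sylseq.landmarks import (
    DEFAULT_CONFIG, BandSpec, DerivTrace, Envelope, F1Range, FlaggedTrialError,
    LandmarkSet, SegmentationError, band_envelope_db, band_specs, centroid_track,
    compute_isis, estimate_f1_range, find_consonant_onsets, find_vowel_landmarks,
    flag_ambiguous_release, gaussian_derivative, segment_trial,
    select_calibration_trials,
)
from sylseq.stimuli import build_schedule, stimulus_by_key
from sylseq.synth_audio import (
    DEFAULT_PROFILE, SpeakerProfile, Waveform, add_noise, inject_double_release,
    synth_sequence,
)

FS = 22050


def tone(freq, dur_s=0.6, fs=FS, amp=0.5):
    t = np.arange(int(dur_s * fs)) / fs
    return Waveform(amp * np.sin(2 * np.pi * freq * t), fs)


class TestBandEnvelope:
    def test_silence_sits_at_floor(self):
        spec = band_specs(630, 770)["nasal"]
        env = band_envelope_db(Waveform(np.zeros(FS // 2), FS), spec)
        assert np.all(env.values == DEFAULT_CONFIG.db_floor)

    def test_band_selectivity_for_low_tone(self):
        """A 200 Hz tone drives the nasal band but not the 2 kHz high-pass."""
        w = tone(200.0)
        specs = band_specs(630, 770)
        nasal = band_envelope_db(w, specs["nasal"])
        # compare absolute filtered RMS (both dB traces are self-normalised)
        from scipy import signal as sps
        sos_n = sps.butter(5, [60, 500], "bandpass", fs=FS, output="sos")
        sos_s = sps.butter(5, 2000, "highpass", fs=FS, output="sos")
        rms = lambda sos: np.sqrt(np.mean(sps.sosfiltfilt(sos, w.samples) ** 2))
        assert 20 * np.log10(rms(sos_n) / rms(sos_s)) >= 40.0
        assert nasal.values.max() == 0.0

    def test_nasal_band_edges(self):
        spec = band_specs(630, 770)["nasal"]
        assert (spec.low_hz, spec.high_hz, spec.filter_order) == (60.0, 500.0, 5)

    def test_band_outside_nyquist_rejected(self):
        bad = BandSpec("nasal", "bandpass", 60.0, 12000.0)
        with pytest.raises(SegmentationError, match="band edges"):
            band_envelope_db(tone(200.0), bad)


class TestCentroidTrack:
    def test_white_noise_centroid_near_half_nyquist(self):
        rng = np.random.default_rng(0)
        w = Waveform(rng.standard_normal(FS // 2) * 0.3, FS)
        env = centroid_track(w)
        mid = env.values[5:-5]
        assert np.median(mid) == pytest.approx(FS / 4, rel=0.10)

    def test_tone_centroid_at_tone_frequency(self):
        env = centroid_track(tone(1000.0))
        mid = env.values[5:-5]
        assert np.median(mid) == pytest.approx(1000.0, rel=0.05)

    def test_grid_is_12ms_window_4ms_hop(self):
        env = centroid_track(tone(1000.0, dur_s=0.1))
        # hop is the nearest whole-sample step to 4 ms (88 samples at 22050 Hz)
        assert env.hop_ms == pytest.approx(4.0, rel=0.01)
        assert np.allclose(np.diff(env.times), env.hop_ms)
        # first window [0, 12) ms is centred at 6 ms
        assert env.times[0] == pytest.approx(6.0)

    def test_too_short_waveform_rejected(self):
        with pytest.raises(SegmentationError, match="shorter"):
            centroid_track(Waveform(np.zeros(10), FS))


class TestGaussianDerivative:
    def test_constant_envelope_gives_zero(self):
        env = Envelope(np.arange(200) * 2.0, np.full(200, 5.0), "vowel", 2.0)
        d = gaussian_derivative(env, 20.0)
        assert np.max(np.abs(d.values)) < 1e-9 * 5.0

    def test_step_yields_single_peak_at_step(self):
        """step * d(Gaussian) is a Gaussian centred on the step."""
        values = np.where(np.arange(300) >= 150, 1.0, 0.0)
        env = Envelope(np.arange(300) * 2.0, values, "vowel", 2.0)
        d = gaussian_derivative(env, 20.0)
        assert abs(d.times[np.argmax(d.values)] - 300.0) <= 2.0
        # analytic oracle: peak value = Gaussian height / hop at the step
        sigma = 20.0
        expected = 1.0 / (np.sqrt(2 * np.pi) * sigma)
        assert d.values.max() == pytest.approx(expected, rel=0.01)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(150)
        env = Envelope(np.arange(150) * 2.0, vals, "vowel", 2.0)
        env2 = Envelope(env.times, 2.0 * vals, "vowel", 2.0)
        d1, d2 = gaussian_derivative(env, 16.0), gaussian_derivative(env2, 16.0)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_sigma_below_grid_rejected(self):
        env = Envelope(np.arange(50) * 4.0, np.zeros(50), "fricative", 4.0)
        with pytest.raises(SegmentationError, match="too small"):
            gaussian_derivative(env, 6.0)


def _alternation_oracle(times, values, n):
    """Exhaustive subset search over candidate peaks (<=8), for cross-checking
    the dynamic-programming selection."""
    from scipy.signal import find_peaks
    pk, _ = find_peaks(values)
    pk = [i for i in pk if values[i] > 0]
    vl, _ = find_peaks(-values)
    vl = [i for i in vl if values[i] < 0]
    vt = [times[i] for i in vl]
    best, best_sel = -np.inf, None
    for sel in itertools.combinations(pk, n):
        ts = [times[i] for i in sel]
        ok = all(any(a < v < b for v in vt) for a, b in zip(ts, ts[1:]))
        ok = ok and any(v > ts[-1] for v in vt)
        if ok:
            total = sum(values[i] for i in sel)
            if total > best:
                best, best_sel = total, ts
    return best_sel


def _bumpy_trace(rng, n_bumps):
    """Derivative-like trace: alternating positive/negative bumps with random
    heights; returns a DerivTrace with <=8 candidate peaks."""
    t = np.arange(400) * 2.0
    vals = np.zeros(400)
    centers = np.sort(rng.choice(np.arange(30, 370, 12), n_bumps * 2, replace=False))
    for j, c in enumerate(centers):
        h = rng.uniform(0.5, 2.0) * (1 if j % 2 == 0 else -1)
        vals += h * np.exp(-0.5 * ((np.arange(400) - c) / 3.0) ** 2)
    return DerivTrace(t, vals, 10.0)


class TestVowelLandmarkSearch:
    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 4))
    def test_matches_exhaustive_subset_search(self, seed, n):
        rng = np.random.default_rng(seed)
        d = _bumpy_trace(rng, rng.integers(max(n, 2), 5))
        oracle = _alternation_oracle(d.times, d.values, n)
        pairs, flags = find_vowel_landmarks(d, n)
        if oracle is None:
            assert len(pairs) < n and flags
        else:
            assert [p for p, _ in pairs] == pytest.approx(oracle)

    def test_single_bump(self):
        t = np.arange(200) * 2.0
        vals = (np.exp(-0.5 * ((np.arange(200) - 80) / 4) ** 2)
                - np.exp(-0.5 * ((np.arange(200) - 120) / 4) ** 2))
        d = DerivTrace(t, vals, 10.0)
        pairs, flags = find_vowel_landmarks(d, 1)
        assert not flags
        assert pairs[0][0] == pytest.approx(160.0, abs=2.0)
        assert pairs[0][1] == pytest.approx(240.0, abs=2.0)

    def test_small_spurious_bump_never_selected(self):
        """5 tall alternating bumps plus one small extra peak: the 5 largest
        alternation-feasible peaks win."""
        idx = np.arange(700)
        t = idx * 2.0
        vals = np.zeros(700)
        tall = [60, 180, 300, 420, 540]
        for c in tall:
            vals += 2.0 * np.exp(-0.5 * ((idx - c) / 4) ** 2)
            vals -= 2.0 * np.exp(-0.5 * ((idx - c - 60) / 4) ** 2)
        vals += 0.3 * np.exp(-0.5 * ((idx - 650) / 4) ** 2)
        vals -= 0.3 * np.exp(-0.5 * ((idx - 680) / 4) ** 2)
        pairs, flags = find_vowel_landmarks(DerivTrace(t, vals, 10.0), 5)
        assert not flags
        assert [p for p, _ in pairs] == pytest.approx([2.0 * c for c in tall], abs=2.0)

    def test_infeasible_count_flagged(self):
        d = _bumpy_trace(np.random.default_rng(2), 2)
        pairs, flags = find_vowel_landmarks(d, 5)
        assert len(pairs) < 5
        assert any(f[0] == "missingLandmark" for f in flags)


class TestConsonantOnsetSearch:
    @staticmethod
    def _trace(peaks):
        idx = np.arange(500)
        vals = np.zeros(500)
        for c, h in peaks:
            vals += h * np.exp(-0.5 * ((idx - c / 2.0) / 3.0) ** 2)
        return DerivTrace(idx * 2.0, vals, 5.0)

    def test_window_constrained_argmax(self):
        """A larger peak outside the search window must not be chosen."""
        stim = stimulus_by_key(1, 1)   # single nasal syllable "ma"
        traces = {"nasal": self._trace([(100, 1.0), (400, 5.0)])}
        onsets, flags = find_consonant_onsets(traces, [(300.0, 500.0)], stim)
        assert not flags
        assert onsets[0] == pytest.approx(100.0, abs=2.0)

    def test_single_candidate_taken_regardless_of_height(self):
        stim = stimulus_by_key(1, 1)
        traces = {"nasal": self._trace([(150, 0.05)])}
        onsets, flags = find_consonant_onsets(traces, [(300.0, 500.0)], stim)
        assert not flags and onsets[0] == pytest.approx(150.0, abs=2.0)

    def test_empty_window_flagged(self):
        stim = stimulus_by_key(1, 1)
        traces = {"nasal": self._trace([(400, 1.0)])}
        onsets, flags = find_consonant_onsets(traces, [(300.0, 500.0)], stim)
        assert flags == [("missingLandmark", 1)]


class TestAmbiguousRelease:
    def test_comparable_double_peak_flagged(self):
        idx = np.arange(300)
        vals = (np.exp(-0.5 * ((idx - 100) / 4) ** 2)
                + 0.9 * np.exp(-0.5 * ((idx - 140) / 4) ** 2))
        d = DerivTrace(idx * 1.0, vals, 5.0)
        assert flag_ambiguous_release(d, (50.0, 250.0)) is True

    def test_height_ratio_below_threshold_not_flagged(self):
        idx = np.arange(300)
        vals = (np.exp(-0.5 * ((idx - 100) / 4) ** 2)
                + 0.2 * np.exp(-0.5 * ((idx - 140) / 4) ** 2))
        d = DerivTrace(idx * 1.0, vals, 5.0)
        assert flag_ambiguous_release(d, (50.0, 250.0)) is False

    def test_close_peaks_not_flagged(self):
        idx = np.arange(300)
        vals = (np.exp(-0.5 * ((idx - 100) / 3) ** 2)
                + 0.9 * np.exp(-0.5 * ((idx - 108) / 3) ** 2))
        d = DerivTrace(idx * 1.0, vals, 5.0)
        assert flag_ambiguous_release(d, (50.0, 250.0)) is False


class TestF1Calibration:
    def test_constant_f1_speaker(self, stimulus_table):
        prof = SpeakerProfile(vowel_f1=700.0)
        trials = [(synth_sequence(stimulus_table[i], prof, seed=i).waveform,
                   stimulus_table[i]) for i in (0, 4, 9, 14, 19, 24, 29, 7, 12, 22)]
        r = estimate_f1_range(trials)
        assert r.f1_min <= 700.0 <= r.f1_max
        # width ~ 2x the 10% guard, allowing 5% estimation spread
        assert (r.f1_max - r.f1_min) <= 0.25 * 700.0
        assert r.n_trials_used == 10

    def test_mixed_f1_speakers_span_recovered(self, stimulus_table):
        p6 = SpeakerProfile(vowel_f1=600.0, f1_min=450.0, f1_max=800.0)
        p9 = SpeakerProfile(vowel_f1=900.0, f1_min=700.0, f1_max=1100.0)
        trials = [(synth_sequence(stimulus_table[i], p6, seed=i).waveform,
                   stimulus_table[i]) for i in (4, 9, 14)]
        trials += [(synth_sequence(stimulus_table[i], p9, seed=i).waveform,
                    stimulus_table[i]) for i in (19, 24, 29)]
        r = estimate_f1_range(trials)
        assert r.f1_min <= 600.0 * 1.05 and r.f1_max >= 900.0 * 0.95

    def test_calibration_subset_is_first_25_of_runs_1_and_5(self):
        sched = build_schedule(11)
        sel = select_calibration_trials(sched)
        assert len(sel) == 50
        assert {t.run for t in sel} == {1, 5}
        assert all(t.trial <= 25 for t in sel)

    def test_no_voiced_frames_is_labelled_failure(self):
        w = Waveform(np.zeros(FS // 4), FS)
        with pytest.raises(SegmentationError, match="voiced"):
            estimate_f1_range([(w, stimulus_by_key(1, 1))])


class TestSegmentTrial:
    def test_clean_recovery_all_stimuli(self, clean_trials, f1_default):
        """Full sweep: every landmark within 15 ms of synthesis truth."""
        for stim, trial in clean_trials:
            ls = segment_trial(trial.waveform, stim, f1_default)
            assert ls.qc_flags == []
            assert ls.ordered()
            np.testing.assert_allclose(ls.c_on, trial.truth.c_on, atol=15.0)
            np.testing.assert_allclose(ls.v_on, trial.truth.v_on, atol=15.0)
            np.testing.assert_allclose(ls.v_off, trial.truth.v_off, atol=15.0)

    def test_single_syllable_trial(self, f1_default):
        stim = stimulus_by_key(3, 1)   # "ta"
        trial = synth_sequence(stim, DEFAULT_PROFILE, seed=33)
        ls = segment_trial(trial.waveform, stim, f1_default)
        assert ls.qc_flags == [] and ls.n == 1
        assert ls.c_on[0] < ls.v_on[0] < ls.v_off[0]

    def test_double_release_trial_flagged(self, f1_default):
        stim = stimulus_by_key(1, 3)
        trial = synth_sequence(stim, DEFAULT_PROFILE, seed=9)
        doubled = inject_double_release(trial, 2, 40.0)
        ls = segment_trial(doubled.waveform, stim, f1_default)
        assert ("ambiguousRelease", 2) in ls.qc_flags

    def test_noise_robustness_at_30_db(self, clean_trials, f1_default):
        """At SNR 30 dB mean onset error stays within twice the clean bound."""
        errs = []
        for i, (stim, trial) in enumerate(clean_trials):
            noisy = add_noise(trial, 30.0, seed=42 + i)
            ls = segment_trial(noisy.waveform, stim, f1_default)
            if ls.qc_flags:
                continue
            errs += np.abs(np.array(ls.c_on) - trial.truth.c_on).tolist()
            errs += np.abs(np.array(ls.v_on) - trial.truth.v_on).tolist()
        assert len(errs) > 50
        assert np.mean(errs) <= 20.0


class TestComputeIsis:
    def test_onset_to_onset_differences(self):
        ls = LandmarkSet([100.0, 350.0, 600.0], [160.0, 410.0, 660.0],
                         [290.0, 540.0, 790.0])
        recs = compute_isis(ls, "t1")
        assert [r.isi_ms for r in recs] == [250.0, 250.0]
        assert [r.position for r in recs] == [1, 2]

    def test_single_syllable_yields_nothing(self):
        ls = LandmarkSet([100.0], [160.0], [290.0])
        assert compute_isis(ls) == []

    def test_flagged_trial_refused(self):
        ls = LandmarkSet([100.0, 350.0], [160.0, 410.0], [290.0, 540.0],
                         qc_flags=[("ambiguousRelease", 2)])
        with pytest.raises(FlaggedTrialError):
            compute_isis(ls, "t9")

    def test_planned_isis_recovered_from_audio(self, f1_default):
        stim = stimulus_by_key(1, 4)
        plan = [300.0, 200.0, 250.0]
        trial = synth_sequence(stim, DEFAULT_PROFILE, isi_plan=plan, seed=21)
        ls = segment_trial(trial.waveform, stim, f1_default)
        assert ls.qc_flags == []
        recs = compute_isis(ls, "planned")
        assert [r.isi_ms for r in recs] == pytest.approx(plan, abs=15.0)

    def test_count_conservation(self, clean_trials, f1_default):
        """Unflagged n-syllable trials contribute exactly n-1 ISI records."""
        expected = total = 0
        for stim, trial in clean_trials:
            ls = segment_trial(trial.waveform, stim, f1_default)
            if ls.qc_flags or stim.n < 2:
                continue
            expected += stim.n - 1
            total += len(compute_isis(ls))
        assert total == expected > 0
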