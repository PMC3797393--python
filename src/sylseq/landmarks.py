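"""Multi-band landmark segmentation and inter-syllable interval extraction.

The algorithm recovers, for every CV syllable of a known target sequence,
three landmarks — consonant onset, vowel onset, vowel offset — from
class-specific spectral energy trajectories:

1. the signal is band-limited per sound class with zero-phase fifth-order
   Butterworth filters (nasal 60–500 Hz band; stop/affricate 2 kHz
   high-pass; vowel F1 band calibrated per speaker) and converted to a dB
   envelope; the fricative pathway instead tracks the first spectral moment
   (centroid) over 12 ms windows stepped 4 ms;
2. each trajectory is convolved with a Gaussian-derivative kernel whose
   scale matches the rise time of its class;
3. the n largest positive peaks of the vowel derivative that can be
   separated by n negative valleys give the vowel onsets, and the deepest
   valley after each selected peak gives the vowel offset;
4. the k-th consonant onset is the largest derivative peak of that
   consonant's class trace inside the window (vOff_{k−1}, vOn_k);
5. obstruent windows containing two comparable release peaks are flagged as
   ambiguous (double release) and excluded downstream.

ISIs are onset-to-onset differences of consecutive consonant onsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.linalg import solve_toeplitz
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .stimuli import PHONES, SoundClass, Schedule, Stimulus, Trial
from .synth_audio import Waveform

# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class LandmarkConfig:
    """All tunable thresholds of the segmentation stage.

    Defaults: 10 ms RMS window for dB envelopes; envelope hop 1 ms for the
    fast stop/affricate pathway, 2 ms for vowel/nasal, fixed 4 ms for the
    centroid pathway; Gaussian-derivative scales matched to class rise
    times (vowel 20 ms, nasal 10 ms, stop/affricate 5 ms, fricative 10 ms);
    dB floor −30 re trial envelope max; double-release height ratio 0.7 and
    minimum peak separation 15 ms.

    The floor matters for timing accuracy: zero-phase narrow-band filtering
    spreads a small fraction of onset energy backward in time, and on a dB
    scale that low-level tail (≤ −30 dB re max) advances the derivative
    peak by >10 ms.  Clipping at −30 dB keeps the measured rise centred on
    the true amplitude ramp.
    """

    rms_window_ms: float = 10.0
    hop_ms: dict = field(default_factory=lambda: {
        "vowel": 2.0, "nasal": 2.0, "stop": 1.0, "affricate": 1.0, "fricative": 4.0,
    })
    sigma_ms: dict = field(default_factory=lambda: {
        "vowel": 20.0, "nasal": 10.0, "stop": 5.0, "affricate": 5.0, "fricative": 10.0,
    })
    db_floor: float = -30.0
    ambiguity_height_ratio: float = 0.7
    ambiguity_gap_min_ms: float = 15.0
    centroid_window_ms: float = 12.0
    centroid_hop_ms: float = 4.0
    centroid_power_gate_db: float = -35.0
    filter_order: int = 5
    nasal_band: tuple = (60.0, 500.0)
    obstruent_highpass: float = 2000.0
    f1_guard: float = 0.10
    #: peak-prominence quantile below which a landmark is logged low-confidence
    confidence_quantile: float = 0.10


DEFAULT_CONFIG = LandmarkConfig()


class SegmentationError(RuntimeError):
    pass


class FlaggedTrialError(SegmentationError):
    """Raised when ISIs are requested for a QC-flagged trial."""


# ------------------------------------------------------------- containers


@dataclass
class BandSpec:
    sound_class: str
    kind: str                      # bandpass | highpass | centroid
    low_hz: float | None
    high_hz: float | None
    filter_order: int = 5


def band_specs(f1_min: float, f1_max: float,
               config: LandmarkConfig = DEFAULT_CONFIG) -> dict[str, BandSpec]:
    """Per-class band definitions; the vowel band is the speaker's F1 range."""
    lo, hi = config.nasal_band
    return {
        "vowel": BandSpec("vowel", "bandpass", f1_min, f1_max, config.filter_order),
        "nasal": BandSpec("nasal", "bandpass", lo, hi, config.filter_order),
        "stop": BandSpec("stop", "highpass", config.obstruent_highpass, None,
                         config.filter_order),
        "affricate": BandSpec("affricate", "highpass", config.obstruent_highpass, None,
                              config.filter_order),
        "fricative": BandSpec("fricative", "centroid", None, None),
    }


@dataclass
class Envelope:
    times: np.ndarray        # ms
    values: np.ndarray       # dB (energy pathways) or Hz (centroid)
    sound_class: str
    hop_ms: float


@dataclass
class DerivTrace:
    times: np.ndarray
    values: np.ndarray
    sigma_ms: float


@dataclass
class F1Range:
    f1_min: float
    f1_max: float
    n_trials_used: int


@dataclass
class LandmarkSet:
    c_on: list[float]
    v_on: list[float]
    v_off: list[float]
    qc_flags: list[tuple] = field(default_factory=list)
    #: (syllable, landmark, prominence) entries judged low-confidence
    audit: list[tuple] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.v_on)

    def ordered(self) -> bool:
        seq = [t for trip in zip(self.c_on, self.v_on, self.v_off) for t in trip]
        return all(b > a for a, b in zip(seq, seq[1:]))


@dataclass
class ISIRecord:
    trial_ref: str
    position: int      # 1 … n−1
    isi_ms: float


# ------------------------------------------------------------- envelopes


def band_envelope_db(w: Waveform, spec: BandSpec,
                     config: LandmarkConfig = DEFAULT_CONFIG) -> Envelope:
    """Zero-phase Butterworth filtering, sliding-RMS, dB re trial max.

    Zero-phase (forward–backward) filtering keeps landmark times free of
    filter group delay.
    """
    fs = w.sample_rate
    nyq = fs / 2.0
    if spec.kind == "bandpass":
        if not (0 < spec.low_hz < spec.high_hz < nyq):
            raise SegmentationError(f"band edges {spec.low_hz}-{spec.high_hz} outside (0, {nyq})")
        sos = signal.butter(spec.filter_order, [spec.low_hz, spec.high_hz],
                            "bandpass", fs=fs, output="sos")
    elif spec.kind == "highpass":
        if not (0 < spec.low_hz < nyq):
            raise SegmentationError(f"cutoff {spec.low_hz} outside (0, {nyq})")
        sos = signal.butter(spec.filter_order, spec.low_hz, "highpass",
                            fs=fs, output="sos")
    else:
        raise SegmentationError(f"band_envelope_db needs an energy band, got {spec.kind!r}")

    y = signal.sosfiltfilt(sos, w.samples) if len(w.samples) > 50 else np.zeros_like(w.samples)
    win = max(2, int(round(config.rms_window_ms * fs / 1000.0)))
    rms = np.sqrt(np.maximum(uniform_filter1d(y * y, win, mode="nearest"), 0.0))
    hop_ms = config.hop_ms[spec.sound_class]
    hop = max(1, int(round(hop_ms * fs / 1000.0)))
    rms = rms[::hop]
    ref = float(np.max(rms))
    if ref <= 0:
        db = np.full(len(rms), config.db_floor)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(np.maximum(rms, 1e-30) / ref)
        db = np.maximum(db, config.db_floor)
    times = np.arange(len(db)) * (hop * 1000.0 / fs)
    return Envelope(times, db, spec.sound_class, hop * 1000.0 / fs)


def centroid_track(w: Waveform, config: LandmarkConfig = DEFAULT_CONFIG) -> Envelope:
    """First spectral moment (Hz) over 12 ms windows stepped 4 ms.

    Windows whose RMS sits more than 35 dB below the loudest window carry
    no usable frication energy (the quietest fricative here sits near
    −20 dB re the vowel peak) and are assigned centroid 0, so frication
    onsets appear as rises from zero rather than jumps measured on silence
    or on a broadband noise floor.
    """
    fs = w.sample_rate
    win = int(round(config.centroid_window_ms * fs / 1000.0))
    hop = int(round(config.centroid_hop_ms * fs / 1000.0))
    x = w.samples
    if len(x) < win:
        raise SegmentationError("waveform shorter than the centroid window")
    starts = np.arange(0, len(x) - win + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[::hop][: len(starts)]
    window = np.hanning(win)
    spec = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    power = spec.sum(axis=1)
    rms = np.sqrt(power / win)
    gate = np.max(rms) * 10 ** (config.centroid_power_gate_db / 20.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (spec @ freqs) / power
    # sustained-power mask: an isolated supra-gate window (e.g. a noise
    # fluctuation in a silent gap) is not frication — require 3 in a row
    mask = rms > gate
    from scipy.ndimage import binary_opening
    mask = binary_opening(mask, structure=np.ones(3, dtype=bool))
    cent = np.where(mask, np.nan_to_num(cent), 0.0)
    times = starts * 1000.0 / fs + config.centroid_window_ms / 2.0
    # report the realised whole-sample hop so the grid is self-consistent
    return Envelope(times, cent, "fricative", hop * 1000.0 / fs)


def gaussian_derivative(e: Envelope, sigma_ms: float) -> DerivTrace:
    """Smoothed time derivative: convolution with a first-derivative-of-
    Gaussian kernel (±4σ support, reflective boundaries); units value/ms."""
    if sigma_ms <= 0 or sigma_ms < 2.0 * e.hop_ms:
        raise SegmentationError(f"sigma {sigma_ms} ms too small for hop {e.hop_ms} ms")
    sigma = sigma_ms / e.hop_ms
    d = gaussian_filter1d(e.values.astype(float), sigma, order=1,
                          mode="reflect", truncate=4.0)
    return DerivTrace(e.times, d / e.hop_ms, sigma_ms)


# ---------------------------------------------------------- F1 calibration


def select_calibration_trials(schedule: Schedule, n_per_run: int = 25) -> list[Trial]:
    """The F1-calibration subset: the first ``n_per_run`` trials of runs 1 and 5."""
    out = []
    for run in (1, 5):
        out.extend(t for t in schedule.run_trials(run) if t.trial <= n_per_run)
    return out


def _lpc_f1(frame: np.ndarray, fs: int, order: int) -> float | None:
    # pre-emphasis flattens the glottal-source spectral tilt, which would
    # otherwise bias the all-pole resonance estimate downward
    frame = np.append(frame[0], frame[1:] - 0.97 * frame[:-1])
    frame = frame * np.hamming(len(frame))
    r = np.correlate(frame, frame, "full")[len(frame) - 1:len(frame) + order]
    if r[0] <= 0:
        return None
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return None
    roots = np.roots(np.concatenate([[1.0], -a]))
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * fs / (2 * np.pi)
    bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / np.pi
    # a true formant root is sharp; broad-bandwidth roots are spectral-tilt
    # artefacts of the all-pole fit
    cand = sorted(f for f, b in zip(freqs, bws) if 350.0 <= f <= 1200.0 and b < 150.0)
    return cand[0] if cand else None


def estimate_f1_range(trials: Sequence[tuple[Waveform, Stimulus]],
                      config: LandmarkConfig = DEFAULT_CONFIG) -> F1Range:
    """Estimate the speaker's F1 range from calibration trials.

    Vowel frames are gated by energy in the 500–1200 Hz region (where the
    F1 of an open vowel lives) that also dominates the 60–450 Hz band —
    the ratio test rejects nasal murmurs, whose energy concentrates at the
    low murmur resonance.  F1 is taken per frame from linear-prediction
    roots (order fs/1000 + 2, candidates 350–1200 Hz), summarised as a
    per-trial median, and the min/max of the trial medians is widened by a
    ±10% guard margin.
    """
    if not trials:
        raise SegmentationError("no calibration trials")
    per_trial: list[float] = []
    for w, _stim in trials:
        fs = w.sample_rate
        sos_mid = signal.butter(4, [500.0, 1200.0], "bandpass", fs=fs, output="sos")
        sos_low = signal.butter(4, [60.0, 450.0], "bandpass", fs=fs, output="sos")
        mid = signal.sosfiltfilt(sos_mid, w.samples)
        low = signal.sosfiltfilt(sos_low, w.samples)
        flen = int(round(0.025 * fs))
        hop = int(round(0.010 * fs))
        starts = np.arange(0, len(w.samples) - flen, hop)
        mid_rms = np.array([np.sqrt(np.mean(mid[s:s + flen] ** 2)) for s in starts])
        low_rms = np.array([np.sqrt(np.mean(low[s:s + flen] ** 2)) for s in starts])
        if mid_rms.size == 0 or mid_rms.max() <= 0:
            continue
        voiced = starts[(mid_rms > 0.25 * mid_rms.max()) & (mid_rms > low_rms)]
        order = int(round(fs / 1000.0)) + 2
        f1s = [f for s in voiced
               if (f := _lpc_f1(w.samples[s:s + flen], fs, order)) is not None]
        if f1s:
            per_trial.append(float(np.median(f1s)))
    if not per_trial:
        raise SegmentationError("no voiced vowel frames found in calibration trials")
    lo, hi = min(per_trial), max(per_trial)
    g = config.f1_guard
    return F1Range(lo * (1 - g), hi * (1 + g), len(per_trial))


# --------------------------------------------------- peak/valley machinery


def _peaks_valleys(d: DerivTrace):
    """Positive local maxima and negative local minima of a derivative trace."""
    pk, _ = signal.find_peaks(d.values)
    pk = pk[d.values[pk] > 0]
    vl, _ = signal.find_peaks(-d.values)
    vl = vl[d.values[vl] < 0]
    return pk, vl


def find_vowel_landmarks(d: DerivTrace, n: int) -> tuple[list[tuple[float, float]], list[tuple]]:
    """Select the n largest positive peaks separable by n valleys.

    Dynamic programme over candidate peaks: maximise total selected peak
    height subject to a negative valley strictly between consecutive
    selections and one after the last; exact for these candidate counts.
    Returns ([(vOn, vOff), …], flags); short selections are flagged
    ``missingLandmark``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pk, vl = _peaks_valleys(d)
    tp, hp = d.times[pk], d.values[pk]
    tv = d.times[vl]
    m = len(tp)

    def valley_between(a: float, b: float) -> bool:
        return bool(np.any((tv > a) & (tv < b)))

    def best_chain(count: int):
        # dp[j][i]: best total height choosing j+1 peaks ending at peak i
        NEG = -math.inf
        dp = [[NEG] * m for _ in range(count)]
        back = [[-1] * m for _ in range(count)]
        for i in range(m):
            dp[0][i] = hp[i]
        for j in range(1, count):
            for i in range(m):
                for i2 in range(i):
                    if dp[j - 1][i2] > NEG and valley_between(tp[i2], tp[i]):
                        cand = dp[j - 1][i2] + hp[i]
                        if cand > dp[j][i] + 1e-12:
                            dp[j][i] = cand
                            back[j][i] = i2
        best, best_i = NEG, -1
        for i in range(m):
            if dp[count - 1][i] > NEG and np.any(tv > tp[i]):
                if dp[count - 1][i] > best + 1e-12:
                    best, best_i = dp[count - 1][i], i
        if best_i < 0:
            return None
        chain = [best_i]
        for j in range(count - 1, 0, -1):
            chain.append(back[j][chain[-1]])
        return chain[::-1]

    chain = None
    used = 0
    for count in range(min(n, m), 0, -1):
        chain = best_chain(count)
        if chain is not None:
            used = count
            break
    flags: list[tuple] = [("missingLandmark", k) for k in range(used + 1, n + 1)]
    if chain is None:
        return [], flags

    pairs: list[tuple[float, float]] = []
    sel_t = [tp[i] for i in chain]
    for k, t_on in enumerate(sel_t):
        t_end = sel_t[k + 1] if k + 1 < len(sel_t) else d.times[-1] + 1.0
        span = vl[(tv > t_on) & (tv < t_end)]
        if span.size == 0:
            flags.append(("missingLandmark", k + 1))
            continue
        deepest = span[np.argmin(d.values[span])]
        pairs.append((float(t_on), float(d.times[deepest])))
    return pairs, flags


def find_consonant_onsets(traces: dict[str, DerivTrace],
                          vowels: list[tuple[float, float]],
                          stim: Stimulus) -> tuple[list[float], list[tuple]]:
    """Largest class-trace derivative peak in each window (vOff_{k−1}, vOn_k).

    The first window starts at the trace start; ties break to the earliest
    peak.  Windows without a positive peak are flagged ``missingLandmark``.
    """
    if len(vowels) != stim.n:
        raise SegmentationError("need one vowel landmark pair per syllable")
    onsets: list[float] = []
    flags: list[tuple] = []
    for k, c in enumerate(stim.syllables):
        cls = PHONES[c].sound_class.value
        d = traces[cls]
        lo = vowels[k - 1][1] if k > 0 else d.times[0] - 1.0
        hi = vowels[k][0]
        pk, _ = _peaks_valleys(d)
        inwin = pk[(d.times[pk] > lo) & (d.times[pk] < hi)]
        if inwin.size == 0:
            flags.append(("missingLandmark", k + 1))
            onsets.append(math.nan)
            continue
        h = d.values[inwin]
        best = inwin[np.flatnonzero(h >= h.max() - 1e-12)[0]]
        onsets.append(float(d.times[best]))
    return onsets, flags


def flag_ambiguous_release(d: DerivTrace, window: tuple[float, float],
                           config: LandmarkConfig = DEFAULT_CONFIG) -> bool:
    """True iff the window holds ≥2 peaks of comparable height (ratio ≥ θ)
    separated by at least ``gapMin`` — the double-release signature."""
    lo, hi = window
    pk, _ = _peaks_valleys(d)
    inwin = pk[(d.times[pk] > lo) & (d.times[pk] < hi)]
    if inwin.size < 2:
        return False
    t, h = d.times[inwin], d.values[inwin]
    imax = int(np.argmax(h))
    for i in range(len(inwin)):
        if i == imax:
            continue
        if (h[i] / h[imax] >= config.ambiguity_height_ratio
                and abs(t[i] - t[imax]) >= config.ambiguity_gap_min_ms):
            return True
    return False


# ---------------------------------------------------------- full pipeline


def class_traces(w: Waveform, f1: F1Range, classes: set[str],
                 config: LandmarkConfig = DEFAULT_CONFIG) -> dict[str, DerivTrace]:
    """Envelope + Gaussian-derivative traces for the requested sound classes."""
    specs = band_specs(f1.f1_min, f1.f1_max, config)
    traces = {}
    for cls in classes:
        if cls == "fricative":
            env = centroid_track(w, config)
        else:
            env = band_envelope_db(w, specs[cls], config)
        traces[cls] = gaussian_derivative(env, config.sigma_ms[cls])
    return traces


def segment_trial(w: Waveform, stim: Stimulus, f1: F1Range,
                  config: LandmarkConfig = DEFAULT_CONFIG) -> LandmarkSet:
    """Run the full first-stage segmentation for one trial.

    QC flags (missing landmarks, ambiguous double releases) are recorded on
    the result instead of raising, mirroring a reviewer queue.
    """
    classes = {"vowel"} | {PHONES[c].sound_class.value for c in stim.syllables}
    traces = class_traces(w, f1, classes, config)

    vowels, vflags = find_vowel_landmarks(traces["vowel"], stim.n)
    if len(vowels) < stim.n:
        return LandmarkSet([], [v for v, _ in vowels], [o for _, o in vowels],
                           qc_flags=vflags)
    onsets, cflags = find_consonant_onsets(traces, vowels, stim)

    flags = list(vflags) + list(cflags)
    for k, c in enumerate(stim.syllables):
        cls = PHONES[c].sound_class
        if cls in (SoundClass.STOP, SoundClass.AFFRICATE):
            lo = vowels[k - 1][1] if k > 0 else traces[cls.value].times[0] - 1.0
            if flag_ambiguous_release(traces[cls.value], (lo, vowels[k][0]), config):
                flags.append(("ambiguousRelease", k + 1))

    ls = LandmarkSet([float(t) for t in onsets],
                     [v for v, _ in vowels], [o for _, o in vowels], qc_flags=flags)
    _audit_low_confidence(ls, traces, stim, config)
    return ls


def _audit_low_confidence(ls: LandmarkSet, traces: dict[str, DerivTrace],
                          stim: Stimulus, config: LandmarkConfig) -> None:
    """Log landmarks whose derivative peak is small relative to the trial's
    peak distribution — the automated stand-in for stage-two human review."""
    d = traces["vowel"]
    pk, _ = _peaks_valleys(d)
    if pk.size == 0 or not ls.v_on:
        return
    thresh = np.quantile(d.values[pk], config.confidence_quantile)
    for k, t in enumerate(ls.v_on):
        i = int(np.argmin(np.abs(d.times - t)))
        if d.values[i] < thresh:
            ls.audit.append((k + 1, "vOn", float(d.values[i])))


def compute_isis(ls: LandmarkSet, trial_ref: str = "") -> list[ISIRecord]:
    """Onset-to-onset intervals cOn_{k+1} − cOn_k; refuses flagged trials.

    Single-syllable trials yield no records (no second onset exists).
    """
    if ls.qc_flags:
        raise FlaggedTrialError(f"trial {trial_ref!r} carries QC flags: {ls.qc_flags}")
    return [ISIRecord(trial_ref, k + 1, ls.c_on[k + 1] - ls.c_on[k])
            for k in range(len(ls.c_on) - 1)]


def write_landmark_table(path, rows: list[dict]) -> None:
    """Tab-separated landmark/ISI table: trial, syllable, cOn_ms, vOn_ms,
    vOff_ms, isi_ms, flags."""
    cols = ["trial", "syllable", "cOn_ms", "vOn_ms", "vOff_ms", "isi_ms", "flags"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in cols) + "\n")
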