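"""Synthetic CV-sequence audio with exact ground-truth landmarks.

Source-filter synthesis, deliberately simple: a smoothed glottal impulse
train or a white-noise source passed through second-order resonators or
Butterworth bands.  Each sound class gets the spectro-temporal signature its
detector pathway monitors:

* vowel /a/ — periodic source at f0 through an F1 resonance (speaker
  parameter, default 700 Hz) plus a fixed F2 near 1200 Hz;
* nasals — low-amplitude periodic murmur with energy concentrated below
  500 Hz (resonance near 250 Hz plus a low-pass guard);
* stops — silence (closure), a broadband release burst shaped above
  2 kHz, then a 45 ms aspiration gap before the vowel;
* affricates — burst followed by 40 ms of postalveolar frication;
* fricatives — noise shaped to a class-specific spectral centroid
  (sh/z high, th/v moderate, h low-amplitude broadband).

Ground-truth landmark times are recorded at the exact synthesis boundaries
(consonant onset = start of the consonant's acoustic event, i.e. the release
burst for obstruents; every boundary is the start of its 5 ms amplitude
ramp).  Timing is coarticulation-free: syllables are laid out on an
onset-to-onset grid, so a supplied ISI plan is honoured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

from .stimuli import PHONES, SoundClass, Stimulus

DEFAULT_SAMPLE_RATE = 22050


class SynthesisError(ValueError):
    """Raised for invalid synthesis requests (unknown phone, infeasible plan)."""


@dataclass(frozen=True)
class SpeakerProfile:
    """Generative voice parameters for one synthetic speaker.

    ``rate_scale`` multiplies every segment duration (>1 = slower speech);
    ``vowel_f1`` must sit inside [``f1_min``, ``f1_max``], the range the
    speaker's F1 calibration should recover.
    """

    f0: float = 120.0
    f1_min: float = 550.0
    f1_max: float = 900.0
    vowel_f1: float = 700.0
    rate_scale: float = 1.0
    group: str = "healthy"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f1_min < self.vowel_f1 < self.f1_max):
            raise ValueError("require 0 < f1_min < vowel_f1 < f1_max")
        if self.f0 >= self.f1_min:
            raise ValueError("f0 must be below f1_min")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")


DEFAULT_PROFILE = SpeakerProfile()

# nominal segment durations (ms), scaled by profile.rate_scale
DUR = {
    "burst": 15.0,
    "vot": 45.0,       # aspiration gap between stop burst and vowel onset
    "affric": 40.0,    # affricate frication after the burst
    "fric": 70.0,
    "nasal": 70.0,
    "vowel": 130.0,
    "gap": 60.0,       # default inter-syllable gap (vOff -> next cOn)
}
RAMP_MS = 5.0
LEAD_MS = 80.0
TAIL_MS = 100.0
MIN_GAP_MS = 10.0

# fricative noise bands (low Hz, high Hz, amplitude); centroid of the shaped
# noise falls near the band centre
FRIC_BANDS = {
    "sh": (2500.0, 4500.0, 0.50),
    "ch": (2500.0, 4500.0, 0.50),   # frication portion of the affricate
    "j": (2500.0, 4500.0, 0.50),
    "z": (3500.0, 5500.0, 0.50),
    "v": (1200.0, 2800.0, 0.30),
    "th": (1700.0, 3300.0, 0.30),
    "h": (500.0, 8000.0, 0.12),
}
NASAL_AMP = 0.35
VOWEL_AMP = 0.90
BURST_AMP = 1.00


@dataclass
class GroundTruthLandmarks:
    """Per-syllable consonant onset, vowel onset, vowel offset (ms)."""

    c_on: list[float]
    v_on: list[float]
    v_off: list[float]

    @property
    def n(self) -> int:
        return len(self.c_on)

    def isis(self) -> list[float]:
        return [b - a for a, b in zip(self.c_on, self.c_on[1:])]

    def check(self, duration_ms: float) -> None:
        seq = []
        for c, v, o in zip(self.c_on, self.v_on, self.v_off):
            seq += [c, v, o]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("landmarks are not strictly interleaved")
        if seq and (seq[0] < 0 or seq[-1] > duration_ms):
            raise ValueError("landmarks outside waveform")


@dataclass
class Waveform:
    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate


@dataclass
class TrialAudio:
    waveform: Waveform
    truth: GroundTruthLandmarks
    stimulus: Stimulus
    profile: SpeakerProfile
    artifacts: list[tuple] = field(default_factory=list)


# ---------------------------------------------------------------- sources

def _ms(n_ms: float, fs: int) -> int:
    return int(round(n_ms * fs / 1000.0))


def _glottal_source(n: int, f0: float, fs: int, phase0: float = 0.0) -> np.ndarray:
    """Impulse train at f0 smoothed with a 0.3 ms Gaussian (steep HF roll-off)."""
    out = np.zeros(n)
    period = fs / f0
    t = phase0 * period
    while t < n:
        out[int(t)] = 1.0
        t += period
    return gaussian_filter1d(out, 0.3e-3 * fs, mode="constant")


def _resonator(x: np.ndarray, freq: float, bw: float, fs: int) -> np.ndarray:
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * freq / fs
    b = [1.0 - r]
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    return signal.lfilter(b, a, x)


def _normalize(x: np.ndarray, peak: float) -> np.ndarray:
    m = np.max(np.abs(x))
    return x * (peak / m) if m > 0 else x


def _ramp(x: np.ndarray, fs: int, ramp_ms: float = RAMP_MS) -> np.ndarray:
    n = min(_ms(ramp_ms, fs), len(x) // 2)
    if n > 0:
        env = np.ones(len(x))
        env[:n] = np.linspace(0.0, 1.0, n, endpoint=False)
        env[-n:] = np.linspace(1.0, 0.0, n)
        x = x * env
    return x


def _vowel(n: int, profile: SpeakerProfile, fs: int) -> np.ndarray:
    src = _glottal_source(n, profile.f0, fs)
    y = _resonator(src, profile.vowel_f1, 90.0, fs)
    y += 0.4 * _resonator(src, 1200.0, 120.0, fs)
    # no voice bar: vowel energy is confined to the F1/F2 region so the
    # 60-500 Hz band stays exclusive to nasal murmurs (class-segregated
    # spectra are the design goal of this generator)
    sos = signal.butter(2, 400.0, "highpass", fs=fs, output="sos")
    return _normalize(signal.sosfilt(sos, y), VOWEL_AMP)


def _nasal(n: int, profile: SpeakerProfile, fs: int) -> np.ndarray:
    src = _glottal_source(n, profile.f0, fs)
    y = _resonator(src, 250.0, 100.0, fs)
    sos = signal.butter(2, 450.0, "lowpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, y)
    return _normalize(y, NASAL_AMP)


def _noise_band(n: int, lo: float, hi: float, amp: float, fs: int,
                rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(4, [lo, hi], "bandpass", fs=fs, output="sos")
    return _normalize(signal.sosfilt(sos, x), amp)


def _burst(n: int, fs: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = signal.butter(4, 2500.0, "highpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, x)
    # sharp attack, exponential decay — a release transient, not steady noise
    decay = np.exp(-np.arange(n) / (0.25 * n + 1))
    return _normalize(y * decay, BURST_AMP)


# ------------------------------------------------------------ synth_phone

def _consonant_span_ms(label: str, profile: SpeakerProfile) -> float:
    """Duration (ms) from consonant onset to vowel onset for this consonant."""
    cls = PHONES[label].sound_class
    s = profile.rate_scale
    if cls is SoundClass.STOP:
        return (DUR["burst"] + DUR["vot"]) * s
    if cls is SoundClass.AFFRICATE:
        return (DUR["burst"] + DUR["affric"]) * s
    if cls is SoundClass.FRICATIVE:
        return DUR["fric"] * s
    if cls is SoundClass.NASAL:
        return DUR["nasal"] * s
    raise SynthesisError(f"not a consonant: {label!r}")


def _render_consonant(label: str, profile: SpeakerProfile, fs: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Samples of the consonant's acoustic event, starting at its onset."""
    cls = PHONES[label].sound_class
    s = profile.rate_scale
    if cls is SoundClass.STOP:
        y = _burst(_ms(DUR["burst"] * s, fs), fs, rng)
        return np.concatenate([y, np.zeros(_ms(DUR["vot"] * s, fs))])
    if cls is SoundClass.AFFRICATE:
        b = _burst(_ms(DUR["burst"] * s, fs), fs, rng)
        lo, hi, amp = FRIC_BANDS[label]
        f = _ramp(_noise_band(_ms(DUR["affric"] * s, fs), lo, hi, amp, fs, rng), fs)
        return np.concatenate([b, f])
    if cls is SoundClass.FRICATIVE:
        lo, hi, amp = FRIC_BANDS[label]
        return _ramp(_noise_band(_ms(DUR["fric"] * s, fs), lo, hi, amp, fs, rng), fs)
    if cls is SoundClass.NASAL:
        return _ramp(_nasal(_ms(DUR["nasal"] * s, fs), profile, fs), fs)
    raise SynthesisError(f"not a consonant: {label!r}")


def synth_phone(label: str, duration_ms: float, profile: SpeakerProfile = DEFAULT_PROFILE,
                sample_rate: int = DEFAULT_SAMPLE_RATE, seed: int = 0) -> Waveform:
    """Synthesize a single phone of the requested duration.

    Stops render as 2/3 closure silence followed by the release burst;
    affricates as burst plus frication filling the remainder.
    """
    if label not in PHONES:
        raise SynthesisError(f"unknown phone label {label!r}")
    if duration_ms <= 0:
        raise SynthesisError("duration must be positive")
    fs = sample_rate
    n = _ms(duration_ms, fs)
    rng = np.random.default_rng(seed)
    cls = PHONES[label].sound_class
    if cls is SoundClass.VOWEL:
        y = _ramp(_vowel(n, profile, fs), fs)
    elif cls is SoundClass.NASAL:
        y = _ramp(_nasal(n, profile, fs), fs)
    elif cls is SoundClass.STOP:
        closure = int(round(2 * n / 3))
        y = np.concatenate([np.zeros(closure), _burst(n - closure, fs, rng)])
    elif cls is SoundClass.AFFRICATE:
        nb = min(_ms(DUR["burst"], fs), n // 2)
        lo, hi, amp = FRIC_BANDS[label]
        y = np.concatenate(
            [_burst(nb, fs, rng), _ramp(_noise_band(n - nb, lo, hi, amp, fs, rng), fs)]
        )
    else:
        lo, hi, amp = FRIC_BANDS[label]
        y = _ramp(_noise_band(n, lo, hi, amp, fs, rng), fs)
    return Waveform(np.clip(y, -1.0, 1.0), fs)


# --------------------------------------------------------- synth_sequence

def synth_sequence(stim: Stimulus, profile: SpeakerProfile = DEFAULT_PROFILE,
                   isi_plan: Sequence[float] | None = None,
                   sample_rate: int = DEFAULT_SAMPLE_RATE,
                   seed: int | None = None) -> TrialAudio:
    """Synthesize one trial and record exact ground-truth landmarks.

    If ``isi_plan`` is given (stim.n − 1 onset-to-onset intervals, ms) the
    ground-truth consonant onsets honour it exactly; otherwise default
    durations plus a 60 ms (rate-scaled) inter-syllable gap are used.
    """
    fs = sample_rate
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    s = profile.rate_scale
    vowel_ms = DUR["vowel"] * s

    spans = [_consonant_span_ms(c, profile) for c in stim.syllables]
    if isi_plan is not None:
        isi_plan = list(isi_plan)
        if len(isi_plan) != stim.n - 1:
            raise SynthesisError(
                f"isi_plan needs {stim.n - 1} entries, got {len(isi_plan)}"
            )
        for k, isi in enumerate(isi_plan):
            need = spans[k] + vowel_ms + MIN_GAP_MS
            if isi < need:
                raise SynthesisError(
                    f"isi_plan[{k}]={isi} ms shorter than syllable span {need:.1f} ms"
                )

    c_on = [LEAD_MS]
    for k in range(stim.n - 1):
        step = isi_plan[k] if isi_plan is not None else (
            spans[k] + vowel_ms + DUR["gap"] * s
        )
        c_on.append(c_on[-1] + step)
    v_on = [c + sp for c, sp in zip(c_on, spans)]
    v_off = [v + vowel_ms for v in v_on]

    total = _ms(v_off[-1] + TAIL_MS, fs)
    y = np.zeros(total)
    for k, c in enumerate(stim.syllables):
        seg = _render_consonant(c, profile, fs, rng)
        i0 = _ms(c_on[k], fs)
        y[i0:i0 + len(seg)] += seg[: total - i0]
        vow = _ramp(_vowel(_ms(vowel_ms, fs), profile, fs), fs)
        j0 = _ms(v_on[k], fs)
        y[j0:j0 + len(vow)] += vow[: total - j0]

    peak = np.max(np.abs(y))
    if peak > 0.98:
        y *= 0.98 / peak

    truth = GroundTruthLandmarks(c_on, v_on, v_off)
    truth.check(1000.0 * total / fs)
    return TrialAudio(Waveform(y, fs), truth, stim, profile)


def add_noise(trial: TrialAudio, snr_db: float, seed: int) -> TrialAudio:
    """Add white noise at ``snr_db`` (20·log10 of speech RMS over noise RMS)."""
    if not np.isfinite(snr_db):
        raise ValueError("snr must be finite")
    x = trial.waveform.samples
    rng = np.random.default_rng(seed)
    speech_rms = float(np.sqrt(np.mean(x**2)))
    noise = rng.standard_normal(len(x))
    noise *= (speech_rms / 10 ** (snr_db / 20.0)) / np.sqrt(np.mean(noise**2))
    wf = Waveform(x + noise, trial.waveform.sample_rate)
    return TrialAudio(wf, trial.truth, trial.stimulus, trial.profile,
                      trial.artifacts + [("addedNoiseSNRdB", snr_db)])


def inject_double_release(trial: TrialAudio, k: int, gap_ms: float,
                          seed: int = 1234) -> TrialAudio:
    """Insert a second, comparable-amplitude release burst ``gap_ms`` after
    syllable ``k``'s true burst (1-based; consonant must be stop/affricate)."""
    c = trial.stimulus.syllables[k - 1]
    cls = PHONES[c].sound_class
    if cls not in (SoundClass.STOP, SoundClass.AFFRICATE):
        raise SynthesisError(f"syllable {k} consonant {c!r} is not an obstruent stop/affricate")
    if gap_ms < MIN_GAP_MS:
        raise SynthesisError("gap must be >= 10 ms")
    fs = trial.waveform.sample_rate
    burst_ms = DUR["burst"] * trial.profile.rate_scale
    t0 = trial.truth.c_on[k - 1] + gap_ms
    if t0 + burst_ms > trial.truth.v_on[k - 1]:
        raise SynthesisError("second release would overlap the vowel onset")
    rng = np.random.default_rng(seed)
    seg = _burst(_ms(burst_ms, fs), fs, rng)
    y = trial.waveform.samples.copy()
    i0 = _ms(t0, fs)
    y[i0:i0 + len(seg)] += seg[: len(y) - i0]
    wf = Waveform(np.clip(y, -1.0, 1.0), fs)
    return TrialAudio(wf, trial.truth, trial.stimulus, trial.profile,
                      trial.artifacts + [("doubleRelease", k, gap_ms)])


# ------------------------------------------------------------------- I/O

def write_wav(path, w: Waveform) -> None:
    """PCM 16-bit WAV."""
    x = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.sample_rate, (x * 32767).astype(np.int16))


def read_wav(path) -> Waveform:
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    return Waveform(data, int(fs))


def write_truth_table(path, trials: list[tuple[str, GroundTruthLandmarks]]) -> None:
    """Tab-separated ground truth: trial, syllable, cOn_ms, vOn_ms, vOff_ms."""
    with open(path, "w") as fh:
        fh.write("trial\tsyllable\tcOn_ms\tvOn_ms\tvOff_ms\n")
        for trial_id, truth in trials:
            for k in range(truth.n):
                fh.write(f"{trial_id}\t{k + 1}\t{truth.c_on[k]:.3f}\t"
                         f"{truth.v_on[k]:.3f}\t{truth.v_off[k]:.3f}\n")


def write_textgrid(path, truth: GroundTruthLandmarks, stim: Stimulus,
                   duration_ms: float) -> None:
    """Praat long-format TextGrid: one syllable interval tier plus cOn/vOn/vOff
    point tiers."""
    dur = duration_ms / 1000.0
    tiers: list[str] = []

    intervals = []
    edges = [0.0] + [t / 1000.0 for c, v, o in
                     zip(truth.c_on, truth.v_on, truth.v_off) for t in (c, o)] + [dur]
    labels = []
    for k in range(truth.n):
        labels += ["", stim.syllables[k] + "a"]
    labels += [""]
    for i in range(len(edges) - 1):
        intervals.append((edges[i], edges[i + 1], labels[i]))
    body = [f'        class = "IntervalTier"', f'        name = "syllable"',
            f"        xmin = 0", f"        xmax = {dur:.6f}",
            f"        intervals: size = {len(intervals)}"]
    for i, (a, b, lab) in enumerate(intervals, 1):
        body += [f"        intervals [{i}]:", f"            xmin = {a:.6f}",
                 f"            xmax = {b:.6f}", f'            text = "{lab}"']
    tiers.append("\n".join(body))

    for name, times in (("cOn", truth.c_on), ("vOn", truth.v_on), ("vOff", truth.v_off)):
        body = [f'        class = "TextTier"', f'        name = "{name}"',
                f"        xmin = 0", f"        xmax = {dur:.6f}",
                f"        points: size = {len(times)}"]
        for i, t in enumerate(times, 1):
            body += [f"        points [{i}]:", f"            number = {t / 1000.0:.6f}",
                     f'            mark = "{i}"']
        tiers.append("\n".join(body))

    with open(path, "w") as fh:
        fh.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
        fh.write(f"xmin = 0\nxmax = {dur:.6f}\ntiers? <exists>\n")
        fh.write(f"size = {len(tiers)}\nitem []:\n")
        for i, tier in enumerate(tiers, 1):
            fh.write(f"    item [{i}]:\n{tier}\n")


def read_textgrid_points(path) -> dict[str, list[float]]:
    """Read the point tiers of a TextGrid written by :func:`write_textgrid`;
    returns tier name -> point times in ms."""
    out: dict[str, list[float]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("name ="):
                name = line.split('"')[1]
            elif line.startswith("number =") and name is not None:
                out.setdefault(name, []).append(1000.0 * float(line.split("=")[1]))
    return {k: v for k, v in out.items() if k in ("cOn", "vOn", "vOff")}
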