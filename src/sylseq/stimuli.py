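"""Stimulus inventory and balanced experimental schedule.

The task is rapid production of consonant-vowel (CV) syllable sequences.
Thirty stimuli are organised as six series, each series nested by length:
the length-k stimulus of a series is the first k syllables of its length-5
stimulus.  A session is five runs of sixty trials; within a run every
stimulus appears exactly twice, so every sequence length gets 12 trials per
run and 60 over the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

VOWEL = "a"

#: consonant labels in the inventory (the vowel is always /a/)
CONSONANTS = ("m", "n", "k", "d", "t", "j", "ch", "h", "v", "z", "th", "sh")


class SoundClass(str, Enum):
    VOWEL = "vowel"
    NASAL = "nasal"
    STOP = "stop"
    AFFRICATE = "affricate"
    FRICATIVE = "fricative"


class Place(str, Enum):
    BILABIAL = "bilabial"
    LABIODENTAL = "labiodental"
    DENTAL = "dental"
    ALVEOLAR = "alveolar"
    POSTALVEOLAR = "postalveolar"
    VELAR = "velar"
    GLOTTAL = "glottal"


@dataclass(frozen=True)
class Phone:
    """A phone with the articulatory features used for error classification."""

    label: str
    sound_class: SoundClass
    voiced: bool
    place: Place


#: fixed phone inventory: label -> Phone (features follow standard
#: American-English descriptions; "th" is the voiceless dental fricative,
#: "j" the voiced postalveolar affricate)
PHONES: dict[str, Phone] = {
    p.label: p
    for p in [
        Phone("a", SoundClass.VOWEL, True, Place.GLOTTAL),
        Phone("m", SoundClass.NASAL, True, Place.BILABIAL),
        Phone("n", SoundClass.NASAL, True, Place.ALVEOLAR),
        Phone("k", SoundClass.STOP, False, Place.VELAR),
        Phone("d", SoundClass.STOP, True, Place.ALVEOLAR),
        Phone("t", SoundClass.STOP, False, Place.ALVEOLAR),
        Phone("j", SoundClass.AFFRICATE, True, Place.POSTALVEOLAR),
        Phone("ch", SoundClass.AFFRICATE, False, Place.POSTALVEOLAR),
        Phone("h", SoundClass.FRICATIVE, False, Place.GLOTTAL),
        Phone("v", SoundClass.FRICATIVE, True, Place.LABIODENTAL),
        Phone("z", SoundClass.FRICATIVE, True, Place.ALVEOLAR),
        Phone("th", SoundClass.FRICATIVE, False, Place.DENTAL),
        Phone("sh", SoundClass.FRICATIVE, False, Place.POSTALVEOLAR),
    ]
}

#: full-length (n=5) consonant strings of the six stimulus series
_SERIES_FULL: dict[int, tuple[str, ...]] = {
    1: ("m", "k", "n", "h", "d"),
    2: ("d", "h", "n", "k", "m"),
    3: ("t", "m", "k", "h", "n"),
    4: ("j", "ch", "v", "z", "th"),
    5: ("v", "z", "th", "sh", "ch"),
    6: ("th", "sh", "z", "v", "ch"),
}

N_SERIES = 6
MAX_LENGTH = 5
TRIALS_PER_RUN = 60
N_RUNS = 5


@dataclass(frozen=True)
class Stimulus:
    """A CV-sequence stimulus: ``series_id``, length ``n`` and its consonants."""

    series_id: int
    n: int
    syllables: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.syllables) != self.n:
            raise ValueError("syllable count must equal n")

    @property
    def text(self) -> str:
        """Orthographic form, e.g. ``'ma ka na'``."""
        return " ".join(c + VOWEL for c in self.syllables)

    @property
    def key(self) -> str:
        return f"s{self.series_id}n{self.n}"


def build_stimulus_table() -> list[Stimulus]:
    """Return the 30 stimuli (6 series x lengths 1-5), series-ordered.

    Stimuli are nested: the length-k stimulus of a series is the length-(k+1)
    stimulus truncated.
    """
    table = []
    for sid in range(1, N_SERIES + 1):
        full = _SERIES_FULL[sid]
        for n in range(1, MAX_LENGTH + 1):
            table.append(Stimulus(sid, n, full[:n]))
    return table


def stimulus_by_key(series_id: int, n: int) -> Stimulus:
    return Stimulus(series_id, n, _SERIES_FULL[series_id][:n])


@dataclass(frozen=True)
class Trial:
    run: int  # 1-5
    trial: int  # 1-60 within run
    stimulus: Stimulus


@dataclass
class Schedule:
    """Ordered list of (run, trial, stimulus) covering 5 x 60 trials."""

    trials: list[Trial]
    seed: int
    #: presentation timing metadata (ms); recorded only, never executed
    alerter_ms: int = 750
    display_ms: int = 2000

    def run_trials(self, run: int) -> list[Trial]:
        return [t for t in self.trials if t.run == run]


def build_schedule(seed: int, include_practice: bool = False) -> Schedule:
    """Build the balanced 300-trial session.

    Each run is a seeded permutation of two copies of every stimulus, so each
    stimulus occurs exactly twice per run (10 times overall) and each length
    exactly 12 times per run (60 overall).  ``include_practice`` prepends a
    familiarization block of 120 trials (4 copies of each stimulus, shuffled)
    marked as run 0; analysis stages ignore run 0.
    """
    rng = np.random.default_rng(seed)
    table = build_stimulus_table()
    trials: list[Trial] = []
    if include_practice:
        block = table * 4
        order = rng.permutation(len(block))
        trials.extend(Trial(0, i + 1, block[j]) for i, j in enumerate(order))
    for run in range(1, N_RUNS + 1):
        block = table * 2
        order = rng.permutation(len(block))
        trials.extend(Trial(run, i + 1, block[j]) for i, j in enumerate(order))
    return Schedule(trials=trials, seed=seed)


def validate_schedule(s: Schedule) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Checks: total trial count, per-run trial count, per-run per-stimulus
    balance (2), overall per-stimulus balance (10), and per-length totals
    (60 overall, 12 per run).  The practice block (run 0) is excluded.
    """
    violations: list[str] = []
    main = [t for t in s.trials if t.run != 0]
    if len(main) != N_RUNS * TRIALS_PER_RUN:
        violations.append(f"total trial count {len(main)} != {N_RUNS * TRIALS_PER_RUN}")
    keys = [t.stimulus.key for t in main]
    for key in (st.key for st in build_stimulus_table()):
        c = keys.count(key)
        if c != 10:
            violations.append(f"stimulus {key} appears {c} times overall, expected 10")
    for run in range(1, N_RUNS + 1):
        rt = [t for t in main if t.run == run]
        if len(rt) != TRIALS_PER_RUN:
            violations.append(f"run {run} has {len(rt)} trials, expected {TRIALS_PER_RUN}")
        rkeys = [t.stimulus.key for t in rt]
        for key in set(rkeys):
            c = rkeys.count(key)
            if c != 2:
                violations.append(f"run {run}: stimulus {key} appears {c} times, expected 2")
        for key in (st.key for st in build_stimulus_table()):
            if key not in rkeys:
                violations.append(f"run {run}: stimulus {key} appears 0 times, expected 2")
        for n in range(1, MAX_LENGTH + 1):
            c = sum(1 for t in rt if t.stimulus.n == n)
            if c != 12:
                violations.append(f"run {run}: length {n} has {c} trials, expected 12")
    for n in range(1, MAX_LENGTH + 1):
        c = sum(1 for t in main if t.stimulus.n == n)
        if c != 60:
            violations.append(f"length {n} has {c} trials overall, expected 60")
    # de-duplicate while keeping order
    seen: set[str] = set()
    out = []
    for v in violations:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


MANIFEST_HEADER = "run\ttrial\tseries\tlength\tsyllables"


def write_manifest(s: Schedule, path) -> None:
    """Serialize a schedule as a tab-separated manifest."""
    with open(path, "w") as fh:
        fh.write(MANIFEST_HEADER + "\n")
        for t in s.trials:
            fh.write(
                f"{t.run}\t{t.trial}\t{t.stimulus.series_id}\t{t.stimulus.n}\t"
                f"{' '.join(t.stimulus.syllables)}\n"
            )


def read_manifest(path) -> Schedule:
    trials = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != MANIFEST_HEADER:
            raise ValueError(f"unrecognized manifest header: {header!r}")
        for line in fh:
            run, trial, series, n, syls = line.rstrip("\n").split("\t")
            trials.append(
                Trial(int(run), int(trial), Stimulus(int(series), int(n), tuple(syls.split())))
            )
    return Schedule(trials=trials, seed=-1)


def manifest_text(s: Schedule) -> str:
    lines = [MANIFEST_HEADER]
    for t in s.trials:
        lines.append(
            f"{t.run}\t{t.trial}\t{t.stimulus.series_id}\t{t.stimulus.n}\t"
            f"{' '.join(t.stimulus.syllables)}"
        )
    return "\n".join(lines) + "\n"
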