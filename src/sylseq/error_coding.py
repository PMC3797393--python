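"""Symbolic speech-error classification and error-rate tabulation.

Produced syllable strings (perceptual transcripts, or stand-ins for them)
are scored against the target sequence with a deterministic rule cascade
covering six criteria: (1) omission / insertion / transposition /
repetition, (2) initial-syllable perseveration of the previous target,
(3) consonant voicing / manner / place substitutions, (4) syllable
segmentation (pausing between syllables), (5) self-correction, and
(6) unintelligible productions.  A trial counts as an error trial if any
code fires; rates are tabulated per speaker and cell (sequence length or
run) as errors/total and arcsine-transformed, asin(sqrt(p)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .stimuli import PHONES, Stimulus

PAUSE = "PAUSE"
REPAIR = "REPAIR"
UNK = "UNK"
_MARKERS = {PAUSE, REPAIR, UNK}


class ErrorCategory(str, Enum):
    OMISSION = "omission"
    INSERTION = "insertion"
    TRANSPOSITION = "transposition"
    REPETITION = "repetition"
    INITIAL_PERSEVERATION = "initialPerseveration"
    VOICING = "voicingError"
    MANNER = "mannerError"
    PLACE = "placeError"
    SEGMENTATION = "segmentation"
    SELF_CORRECTION = "selfCorrection"
    UNINTELLIGIBLE = "unintelligible"


@dataclass(frozen=True)
class ErrorCode:
    category: ErrorCategory
    position: int | None = None   # 1-based syllable index where applicable


@dataclass
class ResponseTranscript:
    trial_ref: str
    produced: list[str]            # consonant labels and/or markers
    previous_target: Stimulus | None = None


def _align(target: list[str], produced: list[str]) -> list[tuple[str | None, str | None]]:
    """Minimum-edit-distance alignment as (target, produced) columns.

    Tie-break order diagonal > deletion > insertion, which yields the
    leftmost-edit alignment under the reversed traceback used here.
    """
    nt, np_ = len(target), len(produced)
    dist = [[0] * (np_ + 1) for _ in range(nt + 1)]
    for i in range(nt + 1):
        dist[i][0] = i
    for j in range(np_ + 1):
        dist[0][j] = j
    for i in range(1, nt + 1):
        for j in range(1, np_ + 1):
            sub = dist[i - 1][j - 1] + (target[i - 1] != produced[j - 1])
            dist[i][j] = min(sub, dist[i - 1][j] + 1, dist[i][j - 1] + 1)
    cols: list[tuple[str | None, str | None]] = []
    i, j = nt, np_
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i][j] == dist[i - 1][j - 1] + (target[i - 1] != produced[j - 1]):
            cols.append((target[i - 1], produced[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and dist[i][j] == dist[i - 1][j] + 1:
            cols.append((target[i - 1], None))
            i -= 1
        else:
            cols.append((None, produced[j - 1]))
            j -= 1
    return cols[::-1]


def _feature_codes(t: str, p: str, pos: int) -> list[ErrorCode]:
    """One code per articulatory feature on which the consonants differ."""
    pt, pp = PHONES[t], PHONES[p]
    out = []
    if pt.voiced != pp.voiced:
        out.append(ErrorCode(ErrorCategory.VOICING, pos))
    if pt.sound_class != pp.sound_class:
        out.append(ErrorCode(ErrorCategory.MANNER, pos))
    if pt.place != pp.place:
        out.append(ErrorCode(ErrorCategory.PLACE, pos))
    return out


def classify_errors(target: Stimulus, resp: ResponseTranscript) -> list[ErrorCode]:
    """Classify one production against its target.

    Cascade: unintelligible short-circuits; self-correction and
    segmentation markers are coded and stripped; the remaining consonant
    string is aligned to the target by minimum edit distance, with
    adjacent exchanges coded as transpositions (before substitutions) and
    inserted duplicates of the preceding syllable as repetitions;
    substitutions emit one code per differing feature; finally the initial
    syllable is checked for perseveration of the previous target.
    """
    if not resp.produced:
        raise ValueError("empty transcript")
    if any(s == UNK for s in resp.produced):
        return [ErrorCode(ErrorCategory.UNINTELLIGIBLE)]
    codes: list[ErrorCode] = []
    if any(s == REPAIR for s in resp.produced):
        codes.append(ErrorCode(ErrorCategory.SELF_CORRECTION,
                               resp.produced.index(REPAIR)))
    for i, s in enumerate(resp.produced):
        if s == PAUSE and 0 < i < len(resp.produced) - 1:
            codes.append(ErrorCode(ErrorCategory.SEGMENTATION, i))
    produced = [s for s in resp.produced if s not in _MARKERS]
    for s in produced:
        if s not in PHONES:
            raise ValueError(f"unknown syllable label {s!r}")

    tgt = list(target.syllables)
    cols = _align(tgt, produced)

    # positions: index into the target for substitution/deletion columns
    tpos = 0
    annotated = []
    for t, p in cols:
        if t is not None:
            tpos += 1
        annotated.append((t, p, tpos))

    i = 0
    while i < len(annotated):
        t, p, pos = annotated[i]
        if t is not None and p is not None and t != p:
            # adjacent exchange beats a substitution pair
            if (i + 1 < len(annotated)
                    and annotated[i + 1][0] is not None
                    and annotated[i + 1][1] is not None
                    and annotated[i + 1][0] == p and annotated[i + 1][1] == t):
                codes.append(ErrorCode(ErrorCategory.TRANSPOSITION, pos))
                i += 2
                continue
            codes.extend(_feature_codes(t, p, pos))
        elif t is not None and p is None:
            codes.append(ErrorCode(ErrorCategory.OMISSION, pos))
        elif t is None and p is not None:
            # an inserted copy of the neighbouring produced syllable is a
            # repetition, wherever the aligner placed the extra column
            prev = annotated[i - 1][1] if i > 0 else None
            nxt = annotated[i + 1][1] if i + 1 < len(annotated) else None
            cat = (ErrorCategory.REPETITION if p in (prev, nxt)
                   else ErrorCategory.INSERTION)
            codes.append(ErrorCode(cat, pos))
        i += 1

    if (resp.previous_target is not None and produced
            and produced[0] == resp.previous_target.syllables[0]
            and produced[0] != tgt[0]):
        codes.append(ErrorCode(ErrorCategory.INITIAL_PERSEVERATION, 1))
    return codes


def trial_is_error(codes: list[ErrorCode]) -> bool:
    """A trial is an error trial iff at least one code fired (counted once)."""
    return bool(codes)


def arcsine(p: float) -> float:
    """Variance-stabilising transform asin(sqrt(p)), radians."""
    return math.asin(math.sqrt(p))


@dataclass
class RateRecord:
    speaker: str
    cell: int                    # sequence length 1-5 or run 1-5
    error_trials: int
    total_trials: int
    rate: float | None
    arcsine_rate: float | None


def tabulate_rates(trials: pd.DataFrame, group_by: str) -> list[RateRecord]:
    """Per-speaker error rates by ``group_by`` ("length" or "run").

    ``trials`` needs columns speaker, length, run, is_error, with QC-flagged
    (ambiguous) trials already removed.  rate = error trials / total trials;
    a full session gives 60 trials per cell.
    """
    if group_by not in ("length", "run"):
        raise ValueError("group_by must be 'length' or 'run'")
    out = []
    for (spk, cell), df in trials.groupby(["speaker", group_by], sort=True):
        total = len(df)
        errs = int(df["is_error"].sum())
        if total == 0:
            out.append(RateRecord(str(spk), int(cell), 0, 0, None, None))
        else:
            r = errs / total
            out.append(RateRecord(str(spk), int(cell), errs, total, r, arcsine(r)))
    return out


def rates_frame(records: list[RateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"speaker": r.speaker, "cell": r.cell, "error_trials": r.error_trials,
          "total_trials": r.total_trials, "rate": r.rate,
          "arcsine_rate": r.arcsine_rate} for r in records]
    )
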