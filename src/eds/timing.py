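"""Typing-time estimation for the regular and error-aware keyboards.

For each sentence two recordings exist: the error-aware one (T1 task,
mistypes left in place and retyped) and the regular-control one (T2
task, mistypes undone with backspace).  With

    t1, t2   first-to-last key-press span in each recording,
    d        edit distance between the typed and the intended sentence,
    k1       mistypes the detector flagged (auto-deleted, no backspace),
    k2       correct presses falsely flagged (must be retyped),
    b_avg    mean time of a backspace press, l_avg of a letter press,

the totals are

    T2 = t2 + d * b_avg
    T1 = t1 + (d - k1) * b_avg + k2 * l_avg

and the gain of the error-aware keyboard is T2 - T1 seconds, or
100 * (T2 - T1) / T2 percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .core_io import TypingSession
from .preprocessing import ERRONEOUS, label_key_events


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit insert/delete/substitute costs."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def estimate_regular_time(t2: float, d: int, b_avg: float) -> float:
    """T2 = t2 + d * b_avg: residual mistypes each cost one backspace."""
    if t2 < 0 or d < 0 or b_avg < 0:
        raise ValueError("times and counts must be non-negative")
    return t2 + d * b_avg


def estimate_error_aware_time(t1: float, d: int, k1: int, k2: int,
                              b_avg: float, l_avg: float) -> float:
    """T1 = t1 + (d - k1) * b_avg + k2 * l_avg.

    Each detected mistype saves its backspace; each false alarm costs
    one letter press to retype the deleted character.
    """
    if k1 > d:
        raise ValueError("more detected errors than errors")
    if min(t1, d, k1, k2, b_avg, l_avg) < 0:
        raise ValueError("times and counts must be non-negative")
    return t1 + (d - k1) * b_avg + k2 * l_avg


# ---------------------------------------------------------------------------
# Press-time estimators
# ---------------------------------------------------------------------------

def press_time_estimates(control_sessions: list[TypingSession]
                         ) -> tuple[float, float]:
    """(b_avg, l_avg) from regular-control recordings.

    Estimated as the mean inter-press interval ending in a backspace
    (resp. letter) registration, pooled over the subject's control
    sessions.  The first press of a session has no preceding interval
    and is skipped.
    """
    back: list[float] = []
    letter: list[float] = []
    for session in control_sessions:
        events = session.events
        for prev, cur in zip(events, events[1:]):
            interval = cur.onset - prev.onset
            (back if cur.is_backspace else letter).append(interval)
    if not letter:
        raise ValueError("control sessions contain no letter intervals")
    l_avg = float(np.mean(letter))
    b_avg = float(np.mean(back)) if back else l_avg
    return b_avg, l_avg


# ---------------------------------------------------------------------------
# Per-sentence report
# ---------------------------------------------------------------------------

@dataclass
class TimingReport:
    sentence_id: str
    t1: float
    t2: float
    d: int
    k1: int
    k2: int
    b_avg: float
    l_avg: float
    T1: float
    T2: float
    gain_seconds: float
    gain_percent: float


def _span(session: TypingSession) -> float:
    if len(session.events) < 2:
        raise ValueError("session needs at least two presses")
    return session.events[-1].onset - session.events[0].onset


def timing_report(error_aware: TypingSession,
                  regular: TypingSession,
                  predictions_by_index: dict[int, str],
                  b_avg: float, l_avg: float) -> TimingReport:
    """Assemble the per-sentence report from LOSO per-press predictions.

    ``predictions_by_index`` maps the error-aware session's letter-event
    indices to predicted labels (presses without a prediction, e.g.
    boundary-dropped epochs, count as predicted correct).  k1 counts
    true mistypes flagged erroneous, k2 correct presses flagged
    erroneous; d is the edit distance of the typed vs intended text.
    """
    if error_aware.intended != regular.intended:
        raise ValueError("unmatched sessions: intended sentences differ")

    t1 = _span(error_aware)
    t2 = _span(regular)
    d = edit_distance(error_aware.typed, error_aware.intended)
    d2 = edit_distance(regular.committed, regular.intended)

    true_labels = label_key_events(error_aware.intended, error_aware.typed)
    letter_events = [e for e in error_aware.events if not e.is_backspace]
    k1 = k2 = 0
    for event, truth in zip(letter_events, true_labels):
        pred = predictions_by_index.get(event.index)
        if pred != ERRONEOUS:
            continue
        if truth == ERRONEOUS:
            k1 += 1
        else:
            k2 += 1
    k1 = min(k1, d)  # guard: d is an edit distance, flags are per press

    T1 = estimate_error_aware_time(t1, d, k1, k2, b_avg, l_avg)
    T2 = estimate_regular_time(t2, d2, b_avg)
    return TimingReport(
        sentence_id=error_aware.sentence_id, t1=t1, t2=t2, d=d, k1=k1, k2=k2,
        b_avg=b_avg, l_avg=l_avg, T1=T1, T2=T2,
        gain_seconds=T2 - T1, gain_percent=100.0 * (T2 - T1) / T2)


def subject_timing(error_aware_sessions: list[TypingSession],
                   regular_sessions: list[TypingSession],
                   folds_by_index: dict[str, dict[int, str]],
                   ) -> list[TimingReport]:
    """Per-sentence timing reports for one subject.

    ``folds_by_index`` maps sentence_id to the LOSO per-press prediction
    dict; press-time estimates come from the control recordings.
    """
    b_avg, l_avg = press_time_estimates(regular_sessions)
    regular_by_id = {s.sentence_id: s for s in regular_sessions}
    reports = []
    for session in error_aware_sessions:
        reports.append(timing_report(
            session, regular_by_id[session.sentence_id],
            folds_by_index.get(session.sentence_id, {}), b_avg, l_avg))
    return reports
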