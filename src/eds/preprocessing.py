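"""Band-pass filtering, event-locked epoching and epoch labelling.

Error-related potentials live in the low-frequency EEG bands, so the raw
recording is zero-phase band-pass filtered to 1-16 Hz before epoching.
Epochs span [-0.2, 0.5) s around each letter-key registration, on both
the EEG and the gaze stream; the gaze trajectory inside the window is
summarized by its accumulated (running path-length) distance series.

The label of an epoch follows the retry protocol: scanning the typed
sequence left to right against the intended sentence, a press that
matches the next outstanding intended character is *correct* and
consumes it; any other press is *erroneous* and consumes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core_io import EEGRecording, GazeRecording, KeyEvent, TypingSession

logger = logging.getLogger(__name__)

CORRECT = "correct"
ERRONEOUS = "erroneous"


class ProtocolViolation(ValueError):
    """Typed sequence is incompatible with the retry protocol."""


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass_filter(eeg: EEGRecording, low: float = 1.0,
                    high: float = 16.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied forward and backward.

    The two-pass application squares the magnitude response (effective
    order ``2*order``) and cancels the phase, so event-locked latencies
    are preserved.
    """
    nyquist = eeg.rate / 2.0
    if high >= nyquist:
        raise ValueError("band exceeds Nyquist")
    if not 0 < low < high:
        raise ValueError("invalid band")
    sos = butter(order, [low, high], btype="bandpass", fs=eeg.rate,
                 output="sos")
    filtered = sosfiltfilt(sos, eeg.samples, axis=1)
    return EEGRecording(samples=filtered, rate=eeg.rate,
                        channel_names=list(eeg.channel_names),
                        start_time=eeg.start_time)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

@dataclass
class LabeledEpoch:
    """Dual-modality segment around one key registration.

    ``eeg`` holds floor(0.7*rate) samples aligned so that index
    ``n_pre = floor(0.2*rate)`` is the sample at the onset; the gaze
    arrays are resampled onto the analogous 30 Hz grid.  ``distance`` is
    the accumulated gaze path length, zero at the first sample.
    """

    eeg: np.ndarray          # channels x n_samples
    eeg_rate: float
    gaze_t: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    gaze_rate: float
    distance: np.ndarray
    event: KeyEvent
    label: str | None = None

    @property
    def n_pre(self) -> int:
        return int(np.floor(0.2 * self.eeg_rate))


def accumulated_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Running length of the on-screen gaze trajectory.

    ``s[0] = 0`` and ``s[i] = s[i-1] + ||(x,y)[i] - (x,y)[i-1]||``; the
    series is non-negative and non-decreasing by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        return np.zeros(0)
    steps = np.hypot(np.diff(x), np.diff(y))
    return np.concatenate([[0.0], np.cumsum(steps)])


def _window_samples(rate: float, window: tuple[float, float]) -> tuple[int, int]:
    """(n_pre, n_total) under the half-open [onset+a, onset+b) convention."""
    a, b = window
    n_total = int(np.floor((b - a) * rate))
    n_pre = int(np.floor(-a * rate))
    return n_pre, n_total


def _resample_gaze(gaze: GazeRecording, grid: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray] | None:
    """Linearly interpolate gaze onto the epoch grid.

    Returns None (drop the epoch) when the grid leaves the recording or
    crosses a gap longer than two nominal sample intervals.
    """
    if grid[0] < gaze.t[0] or grid[-1] > gaze.t[-1]:
        return None
    lo = np.searchsorted(gaze.t, grid[0], side="right") - 1
    hi = np.searchsorted(gaze.t, grid[-1], side="left") + 1
    gaps = np.diff(gaze.t[lo:hi])
    if gaps.size and gaps.max() > 3.0 / gaze.rate:
        return None
    return (np.interp(grid, gaze.t, gaze.x),
            np.interp(grid, gaze.t, gaze.y))


def epochize(session: TypingSession,
             window: tuple[float, float] = (-0.2, 0.5)) -> list[LabeledEpoch]:
    """Cut one unlabelled epoch per letter-key registration.

    Backspace presses are excluded; epochs whose window falls outside
    either recording are dropped with a warning.
    """
    eeg = session.eeg
    n_pre, n_total = _window_samples(eeg.rate, window)
    g_pre, g_total = _window_samples(session.gaze.rate, window)

    epochs: list[LabeledEpoch] = []
    for event in session.events:
        if event.is_backspace:
            continue
        onset_idx = int(np.round((event.onset - eeg.start_time) * eeg.rate))
        start = onset_idx - n_pre
        stop = start + n_total
        if start < 0 or stop > eeg.n_samples:
            logger.warning("epoch at %.3f s exceeds the EEG recording; dropped",
                           event.onset)
            continue
        grid = event.onset + (np.arange(g_total) - g_pre) / session.gaze.rate
        gxy = _resample_gaze(session.gaze, grid)
        if gxy is None:
            logger.warning("epoch at %.3f s exceeds or gaps the gaze stream; "
                           "dropped", event.onset)
            continue
        gx, gy = gxy
        epochs.append(LabeledEpoch(
            eeg=eeg.samples[:, start:stop].copy(),
            eeg_rate=eeg.rate,
            gaze_t=grid, gaze_x=gx, gaze_y=gy,
            gaze_rate=session.gaze.rate,
            distance=accumulated_distance(gx, gy),
            event=event,
        ))
    return epochs


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------

def label_key_events(intended: str, typed: str) -> list[str]:
    """Label each typed character correct/erroneous under the retry rule.

    Greedy left-to-right scan: a pointer walks the intended text and
    advances only on a match, so earlier mistakes never shift the
    reference.  For intended "my dog is brown" and typed
    "muyb dog ias browqn" exactly the u, b, a, q presses come out
    erroneous.
    """
    labels: list[str] = []
    pos = 0
    for ch in typed:
        if pos < len(intended) and ch == intended[pos]:
            labels.append(CORRECT)
            pos += 1
        else:
            labels.append(ERRONEOUS)
    if pos != len(intended):
        raise ProtocolViolation(
            "protocol violation: intended sentence not completed")
    return labels


def label_epochs(session: TypingSession,
                 epochs: list[LabeledEpoch]) -> list[LabeledEpoch]:
    """Attach retry-rule labels to epochs cut from an error-aware session.

    Labels are computed for the full typed sequence and then matched to
    the surviving epochs by event index, so boundary-dropped epochs do
    not shift the assignment.
    """
    letter_events = [e for e in session.events if not e.is_backspace]
    labels = label_key_events(session.intended.rstrip("\n"), session.typed)
    by_index = {ev.index: lab for ev, lab in zip(letter_events, labels)}
    for epoch in epochs:
        epoch.label = by_index[epoch.event.index]
    return epochs


def prepare_session(session: TypingSession,
                    band: tuple[float, float] = (1.0, 16.0),
                    window: tuple[float, float] = (-0.2, 0.5)
                    ) -> list[LabeledEpoch]:
    """Filter, epoch and label one error-aware session."""
    filtered = bandpass_filter(session.eeg, *band)
    work = TypingSession(
        subject_id=session.subject_id, sentence_id=session.sentence_id,
        intended=session.intended, events=session.events,
        eeg=filtered, gaze=session.gaze, mode=session.mode)
    return label_epochs(work, epochize(work, window))
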