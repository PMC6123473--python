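"""Seeded generator of synthetic gaze-keyboard typing sessions.

The generator emulates the statistical structure the error-detection
pipeline relies on, so every downstream stage can be exercised without
recorded human data:

* key sequences for a dwell-time QWERTY keyboard with a configurable
  mistype probability (default 1 in 10 presses), where a mistyped key is
  drawn from the 8-neighbourhood of the intended key — emulating the eye
  tracker misreading an adjacent key;
* event-locked EEG templates added to spatially correlated 1/f noise:
  an error response with a frontocentral negativity near 300 ms followed
  by a centro-parietal positivity near 400 ms, and a milder biphasic
  correct response (central positivity near 200 ms, negativity near
  300 ms);
* gaze traces that execute a large saccade towards the next key after a
  correct registration but only a small within-key adjustment after an
  erroneous one, plus fixation jitter everywhere.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    BACKSPACE,
    EEGRecording,
    ERROR_AWARE,
    GazeRecording,
    KeyEvent,
    REGULAR,
    TypingSession,
)

# ---------------------------------------------------------------------------
# Montage and scalp profiles
# ---------------------------------------------------------------------------

#: 64 electrode labels of the extended 10-10 system, front to back.
CHANNEL_NAMES_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
)
assert len(CHANNEL_NAMES_64) == 64

# Documented constant scalp-weight tables (channel -> relative weight).
FRONTOCENTRAL = {
    "FCz": 1.0, "FC1": 0.8, "FC2": 0.8, "Fz": 0.7, "Cz": 0.8,
    "C1": 0.5, "C2": 0.5, "F1": 0.4, "F2": 0.4, "FC3": 0.4, "FC4": 0.4,
}
CENTROPARIETAL = {
    "CPz": 1.0, "CP1": 0.8, "CP2": 0.8, "Pz": 0.7, "Cz": 0.8,
    "C1": 0.5, "C2": 0.5, "P1": 0.4, "P2": 0.4,
}
CENTRAL = {
    "Cz": 1.0, "C1": 0.7, "C2": 0.7, "FCz": 0.6, "CPz": 0.6,
    "FC1": 0.4, "FC2": 0.4, "CP1": 0.4, "CP2": 0.4,
}


def _profile_vector(profile: dict[str, float],
                    channel_names: tuple[str, ...]) -> np.ndarray:
    return np.array([profile.get(name, 0.0) for name in channel_names])


# ---------------------------------------------------------------------------
# Keyboard layout
# ---------------------------------------------------------------------------

KEY_SIZE = 100.0  # pixels, square keys


def qwerty_layout(key_size: float = KEY_SIZE) -> dict[str, tuple[float, float, float, float]]:
    """Key -> (x, y, w, h) screen rectangle, origin top-left."""
    rows = [
        list("qwertyuiop") + [BACKSPACE],
        list("asdfghjkl"),
        list("zxcvbnm."),
        [" "],
    ]
    offsets = [0.0, 0.5, 1.0, 3.0]
    layout: dict[str, tuple[float, float, float, float]] = {}
    for r, (row, off) in enumerate(zip(rows, offsets)):
        for c, key in enumerate(row):
            w = key_size * (4.0 if key == " " else 1.0)
            layout[key] = ((off + c) * key_size, r * key_size, w, key_size)
    return layout


def key_center(layout: dict, key: str) -> np.ndarray:
    x, y, w, h = layout[key]
    return np.array([x + w / 2.0, y + h / 2.0])


def key_neighbours(layout: dict, key: str) -> list[str]:
    """Typeable keys whose centres fall in the 8-neighbourhood of *key*."""
    c = key_center(layout, key)
    out = []
    for other in layout:
        if other == key or other == BACKSPACE:
            continue
        d = key_center(layout, other) - c
        if max(abs(d[0]), abs(d[1])) <= 1.6 * KEY_SIZE:
            out.append(other)
    return sorted(out)


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """All knobs of the synthetic-session generator.

    ``mistype_probability`` is the per-press chance that the tracker
    registers a neighbouring key instead of the gazed one; ``snr`` scales
    the ERP template amplitude relative to the per-channel noise standard
    deviation.  Inter-key overheads (time beyond the dwell) are log-normal
    with distinct medians for letter and backspace presses.
    """

    layout: dict = field(default_factory=qwerty_layout)
    mistype_probability: float = 0.1
    snr: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0          # per-channel noise sd, microvolts
    saccade_speed: float = 2000.0     # px/s
    fixation_jitter_sd: float = 3.0   # px
    dwell: float = 0.5                # s
    reaction: float = 0.1             # s between registration and eye release
    letter_overhead_median: float = 0.35   # s
    backspace_overhead_median: float = 0.6
    overhead_sigma: float = 0.35      # log-space sd of overhead draws
    uninformative_gaze: bool = False
    eeg_rate: float = 256.0
    gaze_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mistype_probability < 0.5:
            raise ValueError(
                "error rate too high for correction model (need p < 0.5)")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")


# ---------------------------------------------------------------------------
# ERP templates
# ---------------------------------------------------------------------------

@dataclass
class ErpTemplate:
    """Class-specific event-locked EEG response on [0, 0.5) s."""

    kind: str
    waveform: np.ndarray              # channels x floor(0.5*rate) samples
    peaks: list[tuple[float, float, dict[str, float]]]  # (latency, amp, profile)
    channel_names: tuple[str, ...]
    rate: float

    @property
    def dominant_channel(self) -> str:
        """Channel with the largest summed absolute peak weight."""
        total = np.zeros(len(self.channel_names))
        for _, amp, profile in self.peaks:
            total += abs(amp) * _profile_vector(profile, self.channel_names)
        return self.channel_names[int(np.argmax(total))]


def make_erp_template(kind: str, spec: SimulationSpec) -> ErpTemplate:
    """Build the deterministic unit-amplitude template for one class.

    Templates are sums of Gaussian-windowed bumps with fixed scalp-weight
    profiles; the error response peaks later and with opposite leading
    polarity relative to the correct one.
    """
    if kind == "error":
        peaks = [(0.30, -1.0, FRONTOCENTRAL), (0.40, 0.8, CENTROPARIETAL)]
    elif kind == "correct":
        peaks = [(0.20, 0.7, CENTRAL), (0.30, -0.6, CENTRAL)]
    else:
        raise ValueError(f"unknown template kind {kind!r}")

    n = int(np.floor(0.5 * spec.eeg_rate))
    t = np.arange(n) / spec.eeg_rate
    wave = np.zeros((len(CHANNEL_NAMES_64), n))
    for latency, amp, profile in peaks:
        sigma = 0.045 if abs(latency - 0.30) < 0.06 or latency == 0.20 else 0.05
        bump = amp * np.exp(-0.5 * ((t - latency) / sigma) ** 2)
        wave += np.outer(_profile_vector(profile, CHANNEL_NAMES_64), bump)
    return ErpTemplate(kind=kind, waveform=wave, peaks=peaks,
                       channel_names=CHANNEL_NAMES_64, rate=spec.eeg_rate)


# ---------------------------------------------------------------------------
# Typing simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Press:
    """Ground-truth record of one key registration."""

    onset: float
    key: str        # registered key (or BACKSPACE)
    target: str     # intended key at the time of the press
    error: bool     # registered key differs from the target
    index: int

    @property
    def is_backspace(self) -> bool:
        return self.key == BACKSPACE


@dataclass
class TypingTrace:
    """Output of :func:`simulate_typing`: events plus ground truth."""

    presses: list[Press]
    mode: str

    @property
    def typed(self) -> str:
        return "".join(p.key for p in self.presses if not p.is_backspace)

    @property
    def events(self) -> list[KeyEvent]:
        return [KeyEvent(onset=p.onset, key=p.key, index=p.index)
                for p in self.presses]

    @property
    def error_flags(self) -> list[bool]:
        """Ground-truth error flag per non-backspace press, in order."""
        return [p.error for p in self.presses if not p.is_backspace]


def _overhead(spec: SimulationSpec, backspace: bool,
              rng: np.random.Generator) -> float:
    median = (spec.backspace_overhead_median if backspace
              else spec.letter_overhead_median)
    return float(median * np.exp(spec.overhead_sigma * rng.standard_normal()))


def simulate_typing(intended: str, spec: SimulationSpec,
                    mode: str = ERROR_AWARE,
                    rng: np.random.Generator | None = None) -> TypingTrace:
    """Simulate the press sequence for one sentence.

    In error-aware mode a mistyped key is simply left in place and the
    intended character retried, so the intended text is a subsequence of
    the typed one.  In regular mode every mistype is immediately followed
    by a backspace, so the committed text equals the intended text.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = spec.mistype_probability
    presses: list[Press] = []
    onset = spec.dwell  # first key committed after the first dwell interval
    index = 0

    for target in intended:
        if target not in spec.layout:
            raise ValueError(f"character {target!r} not on the keyboard")
        while True:
            mistype = rng.random() < p
            if mistype:
                neighbours = key_neighbours(spec.layout, target)
                key = neighbours[int(rng.integers(len(neighbours)))]
            else:
                key = target
            presses.append(Press(onset=onset, key=key, target=target,
                                 error=mistype, index=index))
            index += 1
            if not mistype:
                onset += spec.dwell + _overhead(spec, backspace=False, rng=rng)
                break
            if mode == REGULAR:
                onset += spec.dwell + _overhead(spec, backspace=True, rng=rng)
                presses.append(Press(onset=onset, key=BACKSPACE, target=BACKSPACE,
                                     error=False, index=index))
                index += 1
            onset += spec.dwell + _overhead(spec, backspace=False, rng=rng)
    return TypingTrace(presses=presses, mode=mode)


# ---------------------------------------------------------------------------
# Gaze simulation
# ---------------------------------------------------------------------------

def _fixation_position(press: Press, spec: SimulationSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Where the eyes actually dwell for this press.

    A mistype is a tracker misinterpretation: the eyes sit near the
    intended key but offset towards the neighbour that got registered.
    """
    target = press.target if press.target in spec.layout else press.key
    pos = key_center(spec.layout, target)
    if press.error and not spec.uninformative_gaze:
        pos = pos + 0.35 * (key_center(spec.layout, press.key) - pos)
    else:
        pos = pos + rng.uniform(-0.15, 0.15, size=2) * KEY_SIZE
    return pos


def simulate_gaze(trace: TypingTrace, spec: SimulationSpec,
                  rng: np.random.Generator | None = None,
                  duration: float | None = None) -> GazeRecording:
    """Render a 30 Hz gaze trace for a press sequence.

    The eye fixates each press's key through its dwell interval, is
    released ``reaction`` seconds after registration, and travels to the
    next fixation at the saccade speed.  After an erroneous registration
    the next fixation is the same key, so only a small adjustment occurs;
    after a correct one the eyes jump to the next character's key.  With
    ``uninformative_gaze`` the trace is an event-independent random walk.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if duration is None:
        duration = (trace.presses[-1].onset + 1.0) if trace.presses else 1.0
    t = np.arange(0.0, duration, 1.0 / spec.gaze_rate)

    if spec.uninformative_gaze:
        # Slow random walk, carries no information about press outcomes.
        steps = rng.normal(scale=8.0, size=(t.size, 2))
        path = np.cumsum(steps, axis=0) + key_center(spec.layout, "g")
        x, y = path[:, 0], path[:, 1]
    else:
        way_t: list[float] = []
        way_xy: list[np.ndarray] = []
        for i, press in enumerate(trace.presses):
            pos = _fixation_position(press, spec, rng)
            start = press.onset - spec.dwell
            release = press.onset + spec.reaction
            if not way_t:
                way_t.append(0.0)
                way_xy.append(pos)
            way_t.append(max(start, way_t[-1] + 1e-6))
            way_xy.append(pos)
            way_t.append(max(release, way_t[-1] + 1e-6))
            way_xy.append(pos)
            if i + 1 < len(trace.presses):
                nxt = _fixation_position(trace.presses[i + 1], spec, rng)
                travel = float(np.linalg.norm(nxt - pos)) / spec.saccade_speed
                arrive = min(release + travel,
                             trace.presses[i + 1].onset - spec.dwell)
                way_t.append(max(arrive, way_t[-1] + 1e-6))
                way_xy.append(nxt)
        if not way_t:
            way_t, way_xy = [0.0], [key_center(spec.layout, "g")]
        way = np.asarray(way_xy)
        x = np.interp(t, way_t, way[:, 0])
        y = np.interp(t, way_t, way[:, 1])

    x = x + rng.normal(scale=spec.fixation_jitter_sd, size=t.size)
    y = y + rng.normal(scale=spec.fixation_jitter_sd, size=t.size)
    return GazeRecording(t=t, x=x, y=y, rate=spec.gaze_rate)


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

_MIXING_SEED = 0xED5  # model constant: fixed spatial mixing of noise sources


def _coloured_noise(n_channels: int, n_samples: int, rate: float,
                    exponent: float, scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated 1/f noise, unit variance per channel x scale."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    floor_hz = 0.5  # flatten the spectrum below this to keep variance finite
    nz = freqs > 0
    shaping[nz] = np.maximum(freqs[nz], floor_hz) ** (-exponent / 2.0)
    shaping[0] = 0.0

    white = rng.standard_normal((n_channels, n_samples))
    sources = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n_samples,
                           axis=1)
    sources /= sources.std(axis=1, keepdims=True)

    mix_rng = np.random.default_rng(_MIXING_SEED)
    mixing = (np.eye(n_channels)
              + 0.35 * mix_rng.standard_normal((n_channels, n_channels))
              / np.sqrt(n_channels))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    return scale * (mixing @ sources)


def simulate_eeg(trace: TypingTrace,
                 templates: dict[str, ErpTemplate],
                 spec: SimulationSpec,
                 rng: np.random.Generator | None = None,
                 duration: float | None = None) -> EEGRecording:
    """Superimpose per-press ERP templates on coloured background noise.

    At every letter registration the template matching the press's
    ground-truth correctness is added starting at the onset sample, with
    peak amplitude ``snr * noise_scale`` microvolts.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if duration is None:
        duration = (trace.presses[-1].onset + 1.0) if trace.presses else 1.0
    n = int(np.round(duration * spec.eeg_rate))
    for tpl in templates.values():
        if tpl.rate != spec.eeg_rate:
            raise ValueError("template rate mismatch")

    data = _coloured_noise(len(CHANNEL_NAMES_64), n, spec.eeg_rate,
                           spec.noise_exponent, spec.noise_scale, rng)
    amp = spec.snr * spec.noise_scale
    if amp > 0:
        for press in trace.presses:
            if press.is_backspace:
                continue
            tpl = templates["error" if press.error else "correct"]
            start = int(np.round(press.onset * spec.eeg_rate))
            stop = min(start + tpl.waveform.shape[1], n)
            if start < n:
                data[:, start:stop] += amp * tpl.waveform[:, : stop - start]
    return EEGRecording(samples=data, rate=spec.eeg_rate,
                        channel_names=CHANNEL_NAMES_64, start_time=0.0)


# ---------------------------------------------------------------------------
# Session composition
# ---------------------------------------------------------------------------

#: Twenty short memorable sentences, lower case, full stop at the end.
DEFAULT_SENTENCES: tuple[str, ...] = (
    "my dog is brown.",
    "the sky turned red at dusk.",
    "she sells sea shells by the shore.",
    "a quick brown fox jumps over it.",
    "we will meet at noon for lunch.",
    "he reads one book every week.",
    "rain fell softly on the roof.",
    "the cat sleeps on the warm mat.",
    "birds sing early in the morning.",
    "coffee smells better than it tastes.",
    "two trains left the old station.",
    "her garden is full of roses.",
    "the moon rose over the quiet lake.",
    "please bring me a glass of water.",
    "winter nights are long and cold.",
    "children play chess in the park.",
    "the baker sold every loaf by ten.",
    "a gentle wind moved the tall grass.",
    "music filled the empty hall.",
    "they walked home under the stars.",
)


def _stable_int(*parts: object) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def simulate_session(intended: str, spec: SimulationSpec,
                     mode: str = ERROR_AWARE,
                     subject_id: str = "S01",
                     sentence_id: str = "sent-00") -> TypingSession:
    """Compose typing, gaze and EEG into one validated TypingSession.

    Deterministic: the stream seeds derive from the spec seed plus the
    subject, sentence and mode identifiers.
    """
    base = np.random.SeedSequence(
        [spec.seed, _stable_int(subject_id, sentence_id, mode)])
    rng_typing, rng_gaze, rng_eeg = (np.random.default_rng(s)
                                     for s in base.spawn(3))
    trace = simulate_typing(intended, spec, mode=mode, rng=rng_typing)
    duration = trace.presses[-1].onset + 1.0
    gaze = simulate_gaze(trace, spec, rng=rng_gaze, duration=duration)
    templates = {"error": make_erp_template("error", spec),
                 "correct": make_erp_template("correct", spec)}
    eeg = simulate_eeg(trace, templates, spec, rng=rng_eeg, duration=duration)
    session = TypingSession(subject_id=subject_id, sentence_id=sentence_id,
                            intended=intended, events=trace.events,
                            eeg=eeg, gaze=gaze, mode=mode)
    # stash ground truth for tests and end-to-end consistency checks
    session.ground_truth = trace  # type: ignore[attr-defined]
    return session


def simulate_subject(spec: SimulationSpec,
                     sentences: tuple[str, ...] = DEFAULT_SENTENCES,
                     subject_id: str = "S01",
                     modes: tuple[str, ...] = (ERROR_AWARE, REGULAR),
                     ) -> dict[str, list[TypingSession]]:
    """Simulate one subject typing every sentence in the requested modes."""
    out: dict[str, list[TypingSession]] = {}
    for mode in modes:
        out[mode] = [
            simulate_session(sent, spec, mode=mode, subject_id=subject_id,
                             sentence_id=f"sent-{i:02d}")
            for i, sent in enumerate(sentences)
        ]
    return out
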