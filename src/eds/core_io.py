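"""Session data model, on-disk bundle format, and pipeline configuration.

A *typing session* is one sentence typed on a gaze-based (dwell-time)
keyboard while EEG (64 channels, 256 Hz) and screen gaze coordinates
(30 Hz) were recorded.  Every key registration — the instant a key is
committed after the dwell time elapses — is a time-locking event for the
downstream error-detection pipeline.

Sessions are stored as plain-text bundle directories so they stay
inspectable and diff-friendly:

    <bundle>/
        manifest.yaml   subject_id, sentence_id, intended, mode, rates
        eeg.csv         "time,<ch1>,...,<chN>"
        gaze.csv        "time,x,y"
        events.tsv      "onset\tkey\tindex"

Floats are serialized with 12 significant digits; round-tripping is
exact to well below 1e-6 for signals in the microvolt / pixel range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

BACKSPACE = "BACKSPACE"

ERROR_AWARE = "error-aware-recording"
REGULAR = "regular-control"
_MODES = (ERROR_AWARE, REGULAR)

_FLOAT_FMT = "%.12g"


class BundleError(ValueError):
    """Malformed or incomplete session bundle."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG: ``samples`` is channels x time in microvolts."""

    samples: np.ndarray
    rate: float = 256.0
    channel_names: Sequence[str] = ()
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.rate <= 0:
            raise ValueError("EEG rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("EEG samples must be a channels x time matrix")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names must match matrix row count")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples contain missing values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def end_time(self) -> float:
        return self.start_time + self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate


@dataclass
class GazeRecording:
    """Screen-gaze samples: pixel coordinates, origin top-left."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.rate <= 0:
            raise ValueError("gaze rate must be positive")
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("gaze timestamps must be monotone non-decreasing")
        # de-duplicate identical timestamps, then require strict increase
        if self.t.size:
            keep = np.concatenate([[True], np.diff(self.t) > 0])
            self.t, self.x, self.y = self.t[keep], self.x[keep], self.y[keep]
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("gaze coordinates must be finite")

    @property
    def start_time(self) -> float:
        return float(self.t[0]) if self.t.size else 0.0

    @property
    def end_time(self) -> float:
        return float(self.t[-1]) if self.t.size else 0.0


@dataclass(frozen=True)
class KeyEvent:
    """One key registration: the end of the dwell interval on a key."""

    onset: float
    key: str
    index: int

    @property
    def is_backspace(self) -> bool:
        return self.key == BACKSPACE


@dataclass
class TypingSession:
    """One sentence's synchronized EEG, gaze, key events and intended text."""

    subject_id: str
    sentence_id: str
    intended: str
    events: list[KeyEvent]
    eeg: EEGRecording
    gaze: GazeRecording
    mode: str = ERROR_AWARE

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.intended or self.intended != self.intended.lower() \
                or not self.intended.endswith("."):
            raise ValueError(
                "intended must be non-empty lower-case text ending in a full stop")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for e in self.events:
            if not (self.eeg.start_time <= e.onset <= self.eeg.end_time
                    and self.gaze.start_time <= e.onset <= self.gaze.end_time):
                raise ValueError("unsynchronized events: onset outside recordings")

    @property
    def typed(self) -> str:
        """Typed character sequence, backspace presses excluded."""
        return "".join(e.key for e in self.events if not e.is_backspace)

    @property
    def committed(self) -> str:
        """Text on screen after replaying all presses (backspace deletes)."""
        out: list[str] = []
        for e in self.events:
            if e.is_backspace:
                if out:
                    out.pop()
            else:
                out.append(e.key)
        return "".join(out)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable pipeline parameters with the published defaults.

    band: pass-band edges in Hz; window: epoch extent in s around key
    registration; dwell: continuous-fixation time to commit a key;
    threshold: decision threshold in normalized SVM margin units.
    """

    band: tuple[float, float] = (1.0, 16.0)
    window: tuple[float, float] = (-0.2, 0.5)
    dwell: float = 0.5
    smote_k: int = 5
    svm_cost: float = 1.0
    threshold: float = 0.0
    mc_repetitions: int = 100
    seed: int = 0
    selection_time: float = 1.0   # nominal time per key selection T_s (s)
    decimation: int = 1           # keep every n-th virtual-sensor sample

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ConfigError("invalid band: low must be below high")
        a, b = self.window
        if not a < 0 < b:
            raise ConfigError("invalid window: must straddle the event onset")
        if not -1.0 <= self.threshold <= 1.0:
            raise ConfigError("invalid threshold: must lie in [-1, 1]")
        if self.dwell <= 0:
            raise ConfigError("invalid dwell: must be positive")
        if self.selection_time <= 0:
            raise ConfigError("invalid selection_time: must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value file; unspecified keys take the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("band", "window"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def write_session(session: TypingSession, path: str | Path) -> Path:
    """Write a session as a plain-text bundle directory readable by
    :func:`read_session`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "subject_id": session.subject_id,
        "sentence_id": session.sentence_id,
        "intended": session.intended,
        "mode": session.mode,
        "eeg_rate": float(session.eeg.rate),
        "gaze_rate": float(session.gaze.rate),
        "eeg_start_time": float(session.eeg.start_time),
    }
    (path / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))

    eeg_df = pd.DataFrame(
        session.eeg.samples.T, columns=list(session.eeg.channel_names))
    eeg_df.insert(0, "time", session.eeg.times())
    eeg_df.to_csv(path / "eeg.csv", index=False, float_format=_FLOAT_FMT)

    gaze_df = pd.DataFrame(
        {"time": session.gaze.t, "x": session.gaze.x, "y": session.gaze.y})
    gaze_df.to_csv(path / "gaze.csv", index=False, float_format=_FLOAT_FMT)

    ev_df = pd.DataFrame(
        {"onset": [e.onset for e in session.events],
         "key": [e.key for e in session.events],
         "index": [e.index for e in session.events]})
    ev_df.to_csv(path / "events.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    return path


def read_session(path: str | Path) -> TypingSession:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    for name in ("manifest.yaml", "eeg.csv", "gaze.csv", "events.tsv"):
        if not (path / name).exists():
            raise BundleError(f"incomplete bundle: missing {name}")

    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    try:
        eeg_df = pd.read_csv(path / "eeg.csv")
        gaze_df = pd.read_csv(path / "gaze.csv")
        ev_df = pd.read_csv(path / "events.tsv", sep="\t",
                            dtype={"key": str}, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - delegated parse errors
        raise BundleError(f"malformed stream: {exc}") from exc

    if eeg_df.columns[0] != "time" or eeg_df.shape[1] < 2:
        raise BundleError("malformed stream: eeg table needs time + channels")
    if list(gaze_df.columns) != ["time", "x", "y"]:
        raise BundleError("malformed stream: gaze table must be time,x,y")
    if list(ev_df.columns) != ["onset", "key", "index"]:
        raise BundleError("malformed stream: events table must be onset,key,index")
    if eeg_df.isna().any().any() or gaze_df.isna().any().any():
        raise BundleError("malformed stream: missing values")

    rate = float(manifest["eeg_rate"])
    times = eeg_df["time"].to_numpy()
    if times.size >= 2:
        step = np.diff(times)
        if not np.allclose(step, 1.0 / rate, atol=1e-6):
            raise BundleError("malformed stream: eeg timestamps off the rate grid")

    eeg = EEGRecording(
        samples=eeg_df.iloc[:, 1:].to_numpy().T,
        rate=rate,
        channel_names=list(eeg_df.columns[1:]),
        start_time=float(manifest.get("eeg_start_time", times[0] if times.size else 0.0)),
    )
    gaze = GazeRecording(
        t=gaze_df["time"].to_numpy(),
        x=gaze_df["x"].to_numpy(),
        y=gaze_df["y"].to_numpy(),
        rate=float(manifest["gaze_rate"]),
    )
    events = [KeyEvent(onset=float(r.onset), key=str(r.key), index=int(r.index))
              for r in ev_df.itertuples(index=False)]
    try:
        return TypingSession(
            subject_id=str(manifest["subject_id"]),
            sentence_id=str(manifest["sentence_id"]),
            intended=str(manifest["intended"]),
            events=events,
            eeg=eeg,
            gaze=gaze,
            mode=str(manifest["mode"]),
        )
    except ValueError as exc:
        if "unsynchronized" in str(exc):
            raise BundleError(str(exc)) from exc
        raise BundleError(f"malformed stream: {exc}") from exc
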