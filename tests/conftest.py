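import numpy as np
import pytest

import eds
from eds.core_io import KeyEvent
from eds.preprocessing import LabeledEpoch


@pytest.fixture(scope="session")
def spec10():
    """High-SNR simulation spec: templates clearly above the noise."""
    return eds.SimulationSpec(seed=0, snr=10.0)


@pytest.fixture(scope="session")
def small_sessions(spec10):
    """Six error-aware sessions at high SNR (shared, read-only)."""
    return [eds.simulate_session(s, spec10, sentence_id=f"sent-{i:02d}")
            for i, s in enumerate(eds.DEFAULT_SENTENCES[:6])]


@pytest.fixture(scope="session")
def small_epochs(small_sessions):
    """Filtered, labelled epochs pooled over the six sessions."""
    return [e for s in small_sessions for e in eds.prepare_session(s)]


def toy_epoch(label: str, index: int, rng: np.random.Generator,
              n_channels: int = 4, eeg: np.ndarray | None = None,
              distance: np.ndarray | None = None) -> LabeledEpoch:
    """Hand-built epoch with controllable EEG and distance content."""
    if eeg is None:
        eeg = rng.standard_normal((n_channels, 179))
    if distance is None:
        distance = np.concatenate(
            [[0.0], np.cumsum(rng.uniform(0.9, 1.1, 20))])
    grid = 0.5 * index + (np.arange(21) - 6) / 30.0
    return LabeledEpoch(
        eeg=np.asarray(eeg, dtype=float), eeg_rate=256.0,
        gaze_t=grid, gaze_x=np.linspace(0, 1, 21) + distance,
        gaze_y=np.zeros(21), gaze_rate=30.0,
        distance=np.asarray(distance, dtype=float),
        event=KeyEvent(onset=0.5 * index + 0.5, key="a", index=index),
        label=label)


def separable_epochs(n_err: int = 12, n_cor: int = 40, seed: int = 0
                     ) -> list[LabeledEpoch]:
    """Epochs separable in both modalities.

    Erroneous presses: short gaze path and a strong channel-0 EEG
    deflection; correct presses: long path, no deflection.
    """
    rng = np.random.default_rng(seed)
    epochs = []
    for i in range(n_err + n_cor):
        err = i < n_err
        slope = 1.0 if err else 20.0
        distance = np.concatenate(
            [[0.0], np.cumsum(rng.uniform(0.9, 1.1, 20) * slope)])
        eeg = 0.1 * rng.standard_normal((4, 179))
        if err:
            eeg[0] += 5.0 * np.sin(np.linspace(0, np.pi, 179))
        epochs.append(toy_epoch("erroneous" if err else "correct", i, rng,
                                eeg=eeg, distance=distance))
    return epochs
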