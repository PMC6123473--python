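"""Detector evaluation: metrics, cross-validation, threshold sweeps,
utility-gain scoring, and the eye-direction-conditioned EEG diagnostic.

The positive class throughout is the *erroneous* press: sensitivity is
the fraction of mistypes flagged, specificity the fraction of correct
presses left alone.  Because mistypes are rare, raw accuracy is nearly
meaningless and configurations are instead ranked by the utility gain —
the ratio of expected correct-characters-per-second with the error
detector to that of the unassisted keyboard, under a renewal model of
the typing process (see :func:`utility_gain`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core_io import PipelineConfig, TypingSession
from .detection import DetectorBundle, decide, fit_detector, score_epochs
from .preprocessing import CORRECT, ERRONEOUS, LabeledEpoch, prepare_session


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

def confusion_metrics(predicted: list[str], true: list[str]
                      ) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with erroneous as positive.

    A metric whose reference class is absent comes back as NaN rather
    than silently zero.
    """
    if len(predicted) != len(true):
        raise ValueError("prediction/label length mismatch")
    pred = np.asarray(predicted)
    truth = np.asarray(true)
    pos = truth == ERRONEOUS
    neg = truth == CORRECT
    tp = int(np.sum(pos & (pred == ERRONEOUS)))
    tn = int(np.sum(neg & (pred == CORRECT)))
    sens = tp / pos.sum() if pos.any() else float("nan")
    spec = tn / neg.sum() if neg.any() else float("nan")
    acc = (tp + tn) / len(truth) if len(truth) else float("nan")
    return sens, spec, acc


# ---------------------------------------------------------------------------
# Utility model
# ---------------------------------------------------------------------------

@dataclass
class UtilityModel:
    """Operating point of the error-aware keyboard.

    p: per-press mistype probability; se/sp: detector sensitivity and
    specificity; selection_time: nominal seconds per key selection
    (identical for letters and backspace; it cancels in the gain).
    """

    p: float
    se: float
    sp: float
    selection_time: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 0.5:
            raise ValueError("p must lie in [0, 0.5)")
        if not (0.0 <= self.se <= 1.0 and 0.0 <= self.sp <= 1.0):
            raise ValueError("se and sp must lie in [0, 1]")
        if self.selection_time <= 0:
            raise ValueError("selection_time must be positive")


def utility_regular(model: UtilityModel) -> float:
    """Expected net correct characters per second, unassisted keyboard.

    Renewal model: every selection costs ``selection_time``; a mistype
    (probability p) must be undone by one backspace, so p presses in
    1 + p selections contribute nothing.
    """
    return (1.0 - model.p) / ((1.0 + model.p) * model.selection_time)


def utility_eds(model: UtilityModel) -> float:
    """Expected net rate with the error-detection system engaged.

    Detected mistypes (p*se) are auto-deleted at no extra selection;
    missed ones (p*(1-se)) still cost a backspace; a falsely deleted
    correct press ((1-p)(1-sp)) wastes its selection.
    """
    progress = (1.0 - model.p) * model.sp
    selections = 1.0 + model.p * (1.0 - model.se)
    return progress / (selections * model.selection_time)


def utility_gain(model: UtilityModel) -> float:
    """Utility ratio EDS / regular: sp * (1 + p) / (1 + p * (1 - se)).

    Equals 1 when the detector never intervenes (se = 0, sp = 1), is
    strictly increasing in both se and sp, and is capped at 1 + p.
    """
    return utility_eds(model) / utility_regular(model)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloResult:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_sd: float
    specificity_sd: float
    accuracy_sd: float
    per_rep: dict[str, np.ndarray]
    reps: int
    p_hat: float
    n_test_erroneous: int
    n_test_correct: int


def _labels_of(epochs: list[LabeledEpoch]) -> np.ndarray:
    return np.asarray([e.label for e in epochs])


def monte_carlo_cv(epochs: list[LabeledEpoch], mode: str,
                   reps: int = 100, seed: int = 0,
                   theta: float | None = None,
                   config: PipelineConfig | None = None) -> MonteCarloResult:
    """Repeated random-split evaluation preserving the class imbalance.

    Every repetition holds out 10 erroneous epochs plus enough correct
    ones to keep the empirical correct:erroneous ratio, trains the full
    pipeline (SMOTE inside) on the remainder, and scores the held-out
    set at threshold theta.  A master seed spawns per-repetition seeds.
    """
    config = config or PipelineConfig()
    labels = _labels_of(epochs)
    err_idx = np.flatnonzero(labels == ERRONEOUS)
    cor_idx = np.flatnonzero(labels == CORRECT)
    if err_idx.size < 11:
        raise ValueError("insufficient minority instances: need >= 11 "
                         "erroneous epochs")
    p_hat = err_idx.size / labels.size
    n_test_err = 10
    n_test_cor = int(np.round(n_test_err * (1.0 - p_hat) / p_hat))
    n_test_cor = min(n_test_cor, cor_idx.size - 1)

    per_rep = {k: np.empty(reps) for k in
               ("sensitivity", "specificity", "accuracy", "flagged_fraction")}
    children = np.random.SeedSequence(seed).spawn(reps)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        test_e = rng.choice(err_idx, size=n_test_err, replace=False)
        test_c = rng.choice(cor_idx, size=n_test_cor, replace=False)
        test_idx = np.concatenate([test_e, test_c])
        test_mask = np.zeros(labels.size, dtype=bool)
        test_mask[test_idx] = True
        train = [epochs[i] for i in np.flatnonzero(~test_mask)]
        test = [epochs[i] for i in test_idx]

        fit_seed = int(rng.integers(2**31 - 1))
        bundle = fit_detector(train, mode, config, seed=fit_seed)
        flags = decide(bundle, score_epochs(bundle, test), theta)
        pred = [ERRONEOUS if f else CORRECT for f in flags]
        se, sp, acc = confusion_metrics(pred, [e.label for e in test])
        per_rep["sensitivity"][r] = se
        per_rep["specificity"][r] = sp
        per_rep["accuracy"][r] = acc
        per_rep["flagged_fraction"][r] = float(np.mean(flags))

    return MonteCarloResult(
        sensitivity=float(per_rep["sensitivity"].mean()),
        specificity=float(per_rep["specificity"].mean()),
        accuracy=float(per_rep["accuracy"].mean()),
        sensitivity_sd=float(per_rep["sensitivity"].std(ddof=1)),
        specificity_sd=float(per_rep["specificity"].std(ddof=1)),
        accuracy_sd=float(per_rep["accuracy"].std(ddof=1)),
        per_rep=per_rep, reps=reps, p_hat=float(p_hat),
        n_test_erroneous=n_test_err, n_test_correct=n_test_cor)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    grid: np.ndarray
    sensitivity: np.ndarray     # mean over repetitions, per theta
    specificity: np.ndarray
    gain: np.ndarray
    best_theta: float
    best_gain: float
    p_hat: float


def threshold_sweep(epochs: list[LabeledEpoch], mode: str,
                    grid_step: float = 0.05, reps: int = 20, seed: int = 0,
                    config: PipelineConfig | None = None) -> SweepResult:
    """Sweep theta over [-1, 1] and score each point by utility gain.

    The pipeline is fitted once per repetition; held-out scores are then
    thresholded at every grid point, so the per-repetition sensitivity
    is non-decreasing and specificity non-increasing along the grid by
    construction.  Gain uses the dataset's empirical mistype rate.
    """
    config = config or PipelineConfig()
    n_grid = int(np.round(2.0 / grid_step)) + 1
    grid = np.linspace(-1.0, 1.0, n_grid)

    labels = _labels_of(epochs)
    err_idx = np.flatnonzero(labels == ERRONEOUS)
    cor_idx = np.flatnonzero(labels == CORRECT)
    if err_idx.size < 11:
        raise ValueError("insufficient minority instances")
    p_hat = err_idx.size / labels.size
    n_test_err = 10
    n_test_cor = min(int(np.round(n_test_err * (1.0 - p_hat) / p_hat)),
                     cor_idx.size - 1)

    sens = np.zeros((reps, n_grid))
    spec = np.zeros((reps, n_grid))
    children = np.random.SeedSequence(seed).spawn(reps)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        test_e = rng.choice(err_idx, size=n_test_err, replace=False)
        test_c = rng.choice(cor_idx, size=n_test_cor, replace=False)
        test_idx = np.concatenate([test_e, test_c])
        test_mask = np.zeros(labels.size, dtype=bool)
        test_mask[test_idx] = True
        train = [epochs[i] for i in np.flatnonzero(~test_mask)]
        test = [epochs[i] for i in test_idx]
        truth = np.asarray([e.label for e in test])

        bundle = fit_detector(train, mode, config,
                              seed=int(rng.integers(2**31 - 1)))
        scores = score_epochs(bundle, test)
        for g, theta in enumerate(grid):
            flags = decide(bundle, scores, float(theta))
            tp = np.sum(flags & (truth == ERRONEOUS))
            tn = np.sum(~flags & (truth == CORRECT))
            sens[r, g] = tp / n_test_err
            spec[r, g] = tn / n_test_cor

    mean_sens = sens.mean(axis=0)
    mean_spec = spec.mean(axis=0)
    gain = np.array([
        utility_gain(UtilityModel(p=p_hat, se=float(se), sp=float(sp)))
        for se, sp in zip(mean_sens, mean_spec)])
    best = int(np.argmax(gain))
    return SweepResult(grid=grid, sensitivity=mean_sens,
                       specificity=mean_spec, gain=gain,
                       best_theta=float(grid[best]),
                       best_gain=float(gain[best]), p_hat=float(p_hat))


# ---------------------------------------------------------------------------
# Leave-one-sentence-out
# ---------------------------------------------------------------------------

@dataclass
class LosoFold:
    session: TypingSession
    epochs: list[LabeledEpoch]
    predicted: list[str]        # aligned with epochs
    by_event_index: dict[int, str]


def loso_cv(sessions: list[TypingSession], mode: str,
            theta: float | None = None,
            config: PipelineConfig | None = None,
            seed: int = 0) -> list[LosoFold]:
    """Leave-one-sentence-out prediction over a subject's sessions.

    For every held-out sentence the detector is fitted on all remaining
    sentences' epochs and applied to each key press of the held-out one.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for LOSO")
    config = config or PipelineConfig()
    prepared = [prepare_session(s, band=config.band, window=config.window)
                for s in sessions]
    folds: list[LosoFold] = []
    children = np.random.SeedSequence(seed).spawn(len(sessions))
    for i, (session, epochs) in enumerate(zip(sessions, prepared)):
        train = [e for j, other in enumerate(prepared) if j != i
                 for e in other]
        if not any(e.label == ERRONEOUS for e in train):
            raise ValueError("degenerate fold: no erroneous epochs in train")
        rng = np.random.default_rng(children[i])
        bundle = fit_detector(train, mode, config,
                              seed=int(rng.integers(2**31 - 1)))
        flags = decide(bundle, score_epochs(bundle, epochs), theta)
        pred = [ERRONEOUS if f else CORRECT for f in flags]
        folds.append(LosoFold(
            session=session, epochs=epochs, predicted=pred,
            by_event_index={e.event.index: p
                            for e, p in zip(epochs, pred)}))
    return folds


# ---------------------------------------------------------------------------
# Direction-conditioned sub-averaging diagnostic
# ---------------------------------------------------------------------------

@dataclass
class DirectionGroups:
    membership: np.ndarray        # group id per epoch
    displacements: np.ndarray     # n x 2 aggregate gaze displacement
    eeg_traces: np.ndarray        # k x time sub-averaged chosen channel
    speed_profiles: np.ndarray    # k x (gaze samples - 1) mean speed


def direction_subaverages(correct_epochs: list[LabeledEpoch], k: int = 4,
                          seed: int = 0, channel: int = 30
                          ) -> DirectionGroups:
    """Group correct-press epochs by eye-movement direction and
    sub-average the EEG.

    The aggregate gaze displacement over the epoch window is clustered
    with k-means into k directions; EEG traces of the chosen channel
    (default index 30, Cz in the bundled montage) and gaze speed
    profiles are then averaged within each group.  An ocular-artefact
    contamination would show up as a polarity inversion between opposite
    direction groups; a genuine cortical response does not invert.
    """
    n = len(correct_epochs)
    if k > n:
        raise ValueError("k exceeds the number of epochs")
    disp = np.stack([[e.gaze_x[-1] - e.gaze_x[0], e.gaze_y[-1] - e.gaze_y[0]]
                     for e in correct_epochs])
    if k == 1:
        membership = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        membership = km.fit_predict(disp)
    eeg_traces = np.stack([
        np.stack([e.eeg[channel] for e, m in zip(correct_epochs, membership)
                  if m == g]).mean(axis=0)
        for g in range(k)])
    speed = np.stack([np.diff(e.distance) * e.gaze_rate
                      for e in correct_epochs])
    speed_profiles = np.stack([speed[membership == g].mean(axis=0)
                               for g in range(k)])
    return DirectionGroups(membership=membership, displacements=disp,
                           eeg_traces=eeg_traces,
                           speed_profiles=speed_profiles)
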