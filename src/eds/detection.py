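"""Class balancing, SVM training and thresholded error decisions.

Erroneous presses are rare (about 1 in 10), so before any fitting the
minority class is brought up to the majority count with SMOTE, applied
to the band-pass filtered EEG epochs (vectorized channels x time) and,
separately, to the gaze accumulated-distance series — i.e. *before* the
spatial filter is fitted, which is label-driven and benefits from the
balanced pool.

Linear SVMs then operate on z-scored features: one per modality, one on
the concatenated features ("early fusion"), while "late fusion" keeps
the two unimodal SVMs and lets the one with the dominant normalized
confidence decide.  Raw SVM decision values are divided by the maximum
absolute training score, so train scores live in [-1, 1] and a decision
threshold theta in that interval is meaningful; positive scores are
evidence for a correct press, and a press is flagged erroneous when the
deciding score falls at or below theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .core_io import PipelineConfig
from .features import (
    SpatialFilter,
    apply_dsp,
    fit_dsp,
    hjorth_descriptors,
    split_by_label,
)
from .preprocessing import CORRECT, ERRONEOUS, LabeledEpoch

logger = logging.getLogger(__name__)

MODES = ("eeg", "gaze", "early", "late")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(minority: np.ndarray, target_count: int, k: int = 5,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Grow a minority sample to ``target_count`` rows with SMOTE.

    Each synthetic instance is ``x + u * (x_nn - x)`` for a random
    parent x, one of its k nearest minority neighbours x_nn (Euclidean)
    and u ~ Uniform(0, 1), so it lies on the segment between the two.
    With a single minority instance the parent is duplicated.  The
    originals are returned first, followed by the synthetic rows.
    """
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n == 0:
        raise ValueError("minority set is empty")
    if target_count < n:
        raise ValueError("target below minority size")
    n_synth = target_count - n
    if n_synth == 0:
        return minority.copy()

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if n == 1:
        logger.warning("single minority instance: SMOTE degenerates to "
                       "duplication")
        return np.vstack([minority, np.repeat(minority, n_synth, axis=0)])

    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
    neighbour_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]

    parents = rng.integers(n, size=n_synth)
    picks = rng.integers(k_eff, size=n_synth)
    u = rng.random(n_synth)
    x = minority[parents]
    x_nn = minority[neighbour_idx[parents, picks]]
    synth = x + u[:, None] * (x_nn - x)
    return np.vstack([minority, synth])


# ---------------------------------------------------------------------------
# Detector bundle
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant features pass through as 0
        return cls(mean=mean, sd=sd)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class DetectorBundle:
    """Fitted error detector for one fusion mode."""

    mode: str
    threshold: float
    spatial_filter: SpatialFilter | None = None
    normalizers: dict[str, Normalizer] = field(default_factory=dict)
    svms: dict[str, SVC] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    n_pre: int = 51
    decimation: int = 1
    gaze_rate: float = 30.0

    @property
    def modalities(self) -> tuple[str, ...]:
        if self.mode in ("eeg", "gaze", "early"):
            return (self.mode,)
        return ("eeg", "gaze")


_LABEL_NUM = {ERRONEOUS: -1, CORRECT: 1}  # positive score => correct


def _hjorth_matrix(series: np.ndarray, rate: float) -> np.ndarray:
    return np.stack([hjorth_descriptors(row, rate).as_vector()
                     for row in series])


def _eeg_feature_matrix(filt: SpatialFilter, stack: np.ndarray, n_pre: int,
                        decimation: int) -> np.ndarray:
    virtual = np.einsum("c,nct->nt", filt.w, stack[:, :, n_pre:])
    return virtual[:, ::decimation]


def fit_detector(train_epochs: list[LabeledEpoch], mode: str,
                 config: PipelineConfig | None = None,
                 seed: int | None = None) -> DetectorBundle:
    """Fit the full detection pipeline on labelled training epochs.

    Order of operations: SMOTE on the raw per-modality representations
    (train only) -> spatial-filter fit / Hjorth extraction -> z-score
    normalization fitted on the augmented train -> linear SVM(s).  Test
    data never enter any fitting step.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    err, cor = split_by_label(train_epochs)
    if not err or not cor:
        raise ValueError("degenerate training set: both classes required")

    rng_eeg, rng_gaze = (np.random.default_rng(s) for s in
                         np.random.SeedSequence(seed).spawn(2))
    target = max(len(err), len(cor))
    n_pre = train_epochs[0].n_pre
    gaze_rate = train_epochs[0].gaze_rate
    bundle = DetectorBundle(mode=mode, threshold=config.threshold,
                            n_pre=n_pre, decimation=config.decimation,
                            gaze_rate=gaze_rate)

    # class-wise raw stacks; SMOTE grows whichever class is smaller
    def balanced(raw_err: np.ndarray, raw_cor: np.ndarray,
                 rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
        if raw_err.shape[0] < target:
            raw_err = smote_oversample(raw_err, target, k=config.smote_k,
                                       seed=rng)
        if raw_cor.shape[0] < target:
            raw_cor = smote_oversample(raw_cor, target, k=config.smote_k,
                                       seed=rng)
        return raw_err, raw_cor

    feats: dict[str, np.ndarray] = {}
    labels = np.concatenate([np.full(target, _LABEL_NUM[ERRONEOUS]),
                             np.full(target, _LABEL_NUM[CORRECT])])

    if mode in ("eeg", "early", "late"):
        shape = err[0].eeg.shape
        vec_err = np.stack([e.eeg.ravel() for e in err])
        vec_cor = np.stack([e.eeg.ravel() for e in cor])
        vec_err, vec_cor = balanced(vec_err, vec_cor, rng_eeg)
        stack_err = vec_err.reshape(-1, *shape)
        stack_cor = vec_cor.reshape(-1, *shape)
        bundle.spatial_filter = fit_dsp(stack_err, stack_cor)
        feats["eeg"] = np.vstack([
            _eeg_feature_matrix(bundle.spatial_filter, stack_err, n_pre,
                                config.decimation),
            _eeg_feature_matrix(bundle.spatial_filter, stack_cor, n_pre,
                                config.decimation)])
        bundle.normalizers["eeg"] = Normalizer.fit(feats["eeg"])

    if mode in ("gaze", "early", "late"):
        dist_err = np.stack([e.distance for e in err])
        dist_cor = np.stack([e.distance for e in cor])
        dist_err, dist_cor = balanced(dist_err, dist_cor, rng_gaze)
        feats["gaze"] = np.vstack([_hjorth_matrix(dist_err, gaze_rate),
                                   _hjorth_matrix(dist_cor, gaze_rate)])
        bundle.normalizers["gaze"] = Normalizer.fit(feats["gaze"])

    def train_svm(name: str, X: np.ndarray) -> None:
        svm = SVC(kernel="linear", C=config.svm_cost)
        svm.fit(X, labels)
        raw = svm.decision_function(X)
        bundle.svms[name] = svm
        bundle.scales[name] = float(np.max(np.abs(raw))) or 1.0

    if mode in ("eeg", "late"):
        train_svm("eeg", bundle.normalizers["eeg"](feats["eeg"]))
    if mode in ("gaze", "late"):
        train_svm("gaze", bundle.normalizers["gaze"](feats["gaze"]))
    if mode == "early":
        X = np.hstack([bundle.normalizers["eeg"](feats["eeg"]),
                       bundle.normalizers["gaze"](feats["gaze"])])
        train_svm("early", X)
    return bundle


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------

def _feature_block(bundle: DetectorBundle, epochs: list[LabeledEpoch],
                   modality: str) -> np.ndarray:
    if modality == "eeg":
        stack = np.stack([e.eeg for e in epochs])
        if bundle.spatial_filter is None:
            raise ValueError("bundle has no fitted spatial filter")
        if stack.shape[1] != bundle.spatial_filter.w.shape[0]:
            raise ValueError("feature dimension mismatch: channel count")
        X = _eeg_feature_matrix(bundle.spatial_filter, stack, bundle.n_pre,
                                bundle.decimation)
        return bundle.normalizers["eeg"](X)
    if modality == "gaze":
        series = np.stack([e.distance for e in epochs])
        return bundle.normalizers["gaze"](
            _hjorth_matrix(series, bundle.gaze_rate))
    raise ValueError(f"unknown modality {modality!r}")


def score_epochs(bundle: DetectorBundle,
                 epochs: list[LabeledEpoch]) -> dict[str, np.ndarray]:
    """Normalized decision scores per modality for a batch of epochs.

    Scores are raw SVM decision values divided by the training scale, so
    training instances lie in [-1, 1]; test scores may exceed that range
    and are deliberately not clipped.
    """
    out: dict[str, np.ndarray] = {}
    for name in bundle.modalities:
        if name == "early":
            X = np.hstack([_feature_block(bundle, epochs, "eeg"),
                           _feature_block(bundle, epochs, "gaze")])
        else:
            X = _feature_block(bundle, epochs, name)
        if X.shape[1] != bundle.svms[name].n_features_in_:
            raise ValueError("feature dimension mismatch")
        out[name] = bundle.svms[name].decision_function(X) / bundle.scales[name]
    return out


def score(bundle: DetectorBundle, epoch: LabeledEpoch) -> dict[str, float]:
    """Normalized score(s) for one epoch; positive favours CORRECT."""
    return {k: float(v[0]) for k, v in score_epochs(bundle, [epoch]).items()}


def decide(bundle: DetectorBundle, scores: dict[str, np.ndarray],
           theta: float | None = None) -> np.ndarray:
    """Vectorized decision rule; returns a boolean erroneous-flag array.

    Unimodal and early fusion flag an epoch erroneous when its score is
    at or below theta.  Late fusion first selects the modality with the
    larger absolute score (ties go to EEG) and then applies the same
    threshold to the winning score.
    """
    if theta is None:
        theta = bundle.threshold
    if not -1.0 <= theta <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    if bundle.mode == "late":
        s_eeg, s_gaze = scores["eeg"], scores["gaze"]
        deciding = np.where(np.abs(s_gaze) > np.abs(s_eeg), s_gaze, s_eeg)
    else:
        deciding = scores[bundle.mode]
    return deciding <= theta


def classify(bundle: DetectorBundle, epoch: LabeledEpoch,
             theta: float | None = None) -> str:
    """Label one epoch correct/erroneous at threshold theta."""
    flag = decide(bundle, score_epochs(bundle, [epoch]), theta)[0]
    return ERRONEOUS if flag else CORRECT


def classify_epochs(bundle: DetectorBundle, epochs: list[LabeledEpoch],
                    theta: float | None = None) -> list[str]:
    flags = decide(bundle, score_epochs(bundle, epochs), theta)
    return [ERRONEOUS if f else CORRECT for f in flags]
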