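"""Discriminant spatial filtering of EEG epochs and gaze Hjorth features.

The EEG feature vector is the time course of a single *virtual sensor*:
the projection of the multichannel epoch through the spatial filter w
that maximizes the Fisher separability ratio

    J(w) = [w (X̄ - Ȳ)(X̄ - Ȳ)ᵀ wᵀ] / [w (C_X + C_Y) wᵀ]

between the class-average responses X̄ (erroneous) and Ȳ (correct),
where C_X and C_Y are the average within-class noise covariances.  The
maximizer is the leading generalized eigenvector of the pair
((X̄-Ȳ)(X̄-Ȳ)ᵀ, C_X + C_Y).  The filter is fitted on the full
[-0.2, 0.5) s window but applied only to the post-onset [0, 0.5) s
samples, where the error response lives.

Gaze epochs are summarized by the Hjorth descriptors of the accumulated
distance series: activity (variance), mobility (root variance ratio of
the derivative to the signal, an estimate of mean frequency) and
complexity (mobility of the derivative over mobility of the signal, a
bandwidth proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preprocessing import CORRECT, ERRONEOUS, LabeledEpoch

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Discriminant Spatial Pattern
# ---------------------------------------------------------------------------

@dataclass
class SpatialFilter:
    w: np.ndarray            # unit-norm channel weights
    Xbar: np.ndarray         # class-average erroneous response (ch x time)
    Ybar: np.ndarray         # class-average correct response
    Cx: np.ndarray           # average noise covariance, erroneous class
    Cy: np.ndarray
    fisher_value: float


def _class_stats(epochs_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class mean and average spatial noise covariance.

    ``epochs_data`` is (n_epochs, channels, time).  Noise is what remains
    after subtracting the class-mean response; its per-epoch spatial
    covariance over time samples, averaged across epochs, equals the
    pooled covariance of the centred, time-concatenated residuals.
    """
    mean = epochs_data.mean(axis=0)
    resid = epochs_data - mean
    n, c, t = resid.shape
    flat = resid.transpose(1, 0, 2).reshape(c, n * t)
    cov = flat @ flat.T / (n * t)
    return mean, cov


def fit_dsp(error_epochs: np.ndarray, correct_epochs: np.ndarray,
            eps_scale: float = 1e-6) -> SpatialFilter:
    """Fit the discriminant spatial filter from per-class epoch stacks.

    Parameters are (n_epochs, channels, time) arrays covering the full
    epoch window.  The weight vector is normalized to unit length and its
    sign fixed so the time-summed projected class difference is >= 0.
    Rank-deficient noise pools are handled by a small Tikhonov ridge
    proportional to the mean channel variance.
    """
    error_epochs = np.asarray(error_epochs, dtype=float)
    correct_epochs = np.asarray(correct_epochs, dtype=float)
    if error_epochs.shape[0] < 2 or correct_epochs.shape[0] < 2:
        raise ValueError("need at least 2 epochs per class")
    if error_epochs.shape[1] != correct_epochs.shape[1]:
        raise ValueError("channel sets differ between classes")

    Xbar, Cx = _class_stats(error_epochs)
    Ybar, Cy = _class_stats(correct_epochs)
    n_ch = Xbar.shape[0]

    if n_ch == 1:
        w = np.ones(1)
        diff = Xbar - Ybar
        denom = (Cx + Cy).item()
        if denom <= 0:
            denom = np.finfo(float).tiny
        return SpatialFilter(w=w, Xbar=Xbar, Ybar=Ybar, Cx=Cx, Cy=Cy,
                             fisher_value=(diff @ diff.T).item() / denom)

    diff = Xbar - Ybar
    S = diff @ diff.T
    noise = Cx + Cy
    ridge = eps_scale * np.trace(noise) / n_ch
    if np.linalg.matrix_rank(noise) < n_ch:
        logger.info("rank-deficient noise pool; ridge regularization applied")
    noise = noise + max(ridge, np.finfo(float).tiny) * np.eye(n_ch)

    eigvals, eigvecs = scipy.linalg.eigh(S, noise)
    w = eigvecs[:, -1]
    w = w / np.linalg.norm(w)
    if float(w @ diff.sum(axis=1)) < 0:
        w = -w
    return SpatialFilter(w=w, Xbar=Xbar, Ybar=Ybar, Cx=Cx, Cy=Cy,
                         fisher_value=float(max(eigvals[-1], 0.0)))


def rayleigh_quotient(filt: SpatialFilter, w: np.ndarray) -> float:
    """Fisher ratio achieved by an arbitrary unit vector under the
    filter's fitted statistics (used for oracle comparisons)."""
    diff = filt.Xbar - filt.Ybar
    num = float(w @ diff @ diff.T @ w)
    den = float(w @ (filt.Cx + filt.Cy) @ w)
    return num / den if den > 0 else np.inf


def apply_dsp(filt: SpatialFilter, epoch: LabeledEpoch | np.ndarray,
              n_pre: int | None = None, decimation: int = 1) -> np.ndarray:
    """Project an epoch onto the virtual sensor, post-onset part only.

    Returns the filtered [0, 0.5) s time course — 128 values at 256 Hz —
    optionally decimated by keeping every ``decimation``-th sample.
    """
    if isinstance(epoch, LabeledEpoch):
        data = epoch.eeg
        n_pre = epoch.n_pre
    else:
        data = np.asarray(epoch, dtype=float)
        if n_pre is None:
            raise ValueError("n_pre required for raw-array epochs")
    if data.shape[0] != filt.w.shape[0]:
        raise ValueError("channel mismatch between filter and epoch")
    virtual = filt.w @ data[:, n_pre:]
    return virtual[::decimation]


# ---------------------------------------------------------------------------
# Hjorth descriptors
# ---------------------------------------------------------------------------

@dataclass
class HjorthFeatures:
    activity: float
    mobility: float
    complexity: float
    degenerate: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array([self.activity, self.mobility, self.complexity])


def hjorth_descriptors(series: np.ndarray, rate: float) -> HjorthFeatures:
    """Hjorth activity, mobility and complexity of a time series.

    Derivatives are forward first differences scaled by the sampling
    rate; variances are population (biased) variances.  A constant
    series has zero activity and undefined mobility/complexity, reported
    as zeros with the degenerate flag set; a series with constant slope
    has well-defined mobility but degenerate complexity.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("series too short for Hjorth descriptors")
    var_x = float(np.var(x))
    if var_x == 0.0:
        return HjorthFeatures(0.0, 0.0, 0.0, degenerate=True)
    dx = np.diff(x) * rate
    var_dx = float(np.var(dx))
    mobility = float(np.sqrt(var_dx / var_x))
    if var_dx == 0.0:
        return HjorthFeatures(var_x, mobility, 0.0, degenerate=True)
    ddx = np.diff(dx) * rate
    var_ddx = float(np.var(ddx))
    mobility_dx = float(np.sqrt(var_ddx / var_dx))
    return HjorthFeatures(var_x, mobility, mobility_dx / mobility,
                          degenerate=False)


def gaze_feature_vector(epoch: LabeledEpoch) -> tuple[np.ndarray, bool]:
    """(activity, mobility, complexity) of the accumulated-distance
    series, with a degeneracy flag for constant-trajectory epochs."""
    feats = hjorth_descriptors(epoch.distance, epoch.gaze_rate)
    return feats.as_vector(), feats.degenerate


# ---------------------------------------------------------------------------
# Epoch stacking helpers
# ---------------------------------------------------------------------------

def stack_eeg(epochs: list[LabeledEpoch]) -> np.ndarray:
    """(n, channels, time) stack of epoch EEG matrices."""
    return np.stack([e.eeg for e in epochs])


def stack_distance(epochs: list[LabeledEpoch]) -> np.ndarray:
    """(n, time) stack of accumulated-distance series."""
    return np.stack([e.distance for e in epochs])


def split_by_label(epochs: list[LabeledEpoch]
                   ) -> tuple[list[LabeledEpoch], list[LabeledEpoch]]:
    """(erroneous, correct) partition; raises on unlabelled epochs."""
    err = [e for e in epochs if e.label == ERRONEOUS]
    cor = [e for e in epochs if e.label == CORRECT]
    if len(err) + len(cor) != len(epochs):
        raise ValueError("epochs must be labelled before feature extraction")
    return err, cor
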