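import numpy as np
import pytest

import eds
from eds.core_io import PipelineConfig
from eds.detection import fit_detector, score_epochs, decide
from eds.evaluation import (
    UtilityModel,
    confusion_metrics,
    direction_subaverages,
    loso_cv,
    monte_carlo_cv,
    threshold_sweep,
    utility_gain,
)

from conftest import separable_epochs, toy_epoch


class TestConfusionMetrics:
    def test_perfect(self):
        truth = ["erroneous"] * 3 + ["correct"] * 5
        assert confusion_metrics(truth, truth) == (1.0, 1.0, 1.0)

    def test_all_predicted_correct(self):
        truth = ["erroneous"] * 3 + ["correct"] * 5
        pred = ["correct"] * 8
        se, sp, acc = confusion_metrics(pred, truth)
        assert (se, sp) == (0.0, 1.0)
        assert acc == pytest.approx(5 / 8)

    def test_undefined_sensitivity_is_nan(self):
        se, sp, _ = confusion_metrics(["correct"], ["correct"])
        assert np.isnan(se) and sp == 1.0

    def test_random_counts_match_hand_computation(self):
        rng = np.random.default_rng(0)
        truth = np.where(rng.random(400) < 0.3, "erroneous", "correct")
        pred = np.where(rng.random(400) < 0.5, "erroneous", "correct")
        se, sp, acc = confusion_metrics(list(pred), list(truth))
        tp = sum(p == t == "erroneous" for p, t in zip(pred, truth))
        tn = sum(p == t == "correct" for p, t in zip(pred, truth))
        assert se == pytest.approx(tp / np.sum(truth == "erroneous"))
        assert sp == pytest.approx(tn / np.sum(truth == "correct"))
        assert acc == pytest.approx((tp + tn) / 400)


class TestUtilityGain:
    def test_eds_off_identity(self):
        assert utility_gain(UtilityModel(p=0.1, se=0.0, sp=1.0)) == 1.0

    def test_perfect_detector_gain(self):
        assert utility_gain(UtilityModel(p=0.1, se=1.0, sp=1.0)) == \
            pytest.approx(1.1)

    def test_strictly_increasing_in_se_and_sp(self):
        grid = np.linspace(0.0, 1.0, 11)
        gains_se = [utility_gain(UtilityModel(p=0.1, se=v, sp=0.9))
                    for v in grid]
        gains_sp = [utility_gain(UtilityModel(p=0.1, se=0.5, sp=v))
                    for v in grid]
        assert np.all(np.diff(gains_se) > 0)
        assert np.all(np.diff(gains_sp) > 0)

    def test_bounded_by_one_plus_p(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = UtilityModel(p=float(rng.uniform(0, 0.49)),
                             se=float(rng.random()), sp=float(rng.random()))
            assert utility_gain(m) <= 1.0 + m.p + 1e-12

    def test_specificity_dominates_at_reported_operating_point(self):
        """Near the published average operating point a unit of
        specificity buys more gain than a unit of sensitivity."""
        base = dict(p=0.1027, se=0.4177, sp=0.9840)
        g0 = utility_gain(UtilityModel(**base))
        assert g0 == pytest.approx(1.024, abs=5e-3)
        eps = 1e-4
        dse = (utility_gain(UtilityModel(**{**base, "se": base["se"] + eps}))
               - g0) / eps
        dsp = (utility_gain(UtilityModel(**{**base, "sp": base["sp"] + eps}))
               - g0) / eps
        assert dsp > dse > 0

    def test_selection_time_cancels(self):
        a = utility_gain(UtilityModel(p=0.2, se=0.6, sp=0.9,
                                      selection_time=1.0))
        b = utility_gain(UtilityModel(p=0.2, se=0.6, sp=0.9,
                                      selection_time=3.7))
        assert a == pytest.approx(b)

    def test_invalid_p(self):
        with pytest.raises(ValueError, match="p must"):
            UtilityModel(p=0.6, se=0.5, sp=0.5)


class TestMonteCarlo:
    def test_separable_toy_perfect(self):
        epochs = separable_epochs(n_err=14, n_cor=60, seed=1)
        res = monte_carlo_cv(epochs, "gaze", reps=5, seed=0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_reps_honoured_and_ratio_preserved(self):
        epochs = separable_epochs(n_err=14, n_cor=60, seed=1)
        res = monte_carlo_cv(epochs, "gaze", reps=7, seed=0)
        assert res.reps == 7
        assert all(v.size == 7 for v in res.per_rep.values())
        p_hat = 14 / 74
        assert res.n_test_erroneous == 10
        assert res.n_test_correct == int(np.round(10 * (1 - p_hat) / p_hat))

    def test_insufficient_minority(self):
        epochs = separable_epochs(n_err=8, n_cor=40, seed=1)
        with pytest.raises(ValueError, match="insufficient minority"):
            monte_carlo_cv(epochs, "gaze", reps=2, seed=0)

    def test_permuted_labels_at_chance(self, small_epochs):
        """Permutation null: with labels re-shuffled on every draw,
        accuracy matches the level expected under prediction/truth
        independence within 3 SEs."""
        rng = np.random.default_rng(0)
        reps, diffs = 15, []
        for rep in range(reps):
            labs = rng.permutation([e.label for e in small_epochs])
            epochs = [toy_epoch(l, i, rng, eeg=e.eeg, distance=e.distance)
                      for i, (e, l) in enumerate(zip(small_epochs, labs))]
            labels = np.asarray(labs)
            err = np.flatnonzero(labels == "erroneous")
            cor = np.flatnonzero(labels == "correct")
            test_idx = np.concatenate([rng.choice(err, 10, replace=False),
                                       rng.choice(cor, 90, replace=False)])
            mask = np.zeros(labels.size, bool)
            mask[test_idx] = True
            train = [epochs[i] for i in np.flatnonzero(~mask)]
            bundle = fit_detector(train, "gaze", seed=rep)
            test = [epochs[i] for i in test_idx]
            truth = np.asarray([e.label for e in test])
            flags = decide(bundle, score_epochs(bundle, test))
            acc = np.mean((flags & (truth == "erroneous"))
                          | (~flags & (truth == "correct")))
            q, p = flags.mean(), 0.1
            diffs.append(acc - (q * p + (1 - q) * (1 - p)))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(reps)
        assert abs(diffs.mean()) < 3 * max(se, 1e-3)


@pytest.fixture(scope="module")
def sweep(small_epochs):
    return threshold_sweep(small_epochs, "late", reps=6, seed=0)


class TestThresholdSweep:
    def test_endpoints_included(self, sweep):
        assert sweep.grid[0] == -1.0 and sweep.grid[-1] == 1.0
        assert sweep.grid.size == 41

    def test_monotone_tradeoff(self, sweep):
        assert np.all(np.diff(sweep.sensitivity) >= -1e-12)
        assert np.all(np.diff(sweep.specificity) <= 1e-12)

    def test_gain_optimum_favours_specificity(self, sweep):
        """At high SNR the utility-optimal threshold is not above 0."""
        assert sweep.best_theta <= 0.0
        assert sweep.best_gain > 1.0


class TestLoso:
    def test_identical_separable_sessions_perfect(self, spec10):
        """Two bit-identical high-SNR sessions: training on one predicts
        the other perfectly (train and test features coincide)."""
        sessions = [eds.simulate_session("a quick brown fox jumps over it.",
                                         spec10, sentence_id="s0")
                    for _ in range(2)]
        folds = loso_cv(sessions, "late", seed=0)
        for fold in folds:
            assert fold.predicted == [e.label for e in fold.epochs]

    def test_replay_oracle(self, spec10):
        """Fold predictions equal a manual train-on-rest / predict
        replay with the same derived seed."""
        sessions = [eds.simulate_session(t, spec10, sentence_id=f"s{i}")
                    for i, t in enumerate(eds.DEFAULT_SENTENCES[:3])]
        config = PipelineConfig()
        folds = loso_cv(sessions, "eeg", config=config, seed=4)
        prepared = [eds.prepare_session(s) for s in sessions]
        children = np.random.SeedSequence(4).spawn(3)
        i = 1
        rng = np.random.default_rng(children[i])
        bundle = fit_detector(prepared[0] + prepared[2], "eeg", config,
                              seed=int(rng.integers(2**31 - 1)))
        flags = decide(bundle, score_epochs(bundle, prepared[i]), None)
        manual = ["erroneous" if f else "correct" for f in flags]
        assert manual == folds[i].predicted

    def test_needs_two_sessions(self, spec10):
        with pytest.raises(ValueError, match="at least 2"):
            loso_cv([eds.simulate_session("a.", spec10)], "eeg")


class TestDirectionSubaverages:
    def _epochs_with_displacement(self, disps, rng, eeg_bump=None):
        out = []
        for i, (dx, dy) in enumerate(disps):
            e = toy_epoch("correct", i, rng, n_channels=64)
            e.gaze_x = np.linspace(0.0, dx, 21) + rng.normal(0, 1, 21)
            e.gaze_y = np.linspace(0.0, dy, 21) + rng.normal(0, 1, 21)
            e.distance = eds.accumulated_distance(e.gaze_x, e.gaze_y)
            if eeg_bump is not None:
                e.eeg = 0.05 * rng.standard_normal((64, 179)) + eeg_bump
            out.append(e)
        return out

    def test_planted_compass_clusters_recovered(self):
        rng = np.random.default_rng(0)
        compass = [(300, 0), (-300, 0), (0, 300), (0, -300)]
        truth = np.repeat(np.arange(4), 10)
        disps = [compass[g] for g in truth]
        epochs = self._epochs_with_displacement(disps, rng)
        groups = direction_subaverages(epochs, k=4, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, groups.membership) == 1.0

    def test_k_one_is_grand_average(self):
        rng = np.random.default_rng(1)
        epochs = self._epochs_with_displacement(
            [(100, 0), (-100, 0), (0, 100)], rng)
        groups = direction_subaverages(epochs, k=1, seed=0)
        grand = np.stack([e.eeg[30] for e in epochs]).mean(axis=0)
        assert np.allclose(groups.eeg_traces[0], grand)

    def test_no_polarity_inversion_without_artefact(self):
        """Direction-independent EEG: the dominant deflection keeps its
        sign across left/right groups (the no-contamination signature)."""
        rng = np.random.default_rng(2)
        bump = np.zeros((64, 179))
        bump[30] = np.exp(-0.5 * ((np.arange(179) - 102) / 10.0) ** 2)
        disps = [(300, 0)] * 12 + [(-300, 0)] * 12
        epochs = self._epochs_with_displacement(disps, rng, eeg_bump=bump)
        groups = direction_subaverages(epochs, k=2, seed=0)
        peaks = groups.eeg_traces[:, 90:115].max(axis=1)
        assert np.all(peaks > 0.5)

    def test_k_exceeds_n(self):
        rng = np.random.default_rng(3)
        epochs = self._epochs_with_displacement([(1, 1)], rng)
        with pytest.raises(ValueError, match="k exceeds"):
            direction_subaverages(epochs, k=4)
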