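import numpy as np
import pytest

import eds
from eds.preprocessing import epochize
from eds.synthetic_data import (
    make_erp_template,
    key_neighbours,
    simulate_eeg,
    simulate_gaze,
    simulate_typing,
)


@pytest.fixture(scope="module")
def spec():
    return eds.SimulationSpec(seed=3)


class TestErpTemplates:
    @pytest.mark.parametrize("kind,neg_win,pos_win", [
        ("error", (0.25, 0.35), (0.35, 0.45)),
        ("correct", (0.25, 0.35), (0.15, 0.25)),
    ])
    def test_extrema_latencies(self, spec, kind, neg_win, pos_win):
        """Dominant-channel deflections sit at the published latencies."""
        tpl = make_erp_template(kind, spec)
        ch = tpl.channel_names.index(tpl.dominant_channel)
        t = np.arange(tpl.waveform.shape[1]) / tpl.rate
        wave = tpl.waveform[ch]
        t_min = t[np.argmin(wave)]
        t_max = t[np.argmax(wave)]
        assert neg_win[0] <= t_min <= neg_win[1] and wave.min() < 0
        assert pos_win[0] <= t_max <= pos_win[1] and wave.max() > 0

    def test_deterministic(self, spec):
        a = make_erp_template("error", spec)
        b = make_erp_template("error", spec)
        assert np.array_equal(a.waveform, b.waveform)

    def test_unknown_kind(self, spec):
        with pytest.raises(ValueError, match="unknown template kind"):
            make_erp_template("neutral", spec)


class TestSimulateTyping:
    def test_p_zero_types_exactly(self):
        spec = eds.SimulationSpec(seed=1, mistype_probability=0.0)
        trace = simulate_typing("the cat sleeps.", spec)
        assert trace.typed == "the cat sleeps."
        assert not any(trace.error_flags)

    def test_insertion_fraction_binomial(self):
        """Mistype fraction over ~10k presses within 3 binomial SEs of p."""
        p = 0.1
        spec = eds.SimulationSpec(seed=5, mistype_probability=p)
        intended = ("the quick brown fox jumps over the lazy dog. " * 200
                    ).strip()
        trace = simulate_typing(intended, spec)
        flags = np.array(trace.error_flags)
        n = flags.size
        assert n > 9000
        se = np.sqrt(p * (1 - p) / n)
        assert abs(flags.mean() - p) < 3 * se

    def test_intended_is_subsequence(self, spec):
        trace = simulate_typing("she sells sea shells.", spec)
        it = iter(trace.typed)
        assert all(ch in it for ch in "she sells sea shells.")

    def test_regular_mode_backspace_replay(self):
        spec = eds.SimulationSpec(seed=2, mistype_probability=0.2)
        intended = "a gentle wind moved the tall grass."
        trace = simulate_typing(intended, spec, mode=eds.REGULAR)
        for prev, cur in zip(trace.presses, trace.presses[1:]):
            if prev.error:
                assert cur.is_backspace
        committed = []
        for press in trace.presses:
            if press.is_backspace:
                committed.pop()
            else:
                committed.append(press.key)
        assert "".join(committed) == intended

    def test_error_rate_too_high_refused(self):
        with pytest.raises(ValueError, match="error rate too high"):
            eds.SimulationSpec(mistype_probability=0.6)

    def test_wrong_keys_are_neighbours(self):
        spec = eds.SimulationSpec(seed=9, mistype_probability=0.3)
        trace = simulate_typing("winter nights are long and cold.", spec)
        for press in trace.presses:
            if press.error:
                assert press.key in key_neighbours(spec.layout, press.target)


class TestSimulateGaze:
    def test_single_key_pure_jitter(self):
        spec = eds.SimulationSpec(seed=4)
        trace = simulate_typing("a.", eds.SimulationSpec(
            seed=4, mistype_probability=0.0))
        trace.presses = trace.presses[:1]
        gaze = simulate_gaze(trace, spec, duration=1.2)
        d = eds.accumulated_distance(gaze.x[-15:], gaze.y[-15:])
        # accumulated jitter of ~15 steps with per-axis sd 3 px
        assert d[-1] < 15 * 6 * spec.fixation_jitter_sd

    def test_zero_jitter_stationary(self):
        spec = eds.SimulationSpec(seed=4, fixation_jitter_sd=0.0)
        trace = simulate_typing("a.", eds.SimulationSpec(
            seed=4, mistype_probability=0.0))
        trace.presses = trace.presses[:1]
        gaze = simulate_gaze(trace, spec, duration=0.6)
        assert np.ptp(gaze.x) == 0 and np.ptp(gaze.y) == 0

    def test_correct_presses_move_more(self):
        """Post-event gaze displacement: correct >> erroneous (many
        presses), mirroring the averaged eye-speed traces."""
        spec = eds.SimulationSpec(seed=11, mistype_probability=0.25, snr=0.0)
        intended = ("the moon rose over the quiet lake. " * 20).strip()
        session = eds.simulate_session(intended, spec)
        epochs = epochize(session)
        flags = session.ground_truth.error_flags
        assert len(epochs) == len(flags) and sum(flags) > 100
        n_pre = 6  # 30 Hz samples before the onset
        disp = np.array([e.distance[-1] - e.distance[n_pre] for e in epochs])
        flags = np.asarray(flags)
        assert disp[~flags].mean() > 3 * disp[flags].mean()


class TestSimulateEEG:
    def _epoch_averages(self, spec, intended):
        session = eds.simulate_session(intended, spec)
        epochs = epochize(session)
        flags = np.asarray(session.ground_truth.error_flags)
        stack = np.stack([e.eeg for e in epochs])
        return stack[flags], stack[~flags]

    def test_snr_zero_no_class_difference(self):
        spec = eds.SimulationSpec(seed=21, mistype_probability=0.3, snr=0.0)
        intended = ("children play chess in the park. " * 12).strip()
        err, cor = self._epoch_averages(spec, intended)
        cz = eds.CHANNEL_NAMES_64.index("Cz")
        diff = err[:, cz].mean(axis=0) - cor[:, cz].mean(axis=0)
        floor = 3 * spec.noise_scale * np.sqrt(1 / len(err) + 1 / len(cor))
        assert np.abs(diff).max() < 3 * floor

    def test_high_snr_average_recovers_template(self):
        """Event-locked averaging over 100+ error epochs reproduces the
        template shape on the dominant channel (r > 0.95)."""
        spec = eds.SimulationSpec(seed=22, mistype_probability=0.3, snr=10.0)
        intended = ("coffee smells better than it tastes. " * 12).strip()
        err, _ = self._epoch_averages(spec, intended)
        assert len(err) >= 100
        tpl = make_erp_template("error", spec)
        ch = tpl.channel_names.index(tpl.dominant_channel)
        avg = err[:, ch].mean(axis=0)[51:]  # post-onset part
        r = np.corrcoef(avg, tpl.waveform[ch])[0, 1]
        assert r > 0.95

    def test_template_rate_mismatch(self, spec):
        trace = simulate_typing("a.", spec)
        bad = make_erp_template("error",
                                eds.SimulationSpec(seed=0, eeg_rate=128.0))
        with pytest.raises(ValueError, match="rate mismatch"):
            simulate_eeg(trace, {"error": bad, "correct": bad}, spec)


class TestSessionComposition:
    def test_determinism_bit_identical(self):
        spec = eds.SimulationSpec(seed=13, snr=1.0)
        a = eds.simulate_session("her garden is full of roses.", spec)
        b = eds.simulate_session("her garden is full of roses.", spec)
        assert np.array_equal(a.eeg.samples, b.eeg.samples)
        assert np.array_equal(a.gaze.x, b.gaze.x)
        assert [e.onset for e in a.events] == [e.onset for e in b.events]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ground_truth_matches_labels(self, seed):
        """Ground-truth mistype flags equal the retry-rule labels."""
        spec = eds.SimulationSpec(seed=seed, mistype_probability=0.15)
        session = eds.simulate_session("two trains left the old station.",
                                       spec)
        labels = eds.label_key_events(session.intended, session.typed)
        truth = ["erroneous" if f else "correct"
                 for f in session.ground_truth.error_flags]
        assert labels == truth

    def test_regular_mode_commits_intended(self):
        spec = eds.SimulationSpec(seed=17, mistype_probability=0.2)
        session = eds.simulate_session("music filled the empty hall.", spec,
                                       mode=eds.REGULAR)
        assert session.committed == session.intended


def test_detector_accuracy_monotone_in_snr():
    """Separability dial: detection accuracy rises with template SNR
    (3-seed majority over adjacent SNR pairs)."""
    from eds.evaluation import monte_carlo_cv
    snrs = [0.0, 1.0, 3.0, 10.0]
    texts = eds.DEFAULT_SENTENCES[:5]
    acc = np.zeros((3, len(snrs)))
    for s, seed in enumerate([0, 1, 2]):
        for j, snr in enumerate(snrs):
            spec = eds.SimulationSpec(seed=seed, snr=snr,
                                      mistype_probability=0.15,
                                      uninformative_gaze=True)
            epochs = [e for i, txt in enumerate(texts)
                      for e in eds.prepare_session(
                          eds.simulate_session(txt, spec,
                                               sentence_id=f"s{i}"))]
            res = monte_carlo_cv(epochs, "eeg", reps=8, seed=seed)
            acc[s, j] = (res.sensitivity + res.specificity) / 2
    for j in range(len(snrs) - 1):
        ordered = np.sum(acc[:, j + 1] >= acc[:, j] - 0.02)
        assert ordered >= 2, (snrs[j], acc[:, j], acc[:, j + 1])
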