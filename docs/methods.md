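# Methods

This note records the modelling and numerical choices behind `eds`,
what the synthetic generator does and does not emulate, and the
problem sizes the tests run at.

## Session model and epoching

All streams share one session clock in seconds.  The time-lock of
every analysis is the *key registration*: the instant a key commits
after 0.5 s of continuous fixation.  Epochs span `[-0.2, 0.5)` s
around it under a half-open convention with 0-based sample indexing:
an epoch holds `floor(0.7·rate)` samples (179 at 256 Hz, 21 at 30 Hz),
aligned so that sample `floor(0.2·rate)` is the sample nearest the
onset.  This removes the off-by-one ambiguity of a closed window and
makes the post-onset block exactly `floor(0.5·rate)` samples (128 at
256 Hz), which is the EEG feature length.  Epochs whose window leaves
either recording are dropped with a warning.  Backspace presses are
never epoched: the error-aware protocol bans backspace, and only
letter registrations elicit the responses of interest.

Gaze is linearly resampled onto the epoch grid; an epoch is dropped if
the window overlaps a gap longer than two nominal sample intervals
(beyond that, interpolation would fabricate the trajectory the Hjorth
descriptors summarize).

Filtering is a 4th-order Butterworth band-pass (1–16 Hz) applied
forward and backward (`sosfiltfilt`): effective 8th order, zero phase,
so ErrP latencies are not shifted.

## Labelling

The retry rule is a greedy left-to-right scan with a pointer into the
intended text; only a match advances the pointer.  If the pointer has
not consumed the intended text at the end, the session violated the
protocol and labelling refuses.  For insertion-only differences the
number of erroneous labels equals the Levenshtein distance between
typed and intended text, which the tests cross-check via an
independent implementation.

## Discriminant spatial filter

The filter maximizes the Fisher ratio between the class-mean
difference energy and the pooled noise covariance.  Choices:

* *Noise covariance:* per-epoch spatial covariance (over time samples)
  of the epoch minus its class mean, averaged over epochs — computed
  on the full `[-0.2, 0.5)` fit window.  Because every epoch is
  centred by the same class mean, this equals the pooled covariance of
  the time-concatenated residuals, which is how it is computed.
* *Regularization:* Tikhonov ridge `1e-6 · trace/channels` added to
  `C_X + C_Y`, so rank-deficient pools (few epochs, or SMOTE
  duplicates) stay solvable; the generalized eigenproblem is solved
  with `scipy.linalg.eigh`.
* *One component:* only the leading eigenvector is used; `w` is
  unit-norm with its sign fixed so the time-summed projected class
  difference is non-negative.  The degenerate single-channel case
  returns the scalar filter 1.
* The filter is fitted on the full window but applied to the
  post-onset `[0, 0.5)` samples only, where the error response lives.

## Hjorth descriptors

Derivatives are forward first differences scaled by the sampling rate;
variances are population (biased) variances.  This fixes the
otherwise unit-free magnitudes: for a sinusoid of frequency f the
mobility converges to 2πf in the dense-sampling limit.  Degenerate
inputs are handled explicitly: a constant series has zero activity and
undefined mobility/complexity (reported as zeros plus a flag, mapped
downstream to a zero feature vector); a constant-slope series has
well-defined zero mobility but degenerate complexity.

## Class balancing and classification

SMOTE grows the minority class until both classes are equal, *before*
any label-driven fitting, on the raw per-modality representations:
vectorized band-passed EEG epochs and, separately, gaze
accumulated-distance series.  Each synthetic instance is
`x + u·(x_nn − x)` with `u ~ U(0,1)` and `x_nn` one of the k = 5
nearest minority neighbours (k shrinks to n−1 for tiny minorities; a
singleton minority duplicates with a warning).  For the fusion modes
the two modalities are balanced independently with separate seeded
streams and synthetic instances paired by position; synthetic rows are
only ever training material, so the pairing carries no test-time
meaning.

SVMs are linear (`SVC(kernel="linear")`, C = 1, no class weights —
imbalance is already handled by SMOTE) on z-scored features;
zero-variance features pass through unscaled and receive zero weight.
Scores are decision values divided by the maximum absolute *training*
decision value, so train scores span `[-1, 1]`; test scores may exceed
the interval and are not clipped.  Positive scores are evidence for a
correct press — this orientation makes lowering θ raise specificity,
which is the direction the utility metric rewards.  Late fusion
selects the modality with the larger |score| (ties, a measure-zero
event, go to EEG) and thresholds the winner.

All fitting — SMOTE, spatial filter, normalization, SVMs, score
scales — sees training data only; the test suite verifies the fitted
bundle is bit-identical under arbitrary corruption of held-out data.

## Evaluation

Monte-Carlo cross-validation draws, per repetition, 10 erroneous
epochs plus enough correct ones to preserve the empirical class ratio,
trains on the remainder and evaluates at θ; a master seed spawns
per-repetition seeds.  The threshold sweep fits once per repetition
and thresholds the held-out scores over the grid (step 0.05, endpoints
±1 included), so the per-repetition sensitivity/specificity curves are
monotone in θ by construction.  `p̂` in the sweep's gain is the
dataset's empirical mistype fraction.

### Utility model

The utility of a keyboard is its expected net correct characters per
unit time.  Under a renewal model in which every key selection costs
the same nominal time `T_s`:

* regular keyboard — a mistype (probability p) must be undone by one
  backspace: utility `(1−p) / ((1+p)·T_s)`;
* error-aware keyboard — detected mistypes (`p·se`) are auto-deleted
  at no extra selection, missed ones (`p·(1−se)`) still cost a
  backspace, and a falsely deleted correct press (`(1−p)(1−sp)`)
  wastes its selection: utility `(1−p)·sp / ((1 + p·(1−se))·T_s)`.

The gain `sp·(1+p)/(1+p·(1−se))` is 1 when the detector never
intervenes (se = 0, sp = 1), strictly increasing in both rates, capped
at `1+p`, and independent of `T_s`.  This is a deliberately simple
surrogate for information-theoretic utility formulations; it assumes
identical letter and backspace press times and error-free backspaces.
Its role here is ranking operating points, not predicting absolute
speeds — the LOSO timing simulation, which uses empirical press times,
is the quantitative statement.

### Timing

`b_avg` and `l_avg` are estimated as the mean inter-press interval
ending in a backspace (resp. letter) registration over a subject's
regular-control recordings — the estimator itself is a package choice,
since only the totals formulas are fixed.  The T2 edit distance is
computed from the control recording's own committed text (typically 0,
since the control protocol requires finishing the sentence correctly);
the T1 formula uses the error-aware recording's typed text.  `t1`
already contains the retypes forced by the retry protocol, so detected
errors are not additionally penalized.

## Synthetic sessions

The generator emulates exactly the structure the pipeline assumes:

* *Typing:* per press, with probability p (default 0.1) the registered
  key is drawn uniformly from the 8-neighbourhood of the target on a
  QWERTY layout of 100-px keys — modelling tracker misreads of
  adjacent keys.  Error-aware mode leaves the mistype and retries;
  regular mode inserts an immediate backspace.  Onsets advance by the
  dwell (0.5 s) plus a log-normal overhead with distinct medians for
  letters (0.35 s) and backspace (0.6 s, σ = 0.35 in log space) —
  sentence spans then land near 25–30 s, a realistic per-sentence
  time, and backspaces are slower than letters as empirical press
  times suggest.
* *EEG:* class-specific templates built from Gaussian-windowed bumps
  with fixed frontocentral / centro-parietal / central scalp-weight
  tables (documented constants, not fitted): error = −1.0 bump at
  300 ms (frontocentral) + 0.8 bump at 400 ms (centro-parietal);
  correct = +0.7 at 200 ms and −0.6 at 300 ms (central).  Templates
  are added at each onset to spatially correlated 1/f noise (fixed
  random mixing of independent 1/f sources, exponent 1, spectrum
  flattened below 0.5 Hz), scaled by `snr · noise_scale`.  The default
  `snr = 1` reflects that single-trial ErrPs sit at or below the
  background amplitude; end-to-end recovery tests use `snr = 10`,
  where event-locked averaging visibly reproduces the template.
* *Gaze:* a waypoint model — fixation on each press's key through its
  dwell, release 0.1 s after registration, linear travel at 2000 px/s
  to the next fixation; after a mistype the next fixation is the same
  key (small adjustment), after a correct press it is the next
  character's key (large saccade).  Gaussian fixation jitter (3 px sd)
  everywhere.  An `uninformative_gaze` switch replaces the trace with
  an event-independent random walk for null experiments.

Determinism: one spec seed plus stable per-(subject, sentence, mode)
identifiers derive independent streams for typing, gaze and EEG, so
sessions are bit-reproducible.

What the generator does **not** emulate: volume-conducted ocular
artefacts, blinks/EMG, latency jitter of the ErrP, template amplitude
variability, head-model-based scalp topographies, or tracker dropout.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour as separability varies — not the classification rates
attainable on recorded human data, whose template amplitudes are
unknown to the generator.

## Problem sizes in the test suite

Unit tests run on toy constructions and 5–8 simulated sentences; the
end-to-end recovery tests use the full default subject (20 sentences,
~700 presses, ~70 mistypes) with 100 Monte-Carlo repetitions, a
30-repetition null at SNR 0, and a 20-fold LOSO timing simulation.
The grid-search oracle for the spatial filter checks 50 random
problems of up to 4 channels against 5000 random unit directions.
Session bundles serialize floats with 12 significant digits, keeping
round-trip deviations below 1e-9 for microvolt/pixel-range signals.

## Known limitations

* The utility surrogate is not calibrated against any specific
  published utility formula; only its identities and monotonicities
  are asserted.
* SMOTE pairing across modalities is positional, not geometric.
* Per-sentence timing gains are noisy because the error-aware and
  control recordings draw their mistypes independently; means over a
  full 20-sentence subject are the meaningful quantity.
* The epoching assumes regularly sampled EEG; gaze may be irregular
  but only mildly gappy.
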