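# Methods

## Model

`sleephmm` scores rodent polysomnography (anterior EEG, posterior EEG,
EMG; optionally LFP) into awake / NREM / REM at a configurable epoch
resolution (default 1 s). The classifier is a supervised Gaussian-emission
hidden Markov model on a two-dimensional linear-discriminant projection of
normalized multitaper spectra. All parameters are estimated in closed form
from labelled training data; there is no EM iteration, no optimizer and no
free parameter beyond the epoch resolution.

**Preprocessing.** Each channel is cut into non-overlapping epochs and
converted to a multitaper power spectral density (via
`mne.time_frequency.psd_array_multitaper`; 1-s segments give a 1-Hz grid
from 0 to the Nyquist frequency; library defaults otherwise, effectively a
time-half-bandwidth product of 4 with 7 DPSS tapers — recorded in the
model archive). Frequency bins inside the exclusion bands [0, 0.5] Hz
(locomotion drift), [45, 55] Hz (mains interference) and [90, Nyquist] Hz
are dropped, leaving 78 of 129 bins per channel at 256 Hz; band bounds are
treated as inclusive, and the same masks apply to every channel, EMG
included. Power is mapped through log(x + 1) — EEG/EMG band power is
approximately exponential, so the transform moves it toward normality —
and each frequency bin is standardized to z-scores. Standardization
statistics are computed **per recording** over its non-excluded epochs, so
a test recording never needs training-set statistics; zero-variance bins
map to zero. Channels are concatenated in the configured order (234
features for three channels).

**Feature extraction.** LDA (scikit-learn, eigen solver, no shrinkage)
projects the features onto K − 1 components. The projection weights,
class means, and log priors are stored directly, and classification is
re-expressed as nearest class mean plus log prior in the whitened
discriminant space (which the eigen solver guarantees); ties break to the
fixed state order awake < NREM < REM. This re-expression makes the fitted
projection fully serializable to JSON and its decision rule exactly
reproducible; a test cross-checks it against scikit-learn's own
`predict`.

**HMM.** Emission parameters are per-state sample means and covariances
of the projected training epochs; each covariance receives diagonal
jitter of 10⁻⁶ × (mean diagonal) so degenerate states keep an evaluable
density. The transition matrix is the count-normalized empirical
transition frequency at epoch resolution, pooled across training
recordings without counting across recording boundaries; off-diagonal
entries with per-second probability below 10⁻⁴ are then zeroed and rows
renormalized (pruning after the MLE, not before — the alternative order is
isolated in `prune_transition_matrix` should sensitivity testing be
needed). The initial distribution is the empirical state occupancy rather
than first-epoch frequencies: a handful of training recordings provides
only a handful of first epochs. Decoding uses the Viterbi algorithm in the
log domain (ties to the lowest state index) and scaled forward–backward
recursions for the per-epoch marginals; both are validated against
exhaustive path enumeration on small instances and survive 10⁵-epoch
sequences without underflow. Per-sample state probabilities are smoothing
marginals: with supervised training there is nothing for Baum-Welch
re-estimation to do, and the forward–backward pass is the step of that
algorithm that yields per-sample probabilities.

**Certainty and intermediate states.** The certainty of an epoch is the
marginal probability of its Viterbi-decoded state (an argmax-of-posterior
variant is a one-line change in `PosteriorSequence.certainty`). The
default threshold is θ = 0.995, the change point of the certainty CDF in
the original analysis of this method; 0.95 is the conservative variant,
and an `elbow` mode locates the knee of the empirical CDF as the point of
maximum perpendicular distance from the end-to-end chord. The CDF is
taken over unique certainty values so that a point mass at 1.0 (a vertical
riser) cannot masquerade as the knee; if all certainties are equal the
elbow is undefined and the fixed value is returned with a warning.
Maximal runs of sub-threshold epochs are classified by their decoded
context: decoded state differs across the run → transition-adjacent;
identical before, inside and after → failed transition toward the
runner-up state by mean within-interval posterior (if the runner-up does
not strictly beat the third state the target is recorded as "mixed");
runs touching the recording boundary are left unclassified. The exact
operational definition of "failed transition" admits more than one
reading; this one — a reverting excursion of the posterior — lives in a
single function for easy revision. No cap is imposed on interval duration.
Failure rates (failed / (failed + successful)) are compared across
transition types with 2×2 χ² contingency tests without continuity
correction; comparisons with an empty margin are skipped with a notice.

**Artefacts.** Clipping artefacts are runs of samples at or beyond the
amplifier's dynamic-range limits, padded by a configurable 1 s on each
side (the deflections flanking a clipped run are usually also corrupted)
and merged. Ambiguous intervals are ranked for human review by descending
residual score Σ(1 − certainty), ties by start time.

## Handling of excluded epochs

Recordings may lack samples in their first and/or last 30 s (electrode
connection periods); such epochs are flagged, excluded from all fitting
and carry no state label in predictions. Epochs labelled `ambiguous` or
`artefact` are likewise excluded from LDA, emission and transition
estimation — in this package's hypnogram vocabulary those labels *replace*
the state label, so there is no vigilance class under which to include
them (in the original workflow artefact epochs retained their state label
and were included in training; with the synthetic benchmark, which
generates no artefact labels, the two conventions coincide). Transition
counting treats excluded epochs as chain breaks. In evaluation, epochs
whose *reference* label is ambiguous/artefact are excluded, while a
prediction of an excluded class against a definite reference counts as an
error.

## Synthetic benchmark

The generator emulates the study conditions rather than biophysics: no
cortical dynamics, no spindle waveform morphology, no within-epoch
nonstationarity — band power statistics only.

* **Hypnograms.** First-order Markov chain at 1-s resolution with
  transition matrix rows awake (0.990, 0.010, 0), NREM (0.012, 0.984,
  0.004), REM (0.013, 0.001, 0.986). Its stationary distribution is
  exactly 55% / 35% / 10% (awake/NREM/REM), the occupancy regime of
  baseline mouse recordings; mean bout durations are ≈100 s (awake),
  ≈63 s (NREM) and ≈71 s (REM); direct awake→REM transitions are absent,
  as in wild-type mice; REM ends mostly into wake, rarely directly into
  NREM.
* **Signals.** Each epoch is band-limited Gaussian noise synthesized in
  the frequency domain with a state- and channel-specific amplitude
  spectrum on a shared 1/f background: NREM has strong 0.5–4 Hz slow
  waves plus a 10–15 Hz spindle band (strongest anteriorly), REM has
  5–10 Hz theta (strongest posteriorly), wake has mild high-frequency EEG
  content and high broadband EMG; EMG amplitude orders wake > NREM > REM.
  Amplitudes are on a µV-like scale.
* **Difficulties.** `easy` uses constant within-state amplitudes and low
  broadband noise: states form well-separated LDA clusters and the
  pipeline should be near-perfect. `hard` shrinks the discriminative band
  amplitudes (×0.35), raises broadband noise, halves the EMG contrast and
  multiplies the state-specific component of each epoch by a lognormal
  gain (log-sd 1.0) — real EEG band power fluctuates roughly lognormally
  between epochs — so single-epoch classification operates in the ~90–95%
  accuracy regime typical of context-free classifiers, temporal context
  is genuinely informative, and a few percent of epochs fall below the
  0.995 certainty threshold. `hard` additionally splices brief (2–5 s)
  wake passages into every REM→NREM transition, reproducing the brief
  awakenings mice show between REM and NREM sleep.

Passing tests on this benchmark demonstrate the machinery (estimation,
decoding, certainty, interval classification) under controlled
conditions; they do not certify accuracy on real recordings, whose
artefacts, drift and inter-animal variability the generator does not
model.

## Problem sizes and numerical choices

End-to-end checks run at desk scale, chosen as the smallest sizes at
which the statistical properties are stable: hold-one-out on six 2-h easy
recordings (accuracy ≥ 0.95 expected), baseline ordering (HMM > naive
Bayes, HMM > per-epoch LDA) and certainty masking on six 1-h hard
recordings, and the label-permutation robustness curve on four 1-h easy
recordings at fractions 0 / 0.5 / 0.9. The permutation experiment itself
(shuffling the labels of a fraction f of epochs among themselves changes
an expected f·(1 − Σ pᵢ²) of labels; ≈6% / 28% / 51% at f = 0.1 / 0.5 /
0.9 under 55/35/10 occupancies) uses 100,000-epoch sequences averaged
over 10 seeds.

Tolerances: posterior rows sum to 1 within 10⁻⁹ and marginals match
enumeration within 10⁻⁹; z-scored columns have mean/variance within 10⁻⁶;
EDF round trips are exact up to the int16 quantization step of each
channel's physical range. The multitaper estimate is biased low within
one taper half-bandwidth (4 Hz) of the DC edge — a property of one-sided
PSD estimation, visible in the white-noise flatness test and harmless
downstream since the per-bin z-scoring absorbs static bias. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
training itself is deterministic.

## Known limitations

* EDF support is minimal: single-rate signals, no EDF+ annotations
  channel; the bundled writer exists chiefly so the synthetic benchmark
  can exercise the real reader.
* Missing-sample detection on read is heuristic (leading/trailing runs
  that are constant on every channel for ≥1 s within the 30-s edge
  allowance), since EDF cannot represent missing values explicitly.
* The consensus operation implements strict-majority voting only; no
  confidence weighting or annotator bias modelling.
* Emissions are single Gaussians per state; mixture or discrete
  emissions, unsupervised training and higher-order chains are out of
  scope.
* Reported failure-rate percentages in the literature on real recordings
  are data-dependent and are not reproduced by the synthetic benchmark;
  only the machinery that computes them is validated.
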