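# Methods

## The decoding problem

A subject holds a manipulandum, receives a visual cue naming one of four
center-out targets (up, down, left, right), waits at least 2 s, and
moves at a self-chosen moment.  The question the pipeline answers is
whether — and how early — the upcoming movement's direction can be read
from single-trial EEG before movement onset, and whether that readout is
specific to movement preparation (it must not fire during the idle
period after the cue, when the subject is resting).

## Signal chain

Order of operations on the continuous recording:

1. discard trials with cue-to-onset latency < 2 s (early starts);
2. restrict to the analysis montage (default 34 central electrodes of
   the extended 10/20 grid; the list is configurable because peripheral
   and EOG-contaminated channels are montage-specific);
3. common average reference (CAR): subtract the instantaneous mean over
   the retained channels;
4. zero-phase Butterworth low-pass at 120 Hz (order 4, forward–backward
   through second-order sections);
5. decimate to the 128 Hz analysis rate.  No extra anti-alias filter is
   inserted here: the 120 Hz low-pass plays that role in this chain, and
   every analysis band lies below 45 Hz, far under the decimated
   Nyquist.  `resample` applies a proper 0.45·rate_out anti-alias filter
   by default for stand-alone use;
6. narrow band-pass (order 2, zero-phase) for the chosen band, then the
   band's feature signal: raw amplitude below 7 Hz, Hilbert-envelope or
   instantaneous-phase above.  Hilbert transforms run on the continuous
   signal *before* epoching so analytic-signal edge artifacts never fall
   on epoch boundaries.

Filter orders are a package choice (they are rarely reported for this
kind of chain): order 4 for the wide low-pass, order 2 for the narrow
bands.  A second-order band-pass at 0.1–1 Hz on 128 Hz data has a
normalized low edge of ~0.0016; higher orders there are numerically
fragile even in second-order sections.  Zero-phase application squares
the magnitude response, which gives the SCP band ≥ 20 dB attenuation at
4 Hz relative to 0.5 Hz.  Whether CAR should precede or follow temporal
filtering is not settled; this package applies CAR first.  Both
operators are linear, so the order affects only numerical details.

The "envelope" of a band is the modulus of the analytic signal.  A
`literal_rectified` option (absolute value of the band-passed signal,
i.e. full-wave rectification) exists because that phrasing circulates in
the literature; the modulus is the default and the established meaning.

## Windows and features

Time conventions: the alignment event (movement onset, or cue for the
idle period) is t = 0; every interval is half-open on the left,
(start, end], and a window is labeled by the time of its **endpoint**.
An epoch over (−2, 1] s at 128 Hz holds 384 samples ending exactly at
+1 s.  The default grid — 250 ms windows every 62.5 ms — then runs from
endpoint −1.750 s to +1.000 s, 45 windows, and the idle grid over
(−1, 2] s around the cue likewise holds 45 windows.

Within a window the 128 Hz signal is decimated to 16 Hz by keeping every
8th sample **anchored at the window end**, so the endpoint sample is
always included and a 250 ms window contributes 4 points per channel.
No extra anti-alias filtering is applied at this step: the SCP band is
more than three octaves below the 8 Hz feature-Nyquist, and envelope
signals of the narrow high bands are comparably smooth.  Ten selected
channels × 4 points give the 40-dimensional feature vector; the full
34-channel matrix used for selection has 136 columns.  Phase features
are expanded to (cos φ, sin φ) pairs by default (80 columns for 10
channels) to remove the ±π wrap from the linear model; a `raw_angle`
mode keeps plain angles.

## Channel selection (CVA)

Per window and per training fold, features are standardized (train-fold
mean/SD) and the canonical variate problem B·v = λ·W·v is solved
(generalized symmetric eigensolver, so vᵀWv = I), with B/W the
between-/within-class scatter.  Four classes give at most three nonzero
eigenvalues.  Discriminant power per feature is the eigenvalue-weighted
squared coefficient, dp_j = Σ_k λ_k w_jk² (normalized to sum to one);
channel DP sums the channel's four columns, channels are ranked by DP
(ties break by montage order) and the top 10 kept.  W is ridge-shrunk
toward a scaled identity only when its condition number exceeds 1e10,
escalating ×10 until well-conditioned, so well-posed problems match a
dense W⁻¹B solve to 1e-8.

A caveat worth knowing: coefficient-based DP credits directions of small
within-class variance, so a *heterogeneously* collinear feature set
(one channel's columns much more mutually correlated than the others')
would be over-credited.  In this pipeline the collinearity is
homogeneous — adjacent 16 Hz samples of any < 1 Hz signal are highly
correlated on every channel — so the ranking is unaffected; for
diagnostics, `dp_mode="structure"` substitutes eigenvalue-weighted
squared structure correlations, which do not have this sensitivity.
CVA may also be run on per-channel window means (`channel_mode="mean"`)
instead of the stacked 136-column matrix.

## Classification (LDA)

Each class is Gaussian with its own mean and a pooled covariance Σ
(within-class, pooled over classes).  Posteriors follow Bayes' rule and
prediction is the argmax.  Σ is shrunk as (1−s)·Σ̂ + s·(tr Σ̂/p)·I with
s = 0.05 by default — 40-dimensional fits on ~96–184 training trials are
occasionally ill-conditioned under permuted labels; s = 0 restores the
plain pooled-covariance model.  Numerics go through a Cholesky
factorization of Σ (never an explicit inverse) with log-sum-exp
normalization; the result agrees with a brute-force evaluation of the
Gaussian densities to 1e-10.  Priors are empirical class frequencies
(uniform available); the difference is negligible for balanced designs.

## Cross-validation, chance, detection

Folds are contiguous chronological blocks (first `n mod k` folds one
trial larger), which respects session non-stationarity; shuffled trial
orders are rejected.  Decoding accuracy (DA) is the confusion-matrix
trace over the total test count.

Chance level re-runs the *identical* pipeline — standardization, CVA
selection, LDA — with freshly permuted training labels per fold, 10
repetitions × 5 folds, scoring against intact test labels.  Re-running
selection under permutation avoids the optimistic bias of only
refitting the classifier; a `refit_only` mode reproduces the cheaper
variant.  For four balanced classes the grand mean sits at ≈ 25 %.

Per window, a one-sided Wilcoxon rank-sum test compares the five fold
DAs against all 50 permuted DAs of the same window; the early-detection
time is the endpoint of the first window beginning a run of five
consecutive windows with p < 0.05.  No multiple-testing correction is
applied — that replicates the standard rule in this analysis family and
is not a statistical endorsement.  The best **pre-onset** window
(argmax of mean DA over endpoints ≤ 0, ties toward onset) is frozen —
each fold keeps its own standardization, channel set and LDA — and
re-applied across all windows of the intention period (sensitivity) and
the cue-aligned idle period (specificity), each fold scoring only its
own test trials.  A percentile band for a fold-mean DA under the null is
derived by resampling fold-size groups from the permuted pool.

## Synthetic data

The generator emulates the protocol, not a brain.  Per channel the
background is 1/f-shaped Gaussian noise (default exponent 1.0,
10 µV RMS) plus white noise (0.5 µV RMS); the 1/f shape is imposed
spectrally, and its log-log PSD slope between 1 and 40 Hz verifies to
within 0.2.  Trials sit on one continuous timeline: a 2–4 s jittered
gap, the cue, a shifted-gamma cue-to-onset latency (2.0 s + Γ(4, 0.25),
mean ≈ 3 s — the order of magnitude reported for this task), the
movement.  A configurable fraction (default 4 %) of trials violate the
2 s rule, so 240 generated trials leave ≈ 230 after the discard step.

The planted direction signal is a half-cosine ramp from 0.5 s before
onset to onset, a 1 s plateau while the movement lasts, and a 0.5 s
release, band-limited to 0.1–1 Hz **causally** (forward-only filter): a
zero-phase filter here would place signal energy before the neural
event that generates it, which no physiological source can do.  Each
direction multiplies this waveform by its own zero-sum spatial pattern
over ten fronto-central/centro-parietal channels — an
anterior–posterior gradient for up/down, a left–right gradient for
left/right — making the classes linearly separable at high SNR and
immune to CAR (zero-sum patterns pass through mean subtraction).  `snr`
scales the planted RMS on a unit-gain channel against the background
RMS inside the effect band, both measured on the generated data, so
`snr=0` plants nothing and leaves the background bit-identical.

What the generator does **not** model: EOG/EMG artifacts, electrode
drift and pops, nonstationary alpha bursts, volume-conducted sources,
lesioned topographies.  Green tests on this data therefore demonstrate
the pipeline's *correctness and statistical calibration* (no label
leakage, honest chance level, recoverable parameters), not its
performance on real recordings.

## Problem sizes in the test suite

The acceptance-style tests run: chance level at the protocol's full 240
trials; parameter recovery at 120 trials × 20 seeds with the detection
grid restricted to the pre-onset span (−2, 0] s (detection is defined
pre-onset only); null specificity at 96 trials × 20 seeds with the
best-window search over the last eight pre-onset windows.  Unit tests
use small crafted arrays throughout.

## Known limitations

- **Anticausal smearing.**  The zero-phase 0.1–1 Hz band-pass has a ~2 s
  anticausal tail from its 0.1 Hz pole.  A strong causal effect
  therefore leaks *backwards* in analysis time: at snr 3 the pre-onset
  lobe (~7 % of peak) is reliably decodable ~0.5–1.5 s before the
  planted effect begins, and the measured early-detection time precedes
  the true effect onset in roughly half of the runs.  This is a property
  of non-causal filtering in pre-movement decoding generally: detection
  times from such pipelines bound *information availability in the
  filtered signal*, not the physiological onset of the underlying
  component, and they could not be achieved by a causal online system.
  The snr = 0 control (no detection, chance-level DA everywhere) shows
  the leak is in time, not between train and test.
- Chance bands and p-values inherit the granularity of 10 × 5 permuted
  scores; very small tail probabilities are not resolvable.
- The 34-channel default montage is a documented stand-in; real
  recordings need their own subset (and EOG-based exclusion happens
  outside this package).
- EDF/BDF reading is a thin optional wrapper over `mne` and expects
  events as annotations (`kind/direction/trial_id`); the internal HDF5
  container is the tested path.
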