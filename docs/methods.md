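# Methods

This note records the modelling and numerical decisions behind the
package, what the synthetic generator does and does not emulate, and the
limitations a user should keep in mind.

## Decomposition

EMFD is realized on the discrete Fourier grid of the segment itself:
`n_fft = len(x)`, no zero padding, bin *k* ↔ ω = 2πk/n_fft ∈ [0, π].
The continuous-frequency description of the method leaves several
discrete choices open; ours are:

- **Candidate peaks** are the DC and Nyquist magnitudes plus *strict*
  local maxima (greater than the nearest differing neighbour on both
  sides); a plateau counts once at its left-most bin.  Ties in the
  magnitude ranking break toward lower frequency.  Both choices are for
  determinism: identical inputs always produce identical segmentations.
- **Boundaries** are half-open, [ωₙ₋₁, ωₙ) with the final band closed
  at π, and the DC bin belongs to mode 1.  A partition (rather than the
  closed intervals a textbook band-pass suggests) is what makes
  reconstruction exact: every bin is claimed by exactly one mode, so
  the modes sum to the input at machine precision and Parseval gives
  energy conservation across modes.
- **Adjacent peaks** (empty open interval between them) collapse the
  boundary onto the shared edge bin; duplicate boundaries are removed,
  which can reduce the delivered mode count.
- **Fewer candidates than requested modes** clamps N with a warning
  instead of raising: batch feature extraction over thousands of short
  or narrowband segments must not abort on one degenerate spectrum.
- **Mode count.**  The default is N = 10; end-to-end synthetic studies
  in this repository use N = 5, which keeps single-CPU runtimes small
  while leaving every band wide enough to carry structure at 128 Hz.
  Both are defensible operating points and N is configurable
  everywhere.

## Entropy features

Per (channel, mode), five measures; defaults are the field-standard
choices where the underlying definitions leave them open:

| parameter | default | meaning |
| --- | --- | --- |
| m | 2 | embedding dimension (ApEn, FuzzyEn) |
| r | 0.2·SD | template tolerance, re-estimated per mode |
| n | 2 | fuzzy membership steepness exp(−(d/r)ⁿ) |
| σ | Silverman, 1.06·SD·P^(−1/5) | Rényi Gaussian kernel width |
| sub-window | 0.5 s, 50% overlap | Higuchi FD sliding window |
| kmax | 10 | Higuchi scale limit |
| M | 10 bins over [1, 2] | FD histogram for FDe |

Conventions worth stating explicitly:

- ApEn follows Pincus: Chebyshev distance, self-matches *included*
  (the statistic is always finite; a constant signal gives exactly 0).
- FuzzyEn follows Chen: templates are mean-removed (hence exact
  offset invariance), self-matches *excluded*, and both embedding
  dimensions use N−m templates.  The two conventions differ on purpose;
  they match the original definitions of each measure.
- Differential entropy uses the Gaussian closed form ½·ln(2πeσ²) with
  the sample SD (ddof = 1).  It is the only feature that can diverge
  (σ → 0); the featurizer clamps the variance at 1e−30 so batch
  extraction never emits −∞, while the bare function raises unless a
  floor is requested.
- Rényi entropy is reported as h₂ = −ln IP.  The information potential
  alone is a similarity, not an entropy; the quadratic Rényi form makes
  it a scalar feature on the same "larger = more irregular" axis as the
  others.
- FDe uses base-2 logs (bits); all other entropies are in nats.
- The O(n²) pairwise kernels (ApEn counts, fuzzy memberships, IP) are
  numba-compiled direct double loops.  Fuzzy memberships below
  exp(−45) are skipped; against an O(n²) sum of O(1) terms this is
  far beneath double-precision round-off, and the test oracles confirm
  agreement to 1e−12.

Feature normalization is min-max with training-fold statistics only; a
constant training column maps to 0.5 and out-of-range test values are
not clipped (clipping would leak test-fold information into the
effective transform).  The optional feature reducer (variance floor
1e−12, then greedy |r| ≥ 0.98 correlation pruning, earlier column wins)
is off by default: it is a generic redundancy filter, not a claim about
any particular published reduction procedure, and the entropy panel is
small enough that boosted trees handle it directly.

## Lobe assignment

The 10–20 label prefix determines the lobe (FP*/AF*/F* frontal, C*
central, T* temporal, P* parietal, O* occipital; midline electrodes to
their letter's lobe).  FC5/FC6 are fronto-central; the 14-channel
montage declares no central lobe, so they are grouped frontal.  This is
a nomenclature-based inference, not a measured fact — a custom mapping
overrides it.

## Classification and evaluation

- The positive class is `task`, so sensitivity tracks task detection.
- "Boosted trees" is gradient boosting; "subspace" families are
  random-feature-subspace baggers; "kernel naive Bayes" is a per-class,
  per-feature Gaussian-KDE naive Bayes written in-package because no
  installed library provides one.
- Headline Ac/Se/Sp/Pr/Fs pool the confusion counts across folds;
  mean ± SD and the t-based 95% CI come from per-fold accuracies; ROC
  and AUC come from pooled out-of-fold scores with rank-averaged ties.
  Undefined ratios (empty denominators) are reported as absent, never
  as zero.
- CV is stratified at segment level by default, matching the apparent
  protocol of segment-wise workload studies; `groups=subject`
  switches to subject-grouped folds.  Segment-level CV on real data
  risks subject leakage — both modes are first-class precisely so that
  the comparison can be made.
- Hyperparameter search is GP-EI: random initialization (8 points),
  Matérn-5/2 surrogate on unit-scaled (log-scaled where appropriate)
  parameters, expected improvement maximized over 256 random
  candidates, objective = inner stratified 5-fold mean accuracy,
  default budget 30.
- The permutation test reshuffles labels wholesale and reruns the full
  CV; p = (1 + #{permuted ≥ observed})/(n_perm + 1) is never zero and
  is valid (super-uniform) under exchangeability.

## Synthetic EEG

Each channel is 20 µV-RMS spectrally shaped 1/f noise (exponent 1.0,
DC removed) plus narrowband-filtered-noise oscillators: theta 6 µV,
alpha 8 µV, beta 4 µV RMS before subject gains.  Oscillators are
filtered noise, not sinusoids, so entropy features are non-degenerate.
Under task: frontal theta amplitude × `frontal_theta_gain`, alpha
amplitude × `alpha_suppression` on all channels, plus
`irregularity_delta` × background-RMS of extra white noise.  Per-subject
log-normal band gains (SD 0.2) are drawn once per subject and shared
across conditions, so subject identity is a real source of variance.

The strong preset (gain 2.5, suppression 0.7, delta 0.1) keeps the
spatially global effects mild relative to the frontal-localized theta
effect, so lobe-wise classification has a genuine spatial contrast to
find; the null preset (1.0 / 1.0 / 0.0) makes task and rest
exchangeable.  End-to-end studies use 20 subjects × 40 s per condition
(400 four-second segments) under the 14-channel 128 Hz montage — sizes
chosen to make a full study run comfortably on one CPU.

What the generator does **not** emulate: eye-blink/EMG artifacts,
non-stationary drifts, volume-conduction correlation structure between
channels, realistic posterior-dominant alpha topography, or multi-level
workload.  Passing the synthetic recovery study therefore demonstrates
that the pipeline's machinery is correct and spatially specific — not
that any particular accuracy will transfer to real recordings.

## Preprocessing

Zero-phase forward-backward Butterworth (order 4): 0.5–45 Hz band-pass
for the 19-channel preset; 1 Hz high-pass plus common-average
re-referencing for the 14-channel preset (per-channel mean subtraction
is available as the alternative reading of "re-referencing through data
averaging"); optional 50 Hz notch, off by default.  Filtering pads with
up to 3/low-cutoff seconds of signal reflection because a sub-Hz edge
has a multi-second impulse response and the default padding leaks
transients.  Windows are non-overlapping 4-s slices (overlap is
supported but off: overlapping windows leak shared samples across CV
folds); trailing partial windows are discarded.

## Known limitations

- EDF reading requires channel labels recognizable as 10–20 names;
  T3/T4/T5/T6 ↔ T7/T8/P7/P8 aliasing is applied only on request.
- The Gaussian closed form for differential entropy is exact only for
  Gaussian samples; on strongly non-Gaussian modes it is a
  log-variance feature, which is still discriminative but not an
  entropy in the strict sense.
- Exact numeric parity with any particular GUI/MATLAB classifier
  implementation is a non-goal; families are matched at the level of
  their algorithmic idea.
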