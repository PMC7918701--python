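# Methods

This note documents the models implemented in `ssvepdecode`, the numerical
conventions they rely on, the generative model behind the synthetic data,
and the design decisions taken where more than one reasonable choice
existed.

## Data model

All stages operate on an `EpochSet`: a 4-way array indexed
`(class, trial, channel, sample)` with sampling rate `fs`, unique channel
labels, strictly increasing stimulus frequencies, and `t0`, the time of the
first retained sample relative to stimulus onset. Epoch sets round-trip
bit-exactly through a single self-describing HDF5 container per subject
(dataset `/data` plus attributes, including an append-only preprocessing
log). Sample indexing is 0-based internally; all user-facing times are
seconds.

An adapter converts per-subject matrices in the common public-benchmark
layout `(channel, sample, class, block)`; the axis order must be declared,
never guessed, and classes are re-sorted by stimulus frequency so the
container invariant holds. The adapter trusts the file's declared sampling
rate over any nominal acquisition rate, because distributed copies are
commonly resampled.

## Preprocessing

Epochs are band-pass filtered 7–90 Hz with a Chebyshev type-I IIR filter
applied forward–backward (zero phase), in second-order-sections form for
numerical stability. Order 4 per direction and 1 dB passband ripple are the
conventional values in the filter-bank SSVEP literature; only the family,
band and zero-phase property are externally fixed, so order and ripple are
config knobs (`preprocess.order`, `preprocess.ripple_db`). Note the
forward–backward pass squares the magnitude response: in-band tones can be
attenuated by up to 2 dB at ripple minima, and a tone a few percent below a
sub-band edge sits in the transition knee rather than the full stopband.
Tests assert these designed-response bounds, not idealized flatness.

The analysis window starts 0.64 s after stimulus onset (visual-pathway
latency) and lasts `tw` seconds. Sample conversion is nearest-integer
rounding with a half-open interval `[round(latency·fs),
round(latency·fs) + round(tw·fs))`, so window lengths are reproducible
across sampling rates. Filtering is applied to the full epoch *before*
windowing so filter transients stay outside the analysis window.

## CCA family

The canonical-correlation solver centers rows, forms the covariance
matrices with a divide-by-`T` normalizer, whitens the two auto-covariances
and takes the leading singular pair of the whitened cross-covariance —
algebraically the classical generalized eigenproblem. A ridge of
`1e-8 · trace/dim` on each auto-covariance keeps rank-deficient inputs
solvable (with a warning when it is actually doing work); `ridge=0`
converts that into a hard singularity error. Weight vectors are unit-norm
with canonical sign (largest-magnitude entry positive); every decision
score is invariant to this choice because both operands of each
correlation share the same filter.

One correlation definition is used everywhere a "correlation between two
multichannel matrices" is needed (the unfiltered template/test term of the
two-step method, and the projected pairs of extended CCA): the Pearson
correlation of the two arrays vectorized in row-major order after mean
removal. Zero-variance operands yield 0 with a warning rather than NaN.

Sinusoidal references default to `Nh = 5` harmonics — the choice is known
to be delicate, which is exactly why the template-based methods exist, so
it is a config knob with the literature-standard default. The time grid is
`t = n/fs` for `n = 1..Ns`.

The published form of the extended-CCA correlation vector has garbled
spatial-filter subscripts; this package follows the standard formulation
the method originally cites. With `w_{A,B}` the A-side CCA weight of the
pair `(A, B)`:

- `r₁ = ρ(w_{XZ}ᵀX̄, v_{XZ}ᵀZ_i)` — the plain canonical correlation;
- `r₂ = ρ(w_{XY}ᵀX̄, w_{XY}ᵀY_i)`;
- `r₃ = ρ(w_{XZ}ᵀX̄, w_{XZ}ᵀY_i)`;
- `r₄ = ρ(w_{YZ}ᵀX̄, w_{YZ}ᵀY_i)`;

fused as `ρ_i = Σ_k sign(r_k) r_k²`. Setting the template terms to zero
reduces the ranking to standard CCA, which the tests verify.

## TRCA and the two-step ensemble

For one class with trials `X^{(1)}..X^{(Nt)}` (each `Nc × Ns`,
channel-mean removed per trial):

- `S[c₁,c₂] = Σ_{t₁≠t₂} Cov(X^{(t₁)}_{c₁}, X^{(t₂)}_{c₂})` over ordered
  pairs, computed as `(Σ_t X̃_t)(Σ_t X̃_t)ᵀ − Σ_t X̃_t X̃_tᵀ` after
  centering;
- `Q` = channel covariance of the horizontally concatenated centered
  trials.

Covariances divide by the number of samples (population normalizer)
throughout: rankings are invariant to the normalizer and fixing it keeps
runs bit-reproducible. Per-trial mean removal before both `S` and `Q`
prevents inter-trial offsets from masquerading as reproducible signal. The
filter is the leading eigenvector of the symmetric-definite problem
`S w = λ Q w` (solved as such for stability, with ridge
`1e-8·trace(Q)/Nc` on `Q` against short-window ill-conditioning), unit
norm, canonical sign; the returned eigenvalue equals the Rayleigh quotient
at the optimum.

Standard TRCA scores class *i* with its own filter only,
`ρ̂_i = ρ(w_iᵀX̄, w_iᵀY_i)`, mirroring the non-ensemble baseline; the
ensemble variant (all filters stacked, multichannel correlation) is
available via `trca_score(..., ensemble=True)` and the `EvalConfig`
flag `trca_ensemble`, since which variant a given comparison used is not
always stated in the literature.

The two-step ensemble passes each candidate template/test pair through
*every* class's filter — `β_{i,k} = ρ(w_kᵀY_i, w_kᵀX̄)` for `k = 1..Nf`,
written here as 1-D projection correlations, consistent with the standard
TRCA score — plus the unfiltered `β_{i,0} = ρ(Y_i, X̄)`, and fuses with the
shared signed-square kernel. Under the generative model below, all class
filters estimate nearly the same true spatial direction, each corrupted by
independent estimation noise from its own small training set; summing the
signed squares averages that noise away, which is why the two-step variant
holds its accuracy at short windows where each individual filter is
poorly estimated. Restricting the ensemble to the own-class filter without
squaring recovers standard TRCA exactly (tested).

## Filter bank

The harmonic ("M3") decomposition band-passes the epoch into `Nb` nested
sub-bands `[8b, 90]` Hz; `Nb` defaults to 5 (lowest cutoffs 8, 16, 24, 32,
40 Hz), keeping every band edge below the 90 Hz ceiling. Per-band models
are trained on band-filtered training data, so fit and test always see the
same decomposition. Scores combine as

    ρ_i = Σ_b s_b · sign(r_i^b) (r_i^b)²,   s_b = b^(−1.25) + 0.25.

The published combination rule prints neither the band sum nor the square;
the sum-of-squares form of the filter-bank CCA convention is used. The
square is applied *signed* here: for non-negative base scores (CCA
correlations) this coincides with the plain square, while for
ensemble-style scores that can be negative it preserves the base ranking —
required for the one-band unit-weight wrapper to reduce exactly to its
base method. The unfiltered `β_{i,0}` term of the two-step method is
recomputed per band (uniformity across bands); computing it once on the
full-band data would be the alternative convention.

## Evaluation protocol

Block-wise leave-one-out: each of the `Nt` blocks serves once as test data,
the rest train templates and filters, and all `Nf` held-out trials are
classified per fold. Accuracy is averaged per fold (equal to the pooled
fraction for balanced folds); ITR is computed per fold and then averaged,
matching per-block averaging conventions — hence mean accuracy and mean
ITR need not jointly satisfy the ITR formula, and both terms of the
selection time (`tw` + 0.5 s gaze shift) are carried separately in the
config so alternative conventions are auditable. Precision/recall/F1 are
macro-averaged; classes are balanced by design, so macro and micro
averaging coincide in expectation, and macro keeps per-class behaviour
visible. Ties in the argmax break to the lowest class index and are
logged. The `sweep` helper emits a long-format CSV
(subject, method, tw, n_channels, accuracy, itr, precision, recall, f1)
directly consumable by external statistics tools; significance testing is
deliberately out of scope.

## Synthetic data

Per subject: each class `i` drives a harmonic series
`Σ_h d^(h−1) sin(2π h f_i t + φ_i)` with amplitude decay `d = 0.5` per
harmonic and 3 harmonics; `φ_i` is drawn once per (subject, class) and
frozen — the time-locking that makes templates and inter-trial covariance
informative (an optional per-trial phase jitter stresses exactly this
assumption). The source projects into the channels through a fixed random
unit mixing vector per subject. Defaults: 8 classes on the 8.0–9.4 Hz
grid, 9 occipito-parietal channels, 6 blocks, 250 Hz, 2.14 s epochs
(0.64 s latency padding + 1.5 s usable span) — structured like a speller
recording but small enough for seconds-scale tests.

The background has two parts, neither phase-locked to the stimulus:

- broadband noise, pink (1/f power) by default — the realistic EEG
  spectrum; white noise is available for controlled experiments;
- a spontaneous alpha rhythm: Gaussian-envelope narrow-band noise centered
  at a subject-specific peak drawn from 9–11 Hz (2 Hz width), projected
  through its own fixed random topography, contributing half the in-band
  noise power by default (`alpha_frac = 0.5`).

Alpha is included because it is the canonical confound of SSVEP decoding:
it lies inside the stimulation band, so sinusoid-referenced CCA picks it
up as spurious correlation, while spatial-filter methods can suppress it
because its topography differs from the stimulus-driven one. Without it
(spatially i.i.d. broadband noise only), every template-based method
saturates near ceiling at the default SNR and method comparisons become
uninformative.

SNR is prescribed at the sensor level **on the analysis band** (7–90 Hz):
the noise mixture is scaled so in-band signal power over in-band noise
power (rFFT band masking) equals `snr_db` exactly; the default is −10 dB.
`snr_db = inf` is the noiseless limit (every trial equals its class
source). Cohorts derive per-subject mixing/noise seeds from one base seed
via `numpy`'s `SeedSequence`, so regeneration is bit-identical.

Deliberately not modelled: EEG nonstationarity, eye blinks, electrode
drift, per-class topography differences, realistic inter-channel
correlation of the broadband floor. Passing tests on this generator
therefore demonstrate correctness of the algorithms and the *mechanisms*
behind the methods' relative ordering (template information, spatial
suppression of structured interference, ensemble variance reduction) — not
absolute performance levels on recorded EEG.

## Problem sizes and numerical choices

The test suite and the reproduction script use the default 8-class,
6-block, 9-channel subjects and a 10-subject cohort — sizes chosen so the
full pipeline (including the filter-bank variants) completes in well under
a minute while leaving every method measurably below ceiling at the 0.3 s
window. Key tolerances: oracle equivalence of `S`/`Q` at 1e-10;
eigenvalue-vs-Rayleigh-quotient at 1e-8 relative; CCA invariance checks at
1e-5 absolute (limited by the rank-safety ridge); closed-form ITR values at
the printed precision. Degenerate inputs are handled by convention rather
than failure where a convention is standard: zero-variance projections
score 0 with a warning, argmax ties break low, `x log₂ x = 0` at `x = 0`.

## Known limitations

- The benchmark adapter is tested against synthetic stand-ins only; the
  public 35-subject recordings are an optional external input, and
  absolute accuracies on them are not reproduced here.
- The CCA solver returns only the leading canonical pair; methods here
  never need the full canonical spectrum.
- ITR assumes independent, equiprobable targets and a memoryless
  classifier; it overstates throughput for correlated selections.
- The filter-bank weights `s_b` are fixed by the standard power law; no
  data-driven weight fitting is provided.
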