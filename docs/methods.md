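# Methods

## Problem and pipeline

The package classifies short frames of multichannel EEG into one of two
mental-task classes. A session (by default 10 s at 250 Hz over the six
10–20 electrodes C3, C4, P3, P4, O1, O2) is notch-filtered at the mains
frequency, cut into 1-second frames shifted by 0.5 s (19 frames per 10-s
session), and each frame is processed in four stages: empirical mode
decomposition per channel, inter-channel correlation of same-order IMFs,
assembly of the frame feature vector, and kernel-SVM classification under
leave-one-out cross-validation (LOOCV).

## Empirical mode decomposition

Each channel of a frame is decomposed by iterative sifting: cubic splines
through the local maxima and minima define upper and lower envelopes, and
the envelope mean is subtracted, h_w = h_{w−1} − μ_w, until the iterate is
an admissible IMF. The residue is then re-sifted for the next mode. The
identity y = Σ u_m + r_L holds to floating-point precision by
construction and is property-tested.

Choices that the generic description leaves open, fixed here:

- **Stopping rule.** Sifting stops when the candidate passes the IMF
  admissibility test (extrema and zero-crossing counts differ by at most
  one) *and* the Cauchy ratio Σ(h_{w−1}−h_w)²/Σh²_{w−1} has fallen below
  `sd_threshold` (default 0.2), with a hard cap of 100 iterations.
  Requiring the conjunction (rather than either condition alone) matters:
  broadband iterates pass the admissibility count after one or two sifts
  while their envelope mean is still large, and accepting them produces
  mode-mixed IMFs whose second mode disagrees badly with textbook sifters.
  The conjunction also guarantees every returned IMF is admissible.
- **Envelopes.** Cubic splines through the extrema, with the two outermost
  extrema mirrored about each end of the frame before fitting; mirroring
  suppresses the end swings an unconstrained spline develops.
- **Plateaus.** A run of equal samples higher (lower) than both neighbours
  counts as one maximum (minimum) at the run's midpoint index, lower index
  on even ties.
- **Mode count.** Default L = 3 IMFs per channel (configurable 1–6). The
  low-order IMFs carry the high-frequency, task-discriminative content;
  higher modes are slow trends. Decomposition also stops early when the
  residue has fewer than two maxima or two minima or is constant;
  degenerate inputs yield zero IMFs with residue equal to the input, so
  reconstruction always holds. A frame whose channels cannot supply L IMFs
  is an error in feature extraction — padding would fabricate features
  silently.

## Features

**inter-IMFCC.** For channels i, j and IMF order m, the Pearson
correlation of u_m^(i) and u_m^(j) with covariance normalised by 1/(N−1).
Values lie in [−1, 1]; a constant IMF raises instead of contributing an
arbitrary zero. Three pairing schemes are supported over the six-channel
montage: all 15 unordered pairs (default), the 9 cross-hemisphere pairs
(left × right), and the 8 pairs of a reference region (both channels of
the parietal, central or occipital pair against the four others).

**Per-IMF statistics.** Default set: population standard deviation (1/N —
deliberately different from the correlation's 1/(N−1); both normalisations
are preserved exactly as defined, each in its own function), RMS, and
Shannon entropy. Seven further candidates are available (mean, median,
mode, max, min, skewness, non-excess kurtosis). Entropy and mode need
discrete symbols: amplitudes are quantized onto a uniform grid spanning
the sequence's min–max range, 2¹² levels by default to mirror a 12-bit
acquisition front end. This quantizer is the package's choice — counting
exact float values would degenerate to log₂N for continuous data — and its
grid size is configurable and recorded in the feature provenance.

**Feature vector.** IMF-major ordering, pairs before statistics, pairs in
resolved order, channels in label order; dimension L × (P + |stats|·N_c).
Defaults give 3 × (15 + 18) = 99. Extraction is deterministic: repeated
extraction of one frame is bit-identical.

## Baselines

- **PARq** (q = 4, 5, 6 bands): per band, the power of each channel from a
  Hann-windowed periodogram integrated over [lo, hi) by the rectangle
  rule, plus the asymmetry ratio A(i,j) = (P_i−P_j)/(P_i+P_j) for each of
  the 3 × 3 (left, right) channel pairs: q·9 + q·6 features (60/75/90).
  Band presets: delta < 4, theta 4–7, alpha 8–13, beta 14–20, gamma 23–37,
  high 40–100 Hz. Absolute (not relative) band power is used. Bands
  crossing Nyquist are truncated with a warning (at 250 Hz the high band
  fits under the 125 Hz Nyquist untruncated). Frames are too short for
  Welch averaging, hence the single-taper periodogram.
- **EFn** (n = 8 or 3 features from each of 4 IMFs of each channel;
  192/72 features): RMS, sample variance (1/(N−1)), Shannon entropy
  (same implementation as the main extractor), Lempel–Ziv complexity,
  central frequency (PSD-weighted mean, DC excluded), peak frequency,
  skewness, kurtosis. The LZ measure is the Kaspar–Schuster LZ76 phrase
  count of the median-binarized sequence, normalised by N/log₂N; when ties
  at the median would collapse the binarization to one symbol the
  comparison flips to ≥ so both symbols stay represented. The LZ and
  spectral-moment definitions are common-convention reconstructions, since
  the originating description does not specify them.

## Classification

Soft-margin SVM with kernels: linear (a·b), quadratic ((1+a·b)²), and
polynomial ((1+a·b)^d, default degree 3, coef0 1). The quadratic
programme is delegated to scikit-learn's SVC on a *precomputed* kernel
matrix, but the expansion coefficients c_i and offset b are extracted and
the decision function f(x) = Σ c_i K(x_i, x) + b is evaluated by this
package's own kernel code; a tie f(x) = 0 resolves to the positive class.
Penalty C defaults to 1.0.

LOOCV performs exactly P train/predict cycles. Features are z-scored
inside each fold from the P−1 training rows only — correlations in [−1,1]
and entropies up to ~8 bits must be made commensurate for a kernel
machine, and fold-local statistics prevent the held-out frame leaking into
training (a canary test scrambles a label-copy feature in training rows
only and checks the score collapses). Accuracy is 100·N_t/(N_A+N_B). The
task-pair experiment runs every unordered pair of task labels under every
requested kernel and appends Avg and sample-Std-dev summary rows.

## Synthetic data

Sessions are generated as mixtures of band-limited Gaussian noise sources
(white noise band-pass filtered to a rhythm band, unit RMS) — not pure
tones, so EMD produces several meaningful modes per frame as it does on
real EEG. Each channel is a weighted sum of the shared sources plus
additive noise; channels listed as decoupled replace a fraction δ of each
shared source with an independent realisation of the same band. Amplitudes
are finally quantized to a 12-bit grid, applied after mixing so it
interacts with the entropy quantizer realistically. Per-channel noise may
be white, partially 1/f, or band-limited; the coupling-study profile uses
same-band background so that the shared and independent content of the
first IMF compete directly, making mean inter-IMFCC rise monotonically
with the mixing weight ρ.

Default study conditions: fs 250 Hz, 10-s sessions, the strongly coupled
class mixes theta/alpha/beta sources at weight 0.9 with noise SD 0.2; the
contrast class additionally decouples O1/O2 at δ = 0.9. Multi-session
datasets derive one child seed per session by `SeedSequence` spawning from
the master seed, interleaved so the two classes use disjoint streams;
records are bit-reproducible from (profile, seed).

What the generator does *not* emulate: volume conduction and dipolar
forward models, artifacts (blinks, EMG), non-stationarity within a
session, and 1/f background by default. Passing tests therefore show the
pipeline recovers controllable coupling structure — not that real-subject
accuracies are reproduced.

## Problem sizes used in checks

The repeated-simulation checks use sizes chosen to exercise the pipeline
end to end while staying cheap: the coupling-monotonicity study uses 50
replicates of 1-s sessions at four coupling levels; the end-to-end
classification checks use 5 sessions per class (190 frames) for the
separable and the indistinguishable pair alike. With these sizes the
separable configuration scores ≥ 90% (typically 99–100%) and the
indistinguishable one stays in the mid-chance band, across seeds.

## Known limitations

- EMD is convention-sensitive; different boundary handling or stopping
  rules shift mode boundaries, especially beyond the first IMF. The test
  suite asserts strong correlation of the leading modes against an
  independently written reference sifter, not equality.
- The EDF writer is minimal (16-bit, one-second records, whole-second
  sessions) — sufficient for round-tripping sessions, not a general
  exporter.
- Two-class problems only; multi-class tasks are handled as all pairwise
  experiments, as is conventional for this scheme.
- Real mental-task recordings carry subject-specific structure (unstated
  SVM hyperparameters, electrode impedances, artifacts) that synthetic
  data cannot stand in for; absolute accuracies on real datasets are out
  of scope here.
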