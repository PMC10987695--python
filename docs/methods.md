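# Methods

This note documents the models and procedures implemented in `segvoice`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Problem setting

The package targets *continuous* emotion classification of speech: rather
than classifying whole, semantically coherent utterances, a longer audio
stream is cut into fixed windows of 1.5 s (optionally overlapping) and each
window is classified independently into six categories — anger, disgust,
fear, joy, sadness, neutral (integer codes in alphabetical order). The
fixed window deliberately ignores sentence structure: it emulates
real-world streams where emotion on/offsets are unknown, and it is short
enough that a single window rarely spans more than one emotional state.

## Fixed-window segmentation

Every recording is forced to the window length by symmetric
trimming/padding: a longer input loses `floor(excess/2)` samples at the
start and `ceil(excess/2)` at the end; a shorter one gains
`ceil(deficit/2)` zeros at the start and `floor(deficit/2)` at the end.
The odd-sample tie-break (extra removal at the end, extra zero at the
start) is arbitrary but fixed, so results are bit-reproducible. Stream
windowing places windows at offsets `0, stride, 2·stride, …`; a partial
tail window is zero-padded rather than dropped, so any non-empty stream
yields at least one window.

## Working sample rate

All processing happens at 16 kHz (inputs are resampled on load with a
polyphase filter; stereo is averaged to mono). The rate is pinned by the
feature-frame arithmetic: with the standard short-time parameters
(window 2,048 samples, hop 512, centered frames) a 1.5 s window yields
`1 + floor(24000/512) = 47` frames, which is the frame count all the
47-multiple feature blocks assume. No other common rate reproduces it.

## The feature battery (14,244 entries)

Seventeen feature families are concatenated into one fixed-length, named
vector per window; the intent is to over-generate and let the classifier
select. Block sizes at the default window are listed in
`segvoice/features.py`. Conventions that matter:

- **Variance is population variance** everywhere (well-defined for
  20-sample windows).
- **Raw/HPSS variance** uses non-overlapping 20-sample windows
  (24,000 / 20 = 1,200 values per signal). HPSS is median-filtering
  separation (horizontal median → harmonic mask, vertical → percussive,
  soft Wiener masks, inverse STFT), harmonic block first.
- **Rolloff** is computed at two energy percentages, 0.85 and 0.15,
  concatenated high-first. The low percentage is a symmetric-convention
  choice; only the 85% curve is canonical.
- **Spectral contrast** uses 4 bands (octave edges at 200/400/800 Hz plus
  the residual top band); contrast = dB difference between the mean top
  and bottom 20% of bin energies per band.
- **F0 and voicing** come from normalized frame autocorrelation
  (Wiener–Khinchin, mean-removed, Hann-windowed). Within the 50–500 Hz
  lag range, the candidate period is the *shortest* local maximum
  reaching 80% of the range maximum, which suppresses sub-octave errors
  on strongly periodic frames. The normalized peak is the periodicity
  score: frames with score ≥ 0.45 are voiced; unvoiced frames encode
  F0 = 0 and rely on the flag, keeping vectors finite and fixed-length.
  The voiced block stores the 0/1 flag curve then the probability curve.
- **Pitch tracking** is a sparse per-bin peak picker (parabolic
  interpolation, threshold 10% of the frame maximum) producing a
  1,025 × 47 frequency matrix and magnitude matrix; these, plus the STFT
  magnitude and phase-angle matrices, are summarized bin-wise as variance
  across frames followed by mean (2 × 1,025 values each).
- **MFCC** uses a 128-band mel filterbank (HTK mel scale, Slaney-style
  area normalization), dB compression with an 80 dB floor, orthonormal
  DCT-II, first 20 coefficients.
- **Chroma** folds spectral power onto 12 equal-tempered pitch classes
  (A440 reference, bins below 25 Hz discarded), normalized per frame to
  unit maximum; **tonnetz** is the 6-dimensional tonal-centroid
  projection of the L1-normalized chromagram.
- Matrix blocks are flattened coefficient-major. Any NaN from degenerate
  inputs is replaced by 0 at assembly; silence yields an all-finite,
  well-defined vector.

At other window lengths the same block formulas apply (e.g. a 3 s window
has 2,400 raw-variance values and 94 frames); the 1.5 s / 3 s / 5 s
variants are one parameter, not separate code paths.

## Spectrogram images

Each window renders to a borderless 320 × 240 × 3 image (230,400 values):
a 128-band dB mel spectrogram (80 dB dynamic range), min–max normalized,
mapped through the perceptual viridis colormap, and bilinearly resized.
Row 0 is the highest frequency. The frequency scale and colormap are not
externally pinned; they are encapsulated in `render_spectrogram` and
swappable without touching the models. The dB floor makes silence render
as a constant image.

## Classifier designs

Three designs share one probabilistic contract (six softmax
probabilities; argmax with ties to the lowest class index):

- **dnn** — feedforward ReLU stack with inverted dropout over the
  standardized feature vector (per-feature z-scoring is fitted on the
  first training data the model sees);
- **cnn** — 3 stages of 3×3 same-padding convolution + ReLU + 2×2 max
  pooling (16/32/64 filters) over the image scaled to [−0.5, 0.5],
  flattened into the softmax layer;
- **cdnn** — the feature branch (ending at its last hidden width) and the
  conv branch (projected to the same width) concatenate into a
  feedforward head.

The engine is a purpose-built numpy implementation (im2col convolutions,
Adam, softmax cross-entropy) with end-to-end seeding: `(config, data,
seed)` reproduces identical weights and metrics on one machine, and
backpropagation reaches the inputs for saliency. Training runs at most 4
epochs; after every epoch the validation split is scored and the
best-validation-accuracy weights are kept. Plain accuracy drives the
checkpoint; balanced accuracy is recorded alongside. Loss, activation and
optimizer (cross-entropy, ReLU, Adam) are fixed conventional choices.

**Hyperparameter search** is sequential model-based optimization on the
unit cube: a Matern-5/2 Gaussian process with *fixed* kernel
hyperparameters (length scale 0.25, tiny white noise) is fit to observed
(configuration → validation accuracy) pairs and the next candidate
maximizes expected improvement over 256 random proposals. Fixed kernel
scales keep the loop deterministic and are more robust than
marginal-likelihood fitting with a handful of observations. The default
space: depth 1–4, width {32…512}, dropout [0, 0.5], learning rate
log-uniform [1e-4, 1e-2], batch size {16, 32, 64}.

## Evaluation

- **Balanced accuracy (BAC)**: mean per-class recall; chance level for
  six classes is 1/6 regardless of class balance of the predictions.
- **10-fold cross-validation**: stratified folds (every class in every
  partition — BAC is undefined otherwise), fresh seeded model per fold.
- **Beta posteriors**: accuracy is modeled as a binomial success
  probability with a beta(1,1) flat prior; correct/incorrect counts
  update (α, β) conjugately. MAP = (α−1)/(α+β−2) when the interior mode
  exists, otherwise the mean (so the flat prior reports 0.5). The
  posterior over plain correctness is the default stream summary; an
  optional per-class view (recall posteriors per emotion) is available
  via confusion tables — for balanced streams the two coincide in
  expectation.
- **P(A > B)** between two posteriors: seeded Monte Carlo (default
  100,000 draws) with a deterministic quadrature path
  (∫ f_B(x)(1−F_A(x))dx) as cross-check.
- **Overlap coefficient**: ∫ min(f_A, f_B) computed via the identity
  min = (f_A + f_B − |f_A − f_B|)/2 with |f_A − f_B| integrated exactly by
  CDF differences on sign-constant intervals (crossings located on an
  8,193-point grid) — accurate even for sharply peaked densities.
- **Independent Validation** (prequential): stratified split into 10%
  initial training, 10% fixed validation, 80% stream; the stream is
  consumed in chunks of 16, each chunk predicted *before* joining the
  training set, the posterior absorbing the correct/incorrect counts.
  After absorbing a chunk the optimizer continues for one epoch on the
  enlarged set (incremental training); a full-retrain mode exists behind
  a flag. Validation accuracy is recorded every chunk to monitor
  overfitting. The final posterior equals beta(1 + correct,
  1 + incorrect) over the streamed items by conjugacy.
- **Human comparison**: per-emotion listening-study counts (correct,
  total) become beta(1+c, 1+t−c) posteriors and are compared with the
  model's per-emotion recall posteriors by overlap and P(model > human).
  Emotions with zero ratings are excluded with a warning.

## Interpretation

- **Average saliency**: per image, the absolute gradient of the winning
  logit with respect to the pixels, summed over channels, averaged over
  images. Requires a convolutional branch.
- **Time-segment Shapley values**: the window is divided into 48 equal
  segments (31.25 ms at the default window; the integer-division
  remainder joins the last segment). Feature entries map to segments via
  their frame or variance-window center; the four bin-wise summary blocks
  have no time location and stay as always-present context. Masking
  replaces a segment's features with the dataset mean. The estimator is
  permutation sampling with antithetic pairs (each sampled permutation is
  traversed forwards and backwards), which halves variance and makes the
  two-coalition case exact; the telescoping marginals make the estimates
  exactly efficient (they sum to f(x) − f(baseline)). Attribution on
  spectrogram images (pixel columns grouped into 48 segments) is also
  supported.

## Synthetic data

The generator emulates short emotional utterances as harmonic stacks
(8 partials, 1/k rolloff) with a drifting, vibrato-modulated F0 contour,
an attack/decay envelope with class-rate amplitude modulation, and a
broadband noise floor. Each class is a point in (F0 mean, F0 range,
energy, AM rate, noise fraction) space; the per-class profiles are
declared constants chosen to follow arousal/valence folk wisdom (anger
high/loud/fast, sadness low/quiet/slow) — they are *test fixtures*, not
claims about real emotion acoustics. A `separation` knob interpolates all
profiles toward the neutral profile; at 0 the labels carry no information,
giving an exact negative control. Per-utterance jitter uses index-keyed
seeded substreams so any subset of a dataset is reproducible in isolation.

What passing tests on this generator show: the pipeline is
information-preserving end to end (a learnable acoustic signal survives
feature extraction and training, and a null signal stays at chance), and
the evaluation machinery's probability statements are calibrated. What
they do not show: performance on real speech, which carries phonetic
content, speaker variability, channel effects and far subtler emotion
cues than the synthetic profiles.

## Problem sizes and numerical choices

The evaluation-stack checks run at n = 360 segments (60 per class), the
size at which the Independent Validation bookkeeping is exact (36 initial
+ 36 validation + 288 streamed = 18 chunks of 16); cross-validation and
classifier unit checks use n = 60. Quadrature uses `scipy.integrate.quad`
with up to 200 subdivisions; dB computations floor at 1e-10 power;
feature standardization guards zero-variance columns. Degenerate inputs
are defined: silence is unvoiced with zero F0, flat by convention for
spectral flatness, zero centroid/rolloff/bandwidth, constant spectrogram.

## Known limitations

- The CNN at the full 240 × 320 × 3 contract is computationally heavy in
  a pure-numpy engine; learning-behavior tests use reduced image shapes,
  with the full-size path covered by contract tests.
- The autocorrelation F0 tracker is tuned for the generator's harmonic
  signals; real creaky or breathy voices would need a stronger tracker.
- Shapley estimates on cdnn models are supported through the feature
  route only; image-route attribution assumes a cnn model.
- Human-comparison utilities consume count tables; the package does not
  model rater effects.
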