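# Methods

`foldear` classifies short (1–3 s) mono audio segments recorded in a sheep
barn into three behavior classes — *foraging*, *rumination*, *other* — by
fusing hand-crafted acoustic features with deep features tapped from a
shallow CNN run over spectrogram images, and classifying the fused vector
with an SVM. This note records the model, its assumptions, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Signal model and assumptions

Foraging chews form a fast, fairly regular train of broadband transients;
rumination chews are slower, longer and lower in frequency; the residual
"other" class is heterogeneous (bleats, coughs, panting, ambient noise).
The pipeline assumes segments are already cut to single-behavior clips
(an energy/duration segmenter for long recordings is provided in
`audio_io`), mono, amplitude in [−1, 1], and that the sample rate is
carried as data — no resampling is ever performed implicitly.

## Time–frequency transforms (`spectrograms`)

* **STFT** — windowed DFT magnitude, `N = 2048`, periodic Hann window,
  one-sided spectrum (1025 rows). The hop is `N/4 = 512` (75 % overlap);
  the window and hop are not dictated by the protocol this reimplements
  and are pinned here as conventional defaults.
* **CQT** — evaluated directly from its definition with geometrically
  spaced bins `f_k = f_min · 2^(k/B)`, `K = 200` bins at `B = 32`
  bins/octave (6.25 octaves) from `f_min = 22.05 Hz`, quality factor
  `Q = 1/(2^(1/B) − 1) ≈ 45.7`, per-bin window length
  `N_k = ceil(fs·Q/f_k)`. Kernels at the lowest bins exceed the clip
  length (`N_k ≈ 10^5` samples at 48 kHz); such kernels are **truncated to
  the available signal and renormalized by the actual kernel length**,
  with the complex exponential keeping the nominal `N_k` so the analyzed
  frequency is unchanged. This preserves argmax behavior for audible bins
  and is the one deliberate deviation from the textbook transform.
  Configurations whose top bin exceeds Nyquist raise an error naming the
  first offending bin (unreachable at the default geometry for 16 or
  48 kHz input). Frames start at `τ·hop` (hop 512) for every offset
  inside the signal, with zero padding at the tail.
* **Mel spectrogram** — STFT magnitudes pooled through 128 triangular
  filters spaced uniformly on `Mel(f) = 2595·log10(1 + f/700)` between 0
  and Nyquist, peak weight 1 (no area normalization).

**Rendering.** Magnitude is mapped to dB (`20·log10(v + 1e-10)`), clipped
to 80 dB below the per-image peak, min–max normalized, passed through a
fixed 256-entry RGB lookup table shipped as package data (so images are
bit-reproducible across installs), and bilinearly resized with
half-pixel-centered sampling to the CNN's 100×100×3 input. dB rather than
linear magnitude is a choice (the combination with min–max normalization
makes images invariant to global gain); a flat image (silence) maps to
lookup entry 255 by convention. Whether to use dB was genuinely open and
is flagged here.

## Acoustic features (`acoustic_features`)

34 base features per 50 ms frame (25 ms hop — framing is a package choice,
conventional for short-term bioacoustics): zero-crossing rate, mean-square
energy, energy entropy over 10 sub-blocks; spectral centroid, spread,
entropy, flux (squared distance of successive L2-normalized magnitude
spectra, first frame 0) and 90 % roll-off, all on the un-windowed frame
rFFT with frequencies normalized to Nyquist = 1; 13 MFCCs (40-filter mel
bank on the power spectrum, log with 1e-10 floor, orthonormal DCT-II,
first 13 coefficients); and 13 chroma features — 12 semitone-class energy
fractions (A440 reference, DC bin excluded) plus their population standard
deviation. First-order frame deltas (first frame 0) double the set; the
segment descriptor is the per-column mean of the 68 columns. 34 base
features is the only count arithmetically consistent with the fixed total
of 68; the decomposition of "13 chroma" into 12 classes + std is likewise
the only one consistent with 12-tone chroma.

Standardization is (x − mean)/sd with the population (divide-by-n)
standard deviation, fitted on training rows only; zero-variance columns
get scale 1 and therefore standardize to exactly zero.

## Feature selection (`feature_selection`)

Recursive elimination uses a linear-kernel SVM (`C = 1`; the RBF
classifier used downstream has no per-feature weights), removing one
feature per step by smallest squared weight summed over the one-vs-rest
class vectors. The full elimination order is computed once on the training
split; stratified 5-fold CV weighted F1 is then scored at every surviving
count 1..p, and the count with the best mean (smallest on ties —
parsimony) is selected. Permutation importance (mean drop in weighted F1
over seeded column shuffles) is reported separately and never drives
elimination. The elimination machinery is backed by scikit-learn's RFE and
cross-validation utilities.

## SheepVGG-Lite (`deep_model`)

Fixed architecture: conv 3×3 (stride 1, pad 1) 3→16, ReLU, maxpool 2×2;
conv 3×3 16→32, ReLU, maxpool 2×2; flatten (25·25·32 = 20,000); FC1
20,000→128 with ReLU; FC2 128→3 logits — 2,565,603 float32 parameters,
10.26 MB serialized. The FC1 width (128) and the 3×3 kernels are package
choices pinned so the serialized model stays within the ~11.7 MB
compactness budget the design targets; "two sets of convolutional layers"
is realized as one conv per set. Class order is fixed alphabetically
(foraging = 0, other = 1, rumination = 2) and recorded in every artifact.

The network is implemented in plain numpy — im2col convolutions with
hand-written backward passes verified against numerical differentiation —
so training is exactly reproducible from the seed on one CPU. Training:
Adam (β₁ 0.9, β₂ 0.999, ε 1e-8; moments in float64), batch size 32,
cross-entropy, learning rate interpolated linearly **per epoch** from 1e-3
(epoch 1) to 1e-4 (epoch 50), a stratified seeded 25 % validation split,
no augmentation; the returned weights are the checkpoint with the best
validation weighted F1 (earliest epoch on ties). Deep features are the
post-ReLU FC1 activations (128-d) or the FC2 logits (3-d), extracted
deterministically.

**EigenCAM.** The pooled post-ReLU activations of the last conv block
(25×25×32) are reshaped to 625×32 and projected onto their first right
singular vector; the sign making the projection's maximum positive is
chosen (the larger of the two maxima when both are positive), negatives
are clamped, and the map is bilinearly upsampled to 100×100 and min–max
normalized. All-zero activations yield a defined all-zero map. The
projection is invariant to positive rescaling of the activations.

## Classification protocol (`fusion_classify`)

Early fusion concatenates feature blocks column-wise (e.g.
`CQT_FC1 + STFT_FC1 + ACOUSTIC` → 128 + 128 + |selected| columns). The
corpus is split 80/20 stratified; CNNs are trained on the training split
only; acoustic selection runs on the training split only (with its own
train-fitted standardizer); a **single** standardizer is then fitted on
the fused training matrix — deep and acoustic blocks jointly — which is
one consistent resolution of a point the protocol leaves open. The SVM is
tuned by grid search (kernels {linear, rbf} × C ∈ {0.1, 1, 10}, gamma
"auto" = 1/D, stratified 5-fold weighted F1) and refitted on the full
training split; a fixed RBF/C = 1 setting is available via `use_grid=False`
(`--no-grid`). Metrics come from one-vs-rest confusion counts: per class
accuracy (TP+TN)/n, recall TP/(TP+FN), precision TP/(TP+FP),
F1 = 2PR/(P+R); report-level numbers are support-weighted averages in
percent, zero-denominator ratios are 0 by convention (warned). On a
full-coverage multiclass evaluation the overall accuracy equals the
weighted recall exactly — the identity behind evaluation tables whose
accuracy and recall columns coincide.

## Synthetic corpus (`synthetic_barn`)

The generator emulates the class structure the classifier assumes:
foraging = band-passed (1–6 kHz) noise bursts of 40–80 ms at 3.5 events/s;
rumination = 0.4–3 kHz bursts of 80–150 ms at 1.25 events/s; other = a
0.4/0.2/0.2/0.2 mixture of bleats (harmonic stacks, f0 200–500 Hz, five
harmonics, slow vibrato), single loud broadband coughs, soft 2 events/s
panting, and noise-only clips. Event onsets are jittered-periodic
(±15 % of the period). The background is pink (1/f) noise — closer to barn
ambience than white — scaled to a default 10 dB below event RMS; segments
are peak-normalized to 0.9 and written as 16-bit PCM WAV with per-file
seeds derived from the master seed (SHA-256), so corpora are reproducible
file-by-file.

The reference evaluation corpus is 60 segments per class at 16 kHz,
seed 7. 16 kHz (not the 48 kHz of the recording hardware) keeps a full
pipeline run to minutes; every property exercised — transform geometry,
feature behavior, fusion — is sample-rate-agnostic. What the generator
does **not** model: room reverberation, overlapping animals, microphone
coloration, weather noise, and the long-tailed variability of real barn
sound. Passing the end-to-end benchmark therefore demonstrates that the
pipeline's stages compose correctly and can exploit class structure of
this kind — not that the reported synthetic accuracies transfer to real
recordings.

## Numerical choices and degenerate inputs

* Periodic Hann windows throughout; frames never padded (trailing partial
  frames dropped), so frame counts follow `floor((n − L)/hop) + 1`.
* Silence: empty segment list from the segmenter; all-zero spectrogram
  renders as a uniform image; zero spectra yield 0 for centroid, spread,
  entropy, roll-off and chroma.
* PCM16 round-trip: write quantizes with `round(x·32768)` clipped to the
  int16 range, the exact inverse of the read scaling, so audio survives a
  write/read cycle within 1 LSB.
* Ties: best-F1 checkpoint keeps the earliest epoch; RFE count ties go to
  the smaller subset; the max-pool gradient routes to the first argmax.
* Grid-search and CV folds are stratified and seeded; every stochastic
  stage takes an explicit seed and records it in its outputs.

## Known limitations

* The CQT is direct evaluation (no multi-rate fast algorithm); fine for
  1–3 s clips, quadratic-ish for minutes-long audio.
* CPU-only training; the architecture is small enough that a full 50-epoch
  run on a few hundred images takes on the order of two minutes per
  representation.
* The acoustic feature definitions are pinned, documented conventions;
  other toolkits differ in windowing, normalization and MFCC details, so
  absolute feature values are not interchangeable with theirs.
* Synthetic-data results bound nothing about real-barn performance (see
  above); the package's claims are about correctness and reproducibility
  of the method, which the oracle-equivalence tests check directly.
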