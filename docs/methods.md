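# Methods

## Problem and data model

The package classifies a person's affective state — valence (pleasant vs
unpleasant) and arousal (calm vs activated) — from short segments of
scalp EEG. The input layout follows the preprocessed DEAP distribution:
per participant, a tensor of 40 video trials × 40 channels × 8064
samples at 128 Hz (63 s: 60 s of stimulus plus a 3 s pre-trial segment),
and four continuous self-assessment ratings per trial (valence, arousal,
dominance, liking) on a 1–9 scale. The full 8064-sample trial is used
for feature extraction; the printed window counts throughout the
pipeline are only consistent with that choice, so no pre-trial trimming
is applied. Only the first 32 channels are EEG (Geneva electrode order);
feature extraction uses the 14 electrodes of the Emotiv EPOC+ montage,
resolved by name to 0-based indices — names are unambiguous where
1-based vs 0-based numbering is not.

## Feature extraction

Sliding windows of length *W* samples advance by a step of *S* = 16. A
start offset *s* (a multiple of *S*) is admitted iff **s + W < L**
strictly. This inclusion rule is load-bearing: it reproduces the
windows-per-trial counts for every studied window size (488 at *W* =
256, 440 at *W* = 1024, 504 at *W* = 4, …), and the test suite pins it
against brute-force enumeration.

Each window is transformed with the one-sided DFT and per band the
magnitudes |X[k]| are summed over the bins *k* with low ≤ k·Fs/W < high.
Numerical/design choices, each with its rationale:

- **Sum of magnitudes, not squared magnitudes.** The aggregation is not
  uniquely determined by the published description; the sum of |X[k]| is
  adopted and pinned by an O(N²) direct-DFT oracle test (1e-9 relative
  tolerance). Switching to means or squares rescales columns and is
  largely neutralized by the standardization step that follows.
- **Half-open band edges [low, high)** so adjacent bands never
  double-count a bin. The five-band bank is theta [4, 8), alpha [8, 12),
  low beta [12, 16), high beta [16, 25), gamma [25, 45) Hz, consistent
  with DEAP's 4–45 Hz band-pass.
- **No taper, no detrending.** None is stated upstream, none is applied.
  The DC bin is excluded by construction (all band lows ≥ 4 Hz).
- **Short-window degeneracy is legal.** At *W* = 4 the bin spacing is
  32 Hz and most bands have an empty bin set; their features are 0 and
  the standardizer substitutes scale 1 for the constant columns (with a
  logged warning) rather than failing.

Standardization uses scikit-learn's `StandardScaler`. By default the
statistics are fitted on the **full** feature matrix before the
train/test split, matching the reference protocol's stated order of
operations; this leaks test-set statistics into training and is
therefore optimistic. `standardize_on="train"` fits on training rows
only and applies the frozen statistics to the held-out rows.

## Labels, extension, splitting

Ratings binarize as [1, 5) → class 0 and [5, 9] → class 1 (a rating of
exactly 5 is class 1), one-hot encoded. The feature extension appends
the non-target ratings as input columns in the fixed order of the rating
vector (valence, arousal, dominance, liking, minus the target): widths
70/71/72/73 for none/FE-L/FE-L-D/FE-3. The target itself is structurally
excluded; feeding the correlated other ratings is the method's
deliberate design and the main accuracy lever on real data.

The split defaults to **window-row** granularity with a seeded shuffle
and train size `round(fraction × total)` exactly — the only protocol
reproducing the published sample sizes (e.g. 468,480 / 156,160 at 75/25
on 624,640 rows). Because all windows of a trial share its label, row
splitting places sibling windows on both sides, which inflates held-out
accuracy; a trial-unit split (whole trials to one side) is provided for
honest generalization estimates. During training the held-out test set
doubles as the per-epoch validation set, as the reference protocol
implies; pass a separate validation set for a three-way split.

## Architectures

Five 1-D CNNs (channels-last, stride-1 same-padded convolutions, ReLU,
non-overlapping max pooling, dropout 0.25, 2-way softmax) form a
parameter-reduction ladder. The published description fixes each
variant's layer structure and its exact trainable-parameter total at
input width 73, but not the per-layer hyper-parameters; the counts are
the only bit-exact fingerprint available, so filter counts, kernel
sizes, pooling and dense widths were solved by integer search within the
stated structure to land every count exactly:

| id | structure (all conv k=5 unless noted) | residual wiring | params |
|----|---------------------------------------|-----------------|-------:|
| M1 | conv 64 ·p2· conv 64 ·p2· conv 128 ·p2· conv 128 → dense 2496 → 544 → 2 | identity skips conv1→conv2, conv3→conv4 | 4,381,410 |
| C3D2 | conv 16 · conv 24 ·p2· conv 24 ·p3 → dense 224 → 2 | identity skip conv2→conv3 | 70,130 |
| C2D2 | conv 64 ·p2· conv 32 ·p4 → dense 160 → 2 | 1×1 projection skip | 59,298 |
| M2 | conv 96 · conv 40 → dense 2 | 1×1 projection skip | 29,538 |
| C1D2 | conv 16 (k=7) ·p3 → dense 48 → 2 | none | 18,706 |

(pN = max-pool of size N.) Where successive widths match, the skip is a
parameter-free identity add — removing it changes the forward function
but not the count, which the tests assert; where widths differ, the 1×1
projection's weights are part of the fingerprint. Dropout adds no
parameters, so regularization never perturbs the counts. The
parameter-data-ratio denominator (384,000) matches no array size in the
pipeline and is kept as an explicit constant, not derived.

The network engine (Conv1D/Dense/ReLU/MaxPool1D/Dropout/residual
add/softmax, Adam) is implemented in numpy with hand-derived backward
passes, verified against central finite differences. It is deliberately
minimal: stride-1 same-padding convolutions with odd kernels and
non-overlapping pooling are the entire vocabulary the model family
needs.

## Training protocol

Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), categorical cross-entropy, batch size
100, up to 100 epochs, seeded shuffling — the reference
hyper-parameters. Per-epoch train/validation accuracy is traced for
learning-curve plots; both final-epoch and best-epoch validation
accuracies are recorded, and final-epoch is the reported number (the
choice between them is not pinned externally). A non-finite loss aborts
with diagnostics rather than training through NaNs. Determinism holds
for fixed seeds.

## Synthetic generator: what it emulates, and what not

Each channel is a sum of per-band band-limited noise components —
white noise spectrally confined to the band and RMS-normalized — whose
amplitudes follow `base + slope · (rating − 5)/4` for a designated
rating, plus a broadband noise floor (default 0.5). Defaults: alpha
tracks valence (slope 0.8), high beta tracks arousal (slope 0.6), other
bands rating-blind. Band-limited noise rather than pure tones gives the
FFT features realistic within-band spread; classification is learnable
but not degenerate. Ratings are drawn per trial (independent uniform on
[1, 9] by default) and held constant across the trial's windows,
mirroring per-video labels. A single seed derives per-(participant,
trial) substreams, so partial regeneration is stable.

The two-cluster law used in separability studies pins the target rating
to {2, 8} in a **balanced design** (half the trials each, seeded order)
with a strong alpha gain (base 1.8, slope 2.4: amplitude 0 at rating 2,
3.6 at rating 8). This is the study condition under which the light M2
model is expected to exceed 95 % held-out accuracy, the permutation
null (target column shuffled across windows) to sit near 50 %, and
held-out accuracy to grow with window size (longer windows resolve the
bands better; at very short windows only spectral leakage of the
amplitude difference remains).

What the generator does **not** emulate: the 1/f background spectrum,
artifacts (ocular, muscular), inter-channel covariance and volume
conduction, non-stationarity within trials, or any genuine physiology of
emotion. Passing tests therefore demonstrate that the pipeline's
machinery — windowing, spectral estimation, label plumbing, training —
is correct and sensitive to planted spectral structure; they say nothing
about accuracy attainable on real recordings.

## Problem sizes used in the test suite

Structural checks (window algebra, split sizes, parameter counts) run at
the full published scale, since they are pure arithmetic. Behavioral
checks train on reduced problem sizes chosen to keep the pipeline
representative: four synthetic participants at full DEAP geometry with
every 4th feature row (19,520 rows, 2 epochs) for the separability and
permutation-null checks, and two participants with every 8th row for the
nine-point window sweep. The separable condition saturates well within
these budgets (it reaches perfect accuracy in one epoch at full row
count), so the reductions do not change any conclusion.

## Known limitations

- The per-layer hyper-parameters are one exact solution to the published
  parameter counts within the published layer structure, not a
  transcription of the original diagrams; other solutions exist.
- Row-level splitting (the default, for fidelity to the reference
  protocol) overstates generalization on both real and synthetic data;
  use `SplitSpec(unit="trial")` for subject-internal honest estimates.
- The evaluation protocol is subject-dependent (windows of all
  participants pooled); no subject-independent mode is provided.
- The numpy engine targets clarity and testability, not speed: expect
  roughly a minute per epoch on ~80k rows of width 73 on one CPU core.
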