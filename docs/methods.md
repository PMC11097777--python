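# Methods

## Problem setting

In rapid serial visual presentation (RSVP) target detection, images are
flashed at ~10 Hz and rare task-relevant images (1–4% of trials) evoke a
P300: a positive event-related deflection peaking roughly 300 ms after
stimulus onset, strongest over centro-parietal electrodes. The classifier's
job is single-trial: given one 62 × 250 epoch (0–1000 ms at 250 Hz),
output the probability that the trial contained a target. Two properties
dominate the design: the signal-to-noise ratio of a single trial is low,
and the classes are severely imbalanced.

## Preprocessing

Channel selection keeps channels 1–32, 34–42 and 44–64 of a 64-channel
montage (62 channels); the two dropped indices are taken literally, since
the montage identity of those electrodes is a property of the recording
system, not of this package. The continuous signal is bandpassed at
2–30 Hz with a Butterworth filter before epoching, so filter transients
never touch the analysis windows. The filter order is 4 and it is applied
forward–backward (zero phase) by default: zero-phase filtering preserves
P300 latency, which matters because the network's temporal kernels are
latency-sensitive. Epoch windows are half-open `[start, end)`, so 0–1000 ms
at 250 Hz yields exactly 250 samples. No baseline correction is applied by
default (it is available as an option); no artifact rejection,
re-referencing or resampling is in scope.

## Architecture

The network is an EEGNet-style compact CNN with two pyramid squeeze
attention (PSA) insertions. Feature maps are (batch, channels, electrodes,
time). Defaults: F₁ = 8 temporal filters of extent 125 samples, depth
multiplier D = 2 (F₂ = 16), separable kernel 16, pools (1, 8), dropout 0.5,
PSA kernels (3, 5, 7, 9) after the spatial stage and (1, 3, 5, 7) in the
separable stage (the "A+B" configuration, which maximises TPR among the
swept kernel sets; sets A–E are all available). The classifier input is
16 × 4 = 64 features.

Decisions where the printed architecture left room:

- **Pooling lengths.** 250/8 truncates to 31, but the second pool must emit
  4 (not floor(31/8) = 3) for the flattened size of 64 to hold. Pools
  therefore take an explicit target output length; the final window of the
  second pool averages only the 7 real samples (padding never enters the
  average). With no explicit lengths the first pool floors and the second
  ceils, reproducing the same walk for any input length.
- **Padding.** Both temporal convolutions use symmetric "same" zero
  padding — forced by the shape walk (250 → 250, 31 → 31). The even-length
  kernels (125 is odd, 16 is even) put the extra padded sample on the left.
- **Biases.** All convolutions are bias-free (batch normalisation absorbs
  offsets); the classifier keeps its bias.
- **The PSFE stage normalises and activates both before and after its PSA
  block** — implemented literally from the layer table.
- **Windowed pools, not global.** The layer table specifies (1, 8) windows
  with outputs 31 and 4; that is what is built.
- **Initialisation** is truncated-normal (±2 SD) with fan-in scaling,
  seed-controlled; the classifier bias starts at zero.

### The PSA block

The block splits its C input channels into S = 4 contiguous groups;
branch i convolves its group with a 1 × kᵢ kernel ("same" padding, no
bias, plain convolution within a branch — the channel counts here are far
too small for grouped-convolution schedules). Each branch is squeezed by
global average pooling and passed through a two-layer bottleneck
(hidden width max((C/S)/4, 1), rectifier, then a logistic squash), giving
per-channel attention logits in (0, 1). For every channel slot the S
logits are softmax-normalised across branches (max-subtracted for
stability; weights sum to 1 within 1e-6) and each branch is multiplied
elementwise by its weights before concatenation. Output shape always
equals input shape. A full-channel variant (each branch reads all C
channels) exists behind a config flag; the split variant is the default.
A PSA block placed in the first (PTFE) stage is deliberately not built:
at that stage the feature map is 62 × 250 and the block's cost is far out
of proportion to the rest of the network.

## Numerics

The network, its gradients, and Adam are implemented in numpy. Long
temporal convolutions (kernel ≥ 32) are evaluated in the frequency domain
via real FFTs with linear-convolution padding; short ones with
sliding-window views contracted by einsum. Both paths are exact (they
agree to ~1e-15 relative) and share one gradient derivation; the test
suite checks every parameter group against central finite differences.
Batch normalisation uses biased batch variance, momentum 0.1 running
statistics, and requires batch ≥ 2 in training mode (eval mode accepts
single trials and is fused into one multiply-add). The softmax layer
backpropagates its exact Jacobian; the cross-entropy floors probabilities
at 1e-12 inside the logarithm. Computation is float32 by default;
float64 is available for verification.

## Training protocol

Adam (0.9, 0.999, ε 1e-8) at learning rate 0.001, batch 64. The loss is
class-weighted cross-entropy with w_c = n/(2 n_c) ("balanced"); with 1–4%
targets the weighting is what keeps the optimiser from collapsing onto the
majority class. A stratified 20% of the *training* trials is held out as
the validation monitor — the outer test folds are never touched during
fitting, which is the only leak-free reading of "validation loss" in a
cross-validated protocol. Improvement means a strict decrease of more than
1e-5 (float-jitter guard). After 5 consecutive non-improving epochs the
learning rate is halved (floor 1e-6, counter resets after each halving);
after 20 non-improving epochs training stops and the best-epoch weights
are restored. `max_epochs` defaults to 500; tests and examples use much
smaller budgets because the synthetic problems converge in a handful of
epochs. One seed fans out (via `SeedSequence`) to the split, the shuffling
and the dropout, making runs bit-reproducible.

## Metrics

ACC, TPR, FPR and F1 come from hard decisions at p(target) > 0.5 (the
threshold is configurable; with a two-unit softmax this equals argmax).
Zero-denominator ratios are reported as NaN, never as silent zeros. AUC is
the pairwise ranking probability over all P × N target/non-target pairs,
computed from rank sums in O(n log n), with a brute-force double loop kept
in the tests as the oracle. Two tie policies exist: `strict` (a tied pair
scores 0 — the literal indicator) and `half` (ties score 0.5 — the
Mann–Whitney convention and the reporting default, equal to standard
ROC-AUC).

## Cross-validation and ablations

Stratified k-fold (default k = 5) shuffles within class and deals
round-robin, so per-fold positive counts differ by at most one;
disjointness and coverage are asserted at runtime. Folds whose test part
lacks one class get an undefined AUC, excluded from means with a logged
note. Ablation sweeps (A+A, A+0, 0+A, EEGNet control; pyramid kernel sets
A–E for the second PSA) run every variant on byte-identical fold splits so
comparisons are paired. Statistical testing across variants is out of
scope; the tidy per-fold export is designed to feed any external test.

## Synthetic data

No generative model of RSVP EEG is prescribed anywhere in the protocol, so
the generator is a package-level design: it emulates classic P300
phenomenology rather than fitting any dataset.

- **Stimulus stream:** events every 100 ms (10 Hz); each is a target with
  probability 2% by default (inside the 1–4% oddball range).
- **Target response:** a Gaussian bump, unit peak at 300 ms, width (SD)
  60 ms, scaled by 5 µV nominal amplitude, a per-trial lognormal amplitude
  factor (σ = 0.3, mean 1) and a per-channel topography gain that peaks at
  1 on three designated centro-parietal channels (rows 28–30) and decays
  exponentially with channel distance (arbitrary but fixed). Latency is
  jittered per trial (truncated normal, SD 30 ms, clipped at ±3 SD).
  Overlapping responses superpose linearly — at 10 Hz, 1 s epochs overlap,
  exactly as in real RSVP; an independent-epoch mode spaces stimuli one
  epoch apart for tests that need i.i.d. trials.
- **Background:** 1/f noise (exponent 1, 4 µV RMS) mixed across channels
  through a shared component (mixing 0.3), a 10 Hz alpha oscillation
  (2 µV, random per-channel phase), and 1 µV white sensor noise. The noise
  amplitudes are conventions chosen to put the default 5 µV P300 at a
  plausibly hard single-trial SNR while a 20 µV P300 is reliably decodable.

What the generator does *not* emulate: biophysical volume conduction, eye
or movement artifacts, non-stationarity across blocks, inter-subject
topography variability, or the exact statistics of any public benchmark.
Passing tests on synthetic subjects therefore demonstrate that the
pipeline is correct and that the architecture can learn P300-like
structure under oddball imbalance — not that any particular real-data
score will be reached.

## Test-scale choices

The behavioural acceptance tests use deliberately small budgets chosen as
package defaults for desk-scale verification: the learnability check
trains 5-fold CV on a 2000-stimulus, 5%-target, 20 µV subject for up to 8
epochs; the null check (0 µV) uses 3 epochs, since no amount of training
can create signal where labels are independent of data; the
class-weighting comparison trains 4 epochs on 1000-stimulus, 2%-target
subjects over 5 paired seeds; ablations train 1 epoch on 2 folds of a
300-stimulus subject. Real-data runs would use the full protocol
(max_epochs 500 with early stopping).

## Known limitations

- No real-data loader is bundled: the package consumes generic epoch
  arrays (HDF5/NPZ); parsing any benchmark's native format is a documented
  extension point.
- The numpy implementation is CPU-bound and single-threaded BLAS-scale:
  fine for the compact network (3490 parameters), not intended for large
  architectures.
- The montage identity of the dropped channels (33, 43) and the absence of
  re-referencing are taken as given; the index list is applied literally.
- AUC on folds with a single-class test set is undefined and excluded;
  with fewer positives than folds this is unavoidable and is surfaced as a
  warning rather than hidden.
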