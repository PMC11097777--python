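# psaeegnet

Single-trial detection of the P300 event-related potential in rapid serial
visual presentation (RSVP) EEG, using a compact convolutional network with
pyramid squeeze attention (PSA) blocks — plus everything needed to exercise
it end to end: preprocessing, a class-imbalance-aware training protocol,
ranking metrics, stratified cross-validation, ablation sweeps, and a
synthetic oddball EEG generator so the whole pipeline runs with no data
download.

## Who this is for

BCI / EEG-decoding researchers who need a reproducible, dependency-light
reference implementation of an attention-augmented EEGNet-style classifier
for oddball paradigms, where targets occur on only 1–4% of trials and the
sensitive metrics are the true positive rate (TPR) and the pairwise AUC.

## The model

An epoch is a 62-channel × 250-sample (0–1000 ms at 250 Hz) matrix **X**.
The network is four stages:

1. **PTFE** — temporal convolution, F₁ = 8 filters of size (1, 125), same
   padding, batch norm → feature map (8, 62, 250).
2. **PSFE** — depthwise spatial convolution (62, 1) with depth multiplier
   D = 2 (F₂ = 16 spatial filters), BN + ELU, a PSA block with pyramid
   kernels (3, 5, 7, 9), BN + ELU, average pool (1, 8) → (16, 1, 31),
   dropout 0.5.
3. **DTFE** — separable convolution: depthwise (1, 16), a second PSA block
   (kernels (1, 3, 5, 7) in the default model), pointwise (1, 1), BN + ELU,
   average pool (1, 8) → (16, 1, 4), dropout 0.5.
4. **Classifier** — flatten to 64 features, affine map to 2 units, softmax.

A PSA block splits its C channels into S = 4 groups, convolves each group
at its own temporal scale kᵢ, squeezes each branch with a
squeeze-and-excitation bottleneck into per-channel logits, normalises the
logits across branches with a softmax (so for every channel slot the S
scale-weights sum to 1), and rescales each branch elementwise:

    out = concat_i ( Fᵢ ⊙ softmax_i(SE(Fᵢ)) )

Training follows the standard imbalance-aware protocol: Adam (lr 0.001,
batch 64), cross-entropy weighted by w_c = n/(2 n_c), learning rate halved
after 5 epochs without validation-loss improvement, early stopping after
20, best weights restored. Evaluation reports ACC, TPR, FPR, F1 and the
pairwise AUC = (1/PN) Σᵢ Σⱼ I(pᵢ > pⱼ) over all target/non-target pairs.

The network and its gradients are implemented directly in numpy (verified
against finite differences in the test suite); no deep-learning framework
is required.

## Worked example

```python
import psaeegnet as pg

# a synthetic RSVP subject: 10 Hz stimuli, 5% targets, strong 20 uV P300
epochs = pg.simulate_subject(pg.SimConfig(n_stimuli=800, target_prob=0.05,
                                          p300_amplitude=20.0, seed=7))
train, test = epochs.subset(slice(0, 600)), epochs.subset(slice(600, 800))

model = pg.PSAEEGNet(train)
result = model.fit(seed=1, max_epochs=3)
report = result.evaluate(test)
print(f"test AUC: {report.auc:.4f}  TPR: {report.tpr:.3f}")
```

This prints (numbers from this exact run):

```
test AUC: 0.9069  TPR: 1.000
```

meaning a random target trial outranks a random non-target ~91% of the time
after three epochs of training on 600 trials, and every true target in the
held-out 200 trials was detected at the 0.5 threshold. `result.summary()`
prints the fitted model card (trial counts, 3490 trainable parameters, best
epoch, validation loss). For the full protocol use
`pg.run_cv(epochs, k=5, seed=...)` (stratified five-fold cross-validation)
and `pg.run_ablation(...)` for paired variant comparisons (A+A, A+0, 0+A,
EEGNet control, and pyramid kernel sets A–E).

A CLI wraps the same pipeline:

```bash
psaeegnet shapes                          # layer-by-layer shape walk
psaeegnet simulate --out subj.h5 --seed 1 --n-stimuli 400
psaeegnet train subj.h5 --out run/ --seed 1
psaeegnet evaluate run/checkpoint.npz subj.h5
psaeegnet ablate subj.h5 --out ablation/ --k 5 --seed 1
```

## Layout

- `psaeegnet.preprocessing` — channel selection, Butterworth bandpass, epoching
- `psaeegnet.attention` — the PSA block
- `psaeegnet.network` — architecture, variants, shape contracts
- `psaeegnet.training` — weighted CE, LR plateau schedule, early stopping
- `psaeegnet.metrics` — ACC/TPR/FPR/F1 and pairwise AUC (both tie policies)
- `psaeegnet.crossval` — stratified k-fold, ablations, aggregation
- `psaeegnet.synthetic` — the oddball RSVP generator
- `psaeegnet.model` — `PSAEEGNet` / `PSAEEGNetResults` front door
- `docs/methods.md` — modelling assumptions, defaults and their rationale
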