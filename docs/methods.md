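# Methods

## Problem setting

An SSVEP-based brain–computer interface presents a grid of visual targets,
each flickering at a distinct frequency (and phase). Fixating a target
entrains occipital/parietal EEG at that frequency and its harmonics; the
decoding task is to recover the fixated target from a short multi-channel
EEG window. The package implements a hybrid decoder — an unsupervised
shared-weight multi-channel RBM feature extractor followed by a supervised
spatiotemporal CNN — together with the classical FBCCA template decoder, the
epoch-extraction conventions of two public benchmark protocols, and a
synthetic signal generator that stands in for the recordings.

## Epoch extraction

Two tensor layouts are supported: `[64 ch, 1500 samples, 40 targets,
6 blocks]` at 250 Hz, and `[12 targets, 8 ch, 1114 samples, 15 blocks]` at
256 Hz. Processing order is: select channels (the 9 parieto-occipital
electrodes Pz, PO5, PO3, POz, PO4, PO6, O1, Oz, O2 for the 64-channel
layout; all 8 for the other), expand `targets × blocks` into independent
trials (240 / 180 per subject), crop the analysis window, then band-pass.

* **Window start.** The stimulus begins 0.5 s (first protocol) or 0.15 s
  (second) into the trial, and the cortical response lags it by ~0.14 s, so
  windows start at 0.64 s and 0.29 s respectively. Indices are 0-based,
  half-open, `index = round(seconds × fs)` — e.g. sample 160 for 0.64 s at
  250 Hz, sample 74 for 0.29 s at 256 Hz.
* **Filtering.** 8–90 Hz Butterworth of order 4, applied forward–backward
  (`sosfiltfilt`): the stated design order with zero phase; the doubled
  effective attenuation order is accepted in exchange for no latency
  distortion. Edges use the default odd-reflection padding. Filtering after
  cropping follows the protocols' processing order.
* **Segmentation.** Default is one window per trial (`one_per_trial`), which
  keeps the 240/180 totals; non-overlapping tiling of the remaining signal
  is available by flag since per-window trial totals are protocol-dependent.

## Multi-channel Gaussian–Bernoulli RBM

One RBM per channel with `W [Nv×Nh]`, `a`, `b` shared across channels; the
energy is additive over channels (see README for the formula), making the
conditionals per-channel: Bernoulli hidden units with probability
`σ(vW + b)` and unit-variance Gaussian visible units with mean `hWᵀ + a`.

* **Standardization.** The energy's `v²/2` term and the unit conditional
  variance presuppose unit-scale visibles, so each channel of each trial is
  standardized to zero mean, unit variance before entering the RBM.
* **CD-k schedule.** Positive statistics pair the data with hidden
  *probabilities*. The negative chain samples binary hidden states; the
  visible reconstruction uses the conditional mean by default (a standard
  variance-reduction choice for CD-1), and `CDConfig.sample_visible=True`
  draws the Gaussian conditional — required whenever the negative chain must
  genuinely sample the model, as in the long-chain gradient diagnostics.
  Negative statistics use the final visibles with hidden probabilities.
  Statistics are averaged over the channel axis (factor `1/Nc`) and batch.
* **Pretraining.** Plain SGD on the CD gradient (learning rate 1e-3 default,
  50 epochs, batch 32, weights initialized N(0, 0.01²), biases 0, seeded).
  Adam is reserved for the supervised phase.
* **Features.** The map passed downstream is the deterministic hidden
  probability matrix `σ(vW + b) [C×Nh]` — probabilities rather than samples,
  so feature extraction is reproducible bit for bit. Default `Nh = 256`.

### Exact oracles

For `Nh ≤ 12` the module computes exact quantities by enumerating hidden
configurations and integrating the Gaussian visibles in closed form:

```
log Z = Nc · [ (Nv/2)·log 2π + logsumexp_h ( bᵀh + ‖Wh + a‖²/2 ) ]
```

giving `log p(v)`, its exact parameter gradient (the negative phase is an
exact expectation over the `2^Nh` hidden states, with `E[v|h] = Wh + a`),
and exact hidden marginals. These oracles back the test suite: CD-100 update
directions align with the exact gradient (mean cosine ≈ 0.99 on
`Nv=3, Nh=2` instances), and a 10⁵-sweep alternating Gibbs chain reproduces
the exact hidden marginals. Chain averages are autocorrelated, so their
standard errors are computed by the method of batch means (50 batches)
rather than the independent-sample formula.

## CNN classifier

Implemented on a small numpy engine (`nn.py`) with explicit
forward/backward passes, verified against central finite differences
(relative error < 1e-5 in the tests). Architecture for input `[C, L]`:
`C×1` spatial conv (C filters) + batch norm + ELU; two temporal blocks
(`1×4` then `1×2` kernels, `2C` filters, batch norm, ELU, `1×2` max pool);
flatten; FC 512 → 128 → N with ReLU between, softmax in the loss.
Convolutions are valid (no padding), stride 1; pools are non-overlapping
with floor division of odd lengths. The flattened width is
`2C · floor((floor((L−3)/2) − 1)/2)` and is validated at build time (the
minimal admissible `L` is 9, reported in the error message). Batch norm uses
momentum 0.1 running statistics; in eval mode predictions are independent of
batch composition. No dropout, weight decay or label smoothing. Ties in the
argmax resolve to the lowest class index.

## Two-phase training and evaluation

* **Hybrid.** CD pretraining on the training fold, then the RBM feature map
  becomes the first (differentiable) layer of the network and the whole
  stack is fine-tuned end to end with Adam (lr 0.001) under cross-entropy;
  a `freeze_features` flag keeps the pretrained features fixed.
* **Ablations.** `mcrbm_only` classifies the flattened feature map with the
  FC head alone (no convolutions); `cnn_only` feeds the raw standardized
  window to the CNN (`feature_len = T`).
* **Splits.** Evaluation is subject-dependent. Default is leave-one-block-out
  cross-validation — each recording block is the test fold exactly once, so
  no trial of a test block ever appears in its training set; a stratified
  holdout (default 20%) is available for cheaper runs. The benchmark
  protocols' own train/test split is not published, so reported per-subject
  accuracies from those recordings are not reproduction targets.
* **Reports.** Per-subject accuracy, their unweighted mean and *population*
  variance (matching the convention of reporting variance across subjects),
  wall-clock per-sample classification time, and confusion counts.
* **Determinism.** All randomness flows from one seed through
  `numpy.random.SeedSequence` spawns; identical configurations reproduce
  identical accuracies on the same platform.

## FBCCA baseline

Templates per class: sine/cosine pairs at harmonics `m = 1..5` of the class
frequency, phase advancing as `m·φ` (phase-locked harmonics, matching the
generator's convention), harmonics at or above Nyquist dropped. Sub-bands:
five Butterworth band-passes `[8m, 88]` Hz (order 4, zero phase — the
package's filter convention; the original filter-bank formulation used
Chebyshev designs), combined with weights `w(n) = n^{−1.25} + 0.25`. These
are the canonical defaults of the method; all are configurable, and no claim
is made that they match any particular tuned configuration. The first
canonical correlation is computed by thin QR of the centered data matrices
followed by an SVD of `Q_xᵀQ_y`; rank-deficient inputs drop the deficient
directions with a warning (an all-zero trial scores 0 everywhere and
deterministically decodes as class 0).

## Synthetic generator

Channel `k` of a class-`c` trial carries
`g_k · Σ_m d^{m−1} sin(2π·m·f_c·(t−λ) + m·φ_c)` for `t ≥ λ`, zero before —
emulating the response latency — embedded in noise scaled to a requested
SNR (measured as mean-square power of the clean component over the realized
noise, exact to machine precision). Defaults: 3 harmonics with decay
`d = 0.5`; mixed noise (pink + white at 3:1 power; the pink component's
log-log periodogram slope is ≈ −1); channel gains increasing linearly from
0.4 to 1.0 toward occipital electrodes; SNR 0 dB. The default stimulus plans
are the two benchmark codings: 40 frequencies 8.0–15.8 Hz in 0.2 Hz steps
with 0.5π phase steps, and the standard 12-target plan (9.25–14.75 Hz,
phases 0/0.5π/π/1.5π per frequency column) — the latter chosen because the
12-target protocol's coding table is standard for that public paradigm.

What the generator does **not** emulate: non-stationary background rhythms
(alpha bursts), ocular/muscular artifacts, inter-trial latency jitter,
electrode-specific noise covariance, or subject variability. Synthetic
trials are therefore substantially easier than real recordings — the hybrid
model and FBCCA both saturate near 100% at moderate SNR — so passing
end-to-end tests demonstrates that the pipeline is wired correctly and
behaves monotonically with SNR and window length, not that real-data
accuracy levels are reproduced.

## Problem sizes used in the verification runs

The end-to-end checks use a 4-class plan (8/10/12/14 Hz), 50 blocks
(200 trials), 8 channels, 1 s windows, `Nh = 64`, 20 CD epochs and 40 Adam
epochs — small enough to run the whole suite and the acceptance script in a
few minutes on one CPU while leaving every stage of the pipeline exercised.
The oracle checks use `Nv = 3, Nh = 2` (CD vs exact gradient, 50 seeds ×
20 chains) and `Nv = 2, Nh = 2` (10⁵ Gibbs sweeps).

## Known limitations

* The numpy engine is single-threaded per BLAS call and trains at desk
  scale; it is not intended for full-size (`Nh = 256`, 240-trial, 35-subject)
  sweeps at interactive speed.
* Gradients flow through the deterministic sigmoid feature map during
  fine-tuning; stochastic hidden sampling is not propagated.
* Cross-subject transfer (leave-one-subject-out), information transfer rate,
  and significance testing across subjects are out of scope.
* MAT v5 input assumes one (or a named) 4-D variable per file; compressed
  v7.3/HDF5 MAT variants are not read by the MAT path.
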