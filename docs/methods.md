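# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## Signal model of the synthetic generator

A trial of class *k* (frequency *f_k*, phase *φ_k*) on channel *c* is

    s_c(t) = g_c · Σ_{h=1..H} a^{h−1} sin(2π h f_k t + h φ_k) + n_c(t)

* **Stimulus table.** 40 classes, frequencies 8.0 + 0.2·k Hz, phases
  k·0.5π mod 2π. The base phase of class 0 is 0 by convention (only the
  inter-class 0.5π step is part of the paradigm); it is configurable.
* **Harmonics.** H = 3 with amplitude decay a = 0.5 per harmonic. SSVEP
  responses carry energy at integer multiples of the flicker frequency with
  roughly geometrically decreasing amplitude; three harmonics keep the
  strongest structure while staying far from Nyquist at 250 Hz (the
  generator rejects configurations where h·f exceeds Nyquist).
* **Channel gains.** Default occipital-peaked profile
  0.3 + 0.7·exp(−d/(C/4)), d = distance from the occipital end of the
  canonical montage, reflecting where SSVEP responses are strongest;
  fully user-overridable.
* **Noise.** White Gaussian by default, optional 1/f ("pink") mode. The
  noise realisation is scaled per trial so that the ratio of clean power to
  noise power, averaged over channels with non-zero gain, equals the target
  SNR (0 dB default) exactly up to float rounding. Noise is added to all
  channels, including zero-gain ones.
* **Defaults as study conditions.** 64 channels, 250 Hz, 5 s of stimulation
  per trial, 6 trials per class — one per recording block of the emulated
  benchmark sessions.

What the generator does **not** emulate: cortical forward modelling,
inter-subject variability, non-stationarity, eye-blink/EMG artifacts, and
channel covariance structure beyond the gain profile. Passing tests on this
data therefore certify the *mechanics* of the pipeline and the network's
ability to recover frequency structure from noisy phase-locked harmonics —
they say nothing about accuracy on real recordings.

## Preprocessing

* **Filter.** Chebyshev Type I band-pass, passband 6–90 Hz, stopband
  corners 4–100 Hz. Order is the minimal one meeting 1 dB passband ripple
  and 40 dB stopband attenuation (`scipy.signal.cheb1ord`); these two
  numbers are our choice — the corner specification alone does not fix the
  design — and are recorded in `FilterSpec`. Applied forward–backward
  (zero phase) by default so segment boundaries are delay-free; note this
  doubles attenuation and ripple in dB terms.
* **Cropping.** Real-dataset trial layouts include a 0.5 s cue and 0.5 s
  offset around the stimulation window; `crop_stimulation` removes them.
  Synthetic trials are generated stimulation-only, so the pipeline defaults
  to no cropping.
* **Segmentation.** Non-overlapping windows of `ratio` seconds
  (`ratio ∈ {0.2, 0.4, 0.6, 0.8, 1.0}` in the standard sweep);
  t = floor(Len/(ratio·fs)) segments per trial, trailing remainder
  discarded, labels inherited from the trial.

## Architecture

Layer order: temporal conv (1×17, 64 maps, stride 1, SAME, batch norm,
linear) → 4 × [group depth-wise conv (1×17, stride 2, SAME, bias,
LeakyReLU 0.01, batch norm) + EEG attention] → dropout 0.5 → depth-wise
spatial conv (C×1, VALID, bias, ELU) → point-wise 1×1 to 16 maps (batch
norm, ELU, dropout 0.5) → flatten → dense (no bias) → softmax.

Design points that were genuinely open, and the choices made:

* **Group-block activation and op order.** The block's defining equation
  applies LeakyReLU to bias + convolution, while the accompanying layer
  table lists "linear activation" and places batch norm before it. We
  implement the equation literally (conv + bias → LeakyReLU) and put batch
  norm after the activation in the assembled network; this keeps the
  standalone block testable against a nested-loop oracle.
* **Cross-map sum.** "Depth-wise" naming notwithstanding, the block's
  equation sums over input maps *j* with per-channel kernels
  K_{i,j}^c; we implement that literally. Weight shape per block is
  (C, M_out, M_in, 17) — a factor C more kernels than a regular
  convolution of the same geometry, which is why the regular-conv ablation
  (model1) has *fewer* parameters.
* **SAME + stride 2 semantics.** Output length is ceil(L/2); the nominal
  "Ns/16" after four blocks is read as the idealized value (250 → 16,
  50 → 4).
* **Dropout placement.** Exactly two dropout layers (after the block stack
  and after the point-wise layer), not one per block.
* **Biases.** Present in the group blocks (the equation shows them) and the
  spatial conv; omitted where batch norm immediately follows (temporal
  conv, point-wise conv) because a preceding bias is absorbed by the
  normalisation. The dense layer has no bias (its defining equation has
  none).
* **Batch norm.** Momentum 0.1, ε = 1e-5 (library-convention defaults),
  normalising over the feature-map axis.
* **Attention placement and sharing.** Attention is applied after every
  group block, with independent parameters per block (standard for stacked
  attention); both are config switches (`attention_enabled`,
  `attention_shared`).

## EEG attention

* **Channel stage.** The "M 1×1 filters over the stacked avg/max pooled
  features" is realised as, per feature map m, one learned affine
  combination w_a·avg + w_b·max + b of the pooled pair, shared across EEG
  channels within the map — the fewest-parameter reading consistent with
  per-map filters acting along the channel axis. Sigmoid gives
  M_EC ∈ (0,1)^{C×M}.
* **Network stage.** Global avg/max per map over (C, L), shared bias-free
  MLP M → M/r → M with ReLU hidden nonlinearity, element-wise sum,
  sigmoid. The defining equation contains no bias terms, so none are used.
  The stage's input is the channel-refined cube F′ (the module's own output
  F″ would be circular). Reduction ratio r = 8 (hidden width 8 at M = 64),
  configurable — the value mirrors common channel-attention practice.
* **Max-pool ties** need no tie-break: only the pooled value is used in the
  forward pass; the backward pass routes the gradient to NumPy's argmax
  (first maximal element), which is deterministic.
* Both gates are strictly inside (0,1), so the module is shape-preserving
  and element-wise contractive; with all parameters zero it scales the cube
  by exactly 0.25.
* **CBAM variant (model6).** Channel attention (shared MLP over global
  avg/max map descriptors, r = 8) followed by spatial attention: avg/max
  pooling over the map axis and a kernel-7 convolution along the EEG
  channel axis, per the published CBAM defaults.

## Training and evaluation

* Loss: −(1/n) ΣΣ y_ij log s_ij + λ‖w‖², λ = 0.001. The penalty covers
  convolution, dense and attention weight matrices, not biases or batch
  norm scale/shift ("the weights of the model"). Its gradient 2λw is added
  explicitly so the optimised objective equals the reported loss exactly.
  Zero predicted probability at a true class is clamped at 1e-12 and
  logged.
* Init: every weight matrix i.i.d. N(0, 0.01) (std 0.1), biases zero,
  batch norm at identity; fully determined by one seed.
* Optimiser: Adam (0.9/0.999/1e-8) at lr 0.001, mini-batches of 64
  segments. The loss's t·D_b normalisation is ambiguous about whether a
  batch counts trials or segments; the default counts segments, and a
  `batch_by_trial` mode implements the trial reading (D_b trials → t·D_b
  segments per step).
* Early stopping on validation loss, patience 10, max 200 epochs
  (unspecified in the source; standard values). The best-validation
  weights are restored.
* Two-stage transfer: stage 1 trains from the Gaussian init on dataset A;
  stage 2 re-initialises from the stage-1 weights and fine-tunes on
  dataset B; both checkpoints are persisted.
* Cross-validation: stratified 10-fold, **grouped by source trial** —
  segments of one trial never straddle a split. Without grouping,
  within-trial correlation makes fold accuracy optimistically biased; this
  grouping is our choice and is stated prominently because it makes
  absolute numbers conservative relative to ungrouped splitting.
* Metrics: per-class one-vs-rest ACC/SEN/SPE, macro-averaged (the binary
  formulas do not define the multi-class case by themselves; macro
  averaging is symmetric in classes). Zero denominators yield a flagged
  0.0, never NaN.

## Channel montages

The canonical 64-channel ordering follows the public benchmark montage
(10-10 labels, front to back). Named subsets: occ3 = {O1, Oz, O2},
occ6 = occ3 ∪ {POz, PO3, PO4}, po9 = {O1, Oz, O2, Pz, PO3, PO5, PO4, PO6,
POz}. The 32-channel set is specified only as "occipital, parietal,
central and centro-parietal regions"; we ship the C/CP/P/PO/O rows of the
10-10 grid minus the vertex Cz (which brings the count to exactly 32) and
document it as our reading.

## Scaled experiment sizes

The shipped experiments are sized for a single CPU:

* **Frequency recovery** — 8 classes spread over the full band (1 Hz
  spacing), 8 channels, 25 trials/class of 5 s → 1000 one-second segments
  (800 train / 200 test, split by trial), 0 dB SNR, reduced network
  (16 maps, 2 blocks, attention on). The shuffled-label control permutes
  labels at the trial level so segments of a trial stay consistent.
* **Ablation study** — 4 classes, 6 channels, −8 dB SNR, 0.5 s segments,
  8 maps, full (4-block) model vs model2 (shallow) and model3 (no
  attention), 5 seeds. At these sizes the depth comparison is noisy — a
  shallow model can win on a small, easy task — so the ordering is
  reported with seeds rather than asserted.

## Known limitations

* No GPU path; the NumPy engine is single-threaded per BLAS configuration
  and sized for the scaled experiments, not for 64-channel/40-class
  training at full dataset scale.
* float32 forward/backward; the test suite converts to float64 for
  numerical gradient checks.
* The synthetic data cannot support claims about real-EEG accuracy (see
  generator caveats above).
* The MAT reader targets the benchmark-style 4-D trial array only; no
  EDF/BDF support.
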