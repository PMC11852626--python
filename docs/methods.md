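# Methods

## Problem and model

`cltnet` decodes motor-imagery (MI) EEG: cue-aligned multichannel epochs
(trials × channels × samples, typically 250 Hz) are classified into imagined
movements (left hand, right hand, feet, tongue in the 4-class paradigm). The
discriminative physiology is event-related desynchronization/synchronization
(ERD/ERS) — task-specific attenuation or enhancement of the sensorimotor mu
(8–12 Hz) and beta rhythms over motor cortex.

The classifier is a hybrid of three stages applied to a trial X ∈ R^{C×T}:

1. **CNN stage.** A temporal convolution (F1 filters of length KC1, 'same'
   zero padding, shared across electrodes) extracts band/temporal features; a
   depthwise spatial convolution (one (C, 1) filter per temporal map, depth
   multiplier D) learns spatial patterns across the montage, yielding F2 =
   F1·D maps of spatial extent one; batch normalization, ELU and average
   pooling (1, pool1) follow, then a second full temporal convolution (F2
   filters of length KC2, 'same' padding), batch norm, ELU and pooling
   (1, P2). Both convolution blocks end with dropout. The output is reshaped
   to a feature sequence S ∈ R^{TC×d} with d = F2 and
   TC = ⌊⌊T/pool1⌋/P2⌋ (floor division at both pooling stages). With the
   defaults (T = 1000, pool1 = P2 = 8, F2 = 16) this is a 15-step sequence of
   16 features, and the KC2 = 16 kernel at the nominal 32 Hz post-pooling
   rate spans 500 ms of signal.
2. **LSTM stage.** Two stacked LSTM layers (hidden width equal to d = 16)
   model the temporal dynamics of S. Gates use the standard equations
   i_t = σ(W_xi x_t + W_hi h_{t−1} + b_i) (likewise f_t, o_t), with the
   candidate cell c̃_t = tanh(W_xc x_t + W_hc h_{t−1} + b_c),
   c_t = f_t⊙c_{t−1} + i_t⊙c̃_t, h_t = o_t⊙tanh(c_t). The full output
   sequence is kept (length preserved) and passed through dropout (0.5).
3. **Transformer encoder.** h parallel scaled-dot-product attention heads of
   width d_k (Q_i = S W_i^Q etc., attention = softmax(Q_i K_iᵀ/√d_k)V_i),
   concatenated and projected by W^O ∈ R^{h·d_k×d}; residual + layer norm;
   then a position-wise feed-forward block (linear d→ffn_hidden, exact GELU
   x·Φ(x) via the error function, dropout, linear back to d); residual +
   layer norm. No positional encoding is used — the block is
   permutation-equivariant over sequence positions (verified by test).

The classifier flattens the encoder output, by default concatenated with the
flattened LSTM output sequence ("concat" fusion; "encoder_only" is a config
switch), applies dropout 0.5 and a linear map to N logits; training minimizes
mean softmax cross-entropy.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| F1, D, F2 | 8, 2, 16 | F2 = F1·D is the feature width d; the feature width d = 16 together with D = 2 forces F1 = 8 |
| KC1, KC2 | 16, 16 | temporal kernel lengths (samples); KC1 = fs/16 at 250 Hz keeps sensitivity above ~4 Hz; configurable (a 64-sample variant is sometimes used) |
| pool1, P2 | 8, 8 | pooling widths; P2 = 8 is the only value giving TC = 15 at T = 1000 |
| dropout (CNN/LSTM/FFN/classifier) | 0.3 / 0.5 / 0.3 / 0.5 | the FFN value is aligned with the CNN value; cross-subject runs lower the CNN value to 0.25 |
| encoder_layers, h, d_k, ffn_hidden | 1, 2, 16, 32 | one encoder block; two heads of width 16 (the best-performing sweep point); FFN width 2·d |
| lr, batch, val split | 1e−3, 72, 30% | Adam with defaults β = (0.9, 0.999), ε = 1e−8, no decay/schedule; LOSO uses lr 1e−3, batch 512 (clamped to the fold when larger), 600 epochs |

Model selection returns the weights of the epoch with the best validation
accuracy (no early stopping); with no validation split the epoch with the
lowest training loss is kept.

## Numerical backend

The network, backpropagation and Adam are implemented on a small
reverse-mode automatic-differentiation engine over NumPy float64 arrays
(`cltnet.autodiff`). Convolutions are expressed as sums of shifted
slice-products; softmax and the cross-entropy head use max-shifted
log-sum-exp; GELU uses the exact normal CDF, not the tanh approximation.
Every nonstandard computation is checked against an independent oracle in
the test suite: a straight-loop LSTM, brute-force per-pair attention,
finite-difference gradients, and scipy/scikit-learn for the metrics.
Determinism is promised per device: a fixed training seed drives four
separate RNG streams (split, augmentation donors, weight init, batch
order + dropout) and reproduces histories bit-exactly on one machine.

## Preprocessing conventions

Milliseconds map to 0-based samples by t ↦ ⌊t·fs/1000⌋; an inclusive window
[start, end] ms extracts ⌊(end−start+1)·fs/1000⌋ samples. The canonical
4-class motor-imagery crop is the 2–6 s post-onset segment
(`BCI_IV_2A_WINDOW_MS` = (2001, 6000)), which at 250 Hz is the half-open
sample range [500, 1500) — 1-based samples 501–1500 — and gives the
standard (288, 22, 1000) session shape. Z-scoring is per trial, per
channel, over time, with the population standard deviation; a constant
series becomes zeros (mean removed, scaling skipped) with a logged warning.

## S&R augmentation

Each trial is cut into K contiguous segments (first T mod K segments get one
extra sample when K∤T); an artificial trial of class y takes segment j from
a donor drawn uniformly with replacement among class-y training trials,
independently per segment, keeping the original temporal order and label.
Defaults: K = 8 and one artificial trial per original (doubling the training
set) — both deliberate package choices, since only the mechanism, not the
multiplicity, is standard. Augmentation is applied inside `fit` strictly
after the train/validation split and never touches validation or test
partitions (audited by trial fingerprints). Donor provenance can be
recorded and replayed bit-exactly.

## Synthetic data: what it does and does not show

The generator emulates the spectral statistics that make MI decodable:
1/f^α colored background noise (FFT-shaped, α = 1 by default) plus a
band-limited rhythm (band-pass-filtered white noise, 8–12 Hz), both unit
RMS, with the rhythm scaled by snr·(1 − erd[y, c]) so class y attenuates its
assigned channels. Subjects differ by additive jitter on the ERD map and
log-normal jitter on snr (scale `subject_shift`). Defaults: snr 0.5, ERD
depth 0.5, a contiguous-block class topography.

Pinned fixtures: `tiny-2class` (40 trials, 3 ch, 500 samples) for structural
tests; `default-4class-22ch` matching the 4-class session geometry
(22 ch, 1000 samples, 250 Hz); `strong-erd-2class` (200 trials/class, 3 ch,
500 samples, depth 0.8, snr 1.0) — the strongly separable condition used
for learning-sanity checks. The 3-channel/500-sample geometry keeps
full-length (100-epoch) CPU training of the learning checks fast while
preserving the full architecture; the 22-channel geometry is exercised by
the shape contracts.

What passing these tests shows: the architecture is wired as specified, the
optimizer learns a genuinely present band-power contrast well above chance,
and a label-shuffled control stays at chance (no leakage). What it does not
show: performance on real EEG — the generator has no volume conduction,
artifacts, non-stationarity or inter-session drift, so real-data accuracy
claims require the real benchmark recordings.

## Degenerate inputs and tie-breaks

Constant channels z-score to zeros; zero true-class probabilities in the
cross-entropy metric are clamped at 1e−12 (logged); argmax prediction ties
break toward the lowest class index; a kappa denominator of zero (single
occupied confusion cell) returns 1 for perfect agreement else 0; a class
absent from the truth is excluded from per-class/macro ROC with a warning;
Wilcoxon with all-zero differences returns p = 1. The Wilcoxon test drops
zero differences, uses midranks, enumerates the exact null for n ≤ 12 and
otherwise uses a tie-corrected normal approximation without continuity
correction.

## Reproduction script sizes

`scripts/acceptance.py` recomputes everything at sizes chosen for a single
CPU core: the shape contracts use the full 22-channel, 1000-sample
geometry; the learning-sanity runs train the default model for 100 epochs
on the 400-trial strongly separable task (plus the label-shuffled control);
the leave-one-subject-out run uses three jittered synthetic subjects
(60 trials each, 3 channels, 256 samples) with a reduced model and a
40-epoch schedule, which the separability pilots show is past convergence
for this task.

## Known limitations

* No GPU path; the NumPy backend is practical at the desk scales used here
  (hundreds of trials, ≤ a few hundred epochs), not at multi-session scale.
* GDF ingestion is a thin optional import (via mne) with the documented cue
  event codes; it is not exercised against real session files in the suite.
* Batch-norm statistics make training-mode forwards batch-dependent;
  evaluation mode uses running statistics and is deterministic.
* The macro-ROC FPR grid (101 points) and the fusion rule ("concat") are
  package choices where the design space was genuinely open; both are
  configurable or documented constants.
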