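# Methods

`fatiguecg` implements an end-to-end pipeline for classifying mental fatigue
from single-lead chest-strap ECG sampled at 130 Hz: signal conditioning,
time–frequency featurization, and a multimodal deep classifier, together
with classical/recurrent comparison models, an ablation harness, and a
synthetic ECG generator that stands in for human data.  This note records
the models, the defaults and why they were chosen, and what the synthetic
benchmark does and does not demonstrate.

## The classification problem

A recording session yields a stream of ECG samples plus a visual-analogue
fatigue score (VAS, 0–100 %).  Sessions with VAS strictly above 80 % are
labeled fatigued (F), all others non-fatigued (N).  The unit of
classification is a 10 s window: ten consecutive 1 s segments of 130
samples each.  Cardiac rhythm reflects autonomic state, so the
discriminative information is carried by beat timing and its variability
(heart-rate variability, HRV) as well as by waveform morphology.

## Synthetic data generator

The study-scale datasets this package is evaluated on are synthetic,
produced by `fatiguecg.synthetic`:

* **Beat morphology** — each beat is the sum of five Gaussian bumps
  (P, Q, R, S, T) with textbook-like offsets/amplitudes/widths (R amplitude
  1.0 arbitrary units, QRS width ~30 ms FWHM).  This is visually ECG-like
  and cheap; it is *not* a biophysical model.
* **Rhythm** — RR intervals are i.i.d. Gaussian (optionally AR(1)),
  truncated at 0.3 s.  Class-conditional defaults: N — mean RR 0.80 s,
  SDNN 0.06 s; F — mean RR 0.90 s, SDNN 0.02 s (slower, less variable
  rhythm under fatigue).  These are *fixture parameters* chosen to create a
  learnable, physiologically plausible contrast; no claim of fidelity to
  any real cohort is made, and they are fully configurable.
* **Noise** — additive white Gaussian noise (σ = 0.05 of the R amplitude),
  sinusoidal baseline wander (amplitude 0.1 at 0.3 Hz) and powerline
  interference (amplitude 0.02 at 50 Hz, plausible for a chest strap whose
  analog front end already suppresses mains pickup).  The three components
  exercise the three denoising regimes (broadband, low-frequency,
  narrowband).
* **Metadata** — ages uniform on [18, 27], genders drawn 2:1 male:female
  (a young athletic cohort); a monotone VAS trajectory ends above 80 % for
  F subjects and below for N subjects.
* **Cohort sizing** — the default benchmark uses 20 subjects × 120 s, i.e.
  240 ten-second examples, and a 12-subject cohort for the ablation grid;
  these sizes keep a full CPU run of every model in minutes while leaving
  ~24 held-out examples for the headline accuracy.

Everything is a pure function of its seed: cohorts, training runs and
evaluations are bit-reproducible.

Because class separation is injected through mean RR, a model can succeed
here by learning beat rate alone.  Passing the synthetic benchmark
therefore shows that the pipeline is *correctly wired and trainable*, not
that it detects human mental fatigue; morphological fatigue signatures,
non-stationarity, electrode artifacts and inter-subject baseline shifts
are all absent from the generator.

## Preprocessing

1. **Wavelet denoising** — 9-level Daubechies-5 decomposition (symmetric
   boundary extension) into cA9 and cD9…cD1; detail bands are thresholded
   and the signal reconstructed.  With a zero threshold the transform
   round-trips to ~1e-15 relative error.  At 130 Hz, nine levels put the
   cA9 band below ~0.13 Hz, so baseline drift is reachable by detail-band
   thresholding while the DC trend passes through (and is removed later).
2. **DC removal** — subtract the record mean.
3. **Standardization** — per-record z-scoring with the population standard
   deviation, applied before segmentation so all segments of a record share
   one scale.

**Threshold selection.**  The noise level σ̂ is estimated as
MAD(cD1)/0.6745.  The default rule is the *SureShrink hybrid*: per detail
band, a soft threshold minimizing Stein's unbiased risk estimate, falling
back to the universal threshold σ̂√(2 ln L) when the band's standardized
excess energy is below the Donoho–Johnstone sparsity cut.  The classical
single universal threshold (VisuShrink) is also available (soft or hard),
but it is a poor default for ECG at these noise levels: the QRS complex
spreads over many mid-size coefficients in cD2–cD5, and shrinking all of
them by σ̂√(2 ln L) ≈ 0.21 costs more signal than the removed noise — on
the synthetic records it *increases* clean-signal RMSE (0.088 → 0.10 with
default noise).  The SURE rule adapts per band, leaving signal-dominated
bands nearly untouched while still zeroing the white-noise floor in
cD1/cD2 and the powerline component; it improves RMSE in every seeded
trial (typical margin ≈ 0.01 on a unit-amplitude signal).

## Features

* **Segmentation** — non-overlapping 130-sample windows; trailing
  remainders are discarded (`floor` arithmetic at both the segment and the
  10-segment group level).  Indexing is 0-based with half-open windows.
* **STFT** — per 1 s segment, magnitude spectrogram
  `S[n,k] = |Σ_m x_m g[m] e^{-j2πkm/N}|` with an N-sample analysis window g
  shifted by a fixed hop; windows are placed entirely inside the segment so
  spectrograms never mix adjacent segments.  Default: periodic Hann window,
  N = 32, hop = 4, log magnitude with floor 1e-8 — a 17 × 25 image
  (frequency × time) per segment, 10 images per example.  Dropping the
  absolute-sample phase factor changes only the phase, not the magnitude.
* **Labels** are inherited by every group of a record from that record's
  session VAS.

## Hybrid classifier

Three branches produce d-dimensional tokens (d = 128 by default):

* **T (time)** — the 1300-sample group through a 1D residual network
  (blocks of two convolutions with an identity/projection skip and ELU
  activations; channels 16→32→64→64, first kernel 7 then 3, stride-2
  downsampling to 82 steps), then a 2-layer bidirectional LSTM (hidden 64)
  whose concatenated final states are linearly projected to d.
* **S (spectrogram)** — each of the 10 images through a 2D residual stack
  (8→16→32 channels, 3×3 kernels, stride 2), global average pooling, then
  a BiLSTM over the length-10 image sequence, projected to d.
* **P (physiological)** — age as a 100-dimensional one-hot vector (index =
  years, hence ages must lie in [0, 99]) concatenated with a learned
  8-dimensional gender embedding, through 6 fully connected layers
  (108→128×5→d).  A learned embedding replaces a pretrained word-vector
  lookup: with a two-token vocabulary they are equivalent up to training.

Enabled tokens receive learned *branch-type embeddings* (standing in for
positional encodings over a 3-token sequence, where order carries no
meaning) and pass through a 2-layer pre-norm transformer encoder (4 heads,
feed-forward 256).  The encoder output is mean-pooled and linearly mapped
to two logits; softmax gives P(F), P(N).  Ablation flags construct only the
enabled branches, so a disabled modality provably cannot influence the
output.

**Loss** — mean cross-entropy `L = -(1/N) Σ_q Σ_r S_qr log P_qr`, with
probabilities clipped at 1e-12 where the log would be undefined; training
minimizes the numerically equivalent log-softmax form.

**Optimization** — Adam (lr 1e-3, batch 32), up to 50 epochs with early
stopping on the loss of a 15 % validation holdout (patience 10, at least
10 epochs); the best-validation weights are restored.  The holdout is only
~30 examples at benchmark scale, so the patience is deliberately generous
— aggressive stopping on so noisy an estimate selects poor epochs.

## The autodiff engine

No deep-learning framework is used: `fatiguecg.nn` is a small tape-based
reverse-mode autodiff engine over numpy arrays, providing exactly the
operations the models need (broadcast arithmetic, batched matmul, im2col
convolution via `unfold`, fused per-layer LSTM with hand-derived
backpropagation through time, layer norm, softmax, multi-head attention).
Every operation's gradient is verified against central finite differences
in the test suite.  The LSTM is fused at the layer level (one graph node
per layer-direction, gate layout i,f,o,g with the sigmoid block contiguous)
because per-timestep graph nodes dominated runtime.  All computation is
float64 on CPU and exactly reproducible.

## Baselines

All comparison models consume the same 9:1 split as the hybrid model
(shared split seed), so comparisons are paired:

| model | input | fixed hyperparameters |
|---|---|---|
| SVM | flattened 4×-decimated group series (325 dims) | C = 0.1, γ = 10, sigmoid kernel |
| Random forest | same | 100 trees, seed 40, max depth 100 |
| CNN | 10 spectrogram images stacked as channels | 18 weighted layers (17 conv 3×3 + linear), stride-2 convs in place of pooling |
| LSTM / BiLSTM | decimated series as a length-325 sequence | depth 6, input/hidden dim 64 |

The neural baselines train with the same Adam loop (up to 30 epochs, early
exit when the epoch loss falls below 5e-3).

A caution on the SVM: with γ = 10 the sigmoid kernel saturates to a ±1
sign kernel on any reasonably scaled high-dimensional input, and with
C = 0.1 the margin is heavily regularized; on the synthetic benchmark this
configuration performs at chance level (≈54–63 % across seeds).  This is
not an implementation artifact — the same configuration is reported at
≈55 % accuracy in the comparison literature the defaults are drawn from —
and no feature-scaling variant we measured repairs it while keeping those
hyperparameters.  The SVM is retained as specified for faithful
comparison.

## Evaluation and ablation

Accuracy (percent) and F1 with F as the positive class are computed from
confusion counts (`accuracy = (TP+TN)/total·100`, `F1 = 2TP/(2TP+FP+FN)`);
macro-F1 is also logged.  The default split is example-random at 9:1; a
subject-grouped mode is provided as the leakage-safe alternative (an
example-random split lets windows from one subject appear on both sides,
which inflates absolute numbers — the default mirrors the common, more
optimistic protocol and the two modes are one flag apart).  The ablation
harness trains the six branch combinations S, S+P, T, T+S, T+P, T+S+P on
one shared split and emits a CSV table.

## Numerical and degenerate-input choices

* Standardizing a constant (zero-variance) signal raises
  `DegenerateInputError`; denoising requires ≥ 512 samples (9 levels).
* Segmentation of a signal shorter than one window returns zero segments
  rather than raising.
* Softmax and the training loss are computed with max-shift /
  log-sum-exp stabilization; the evaluation-form cross-entropy clips
  probabilities at 1e-12.
* RR intervals are clipped at 0.3 s so zero/negative intervals cannot
  occur at any SDNN.
* Ties in SURE risk minimization resolve to the smallest candidate
  threshold (`argmin` on a sorted array).

## Known limitations

* The generator's class contrast is rate-based; models that ignore
  morphology entirely can pass the benchmark.
* The transformer fuses at most three tokens; with a single enabled branch
  it degenerates to a per-token MLP with attention weight 1.
* The engine is CPU/float64 only and sized for desk-scale experiments
  (~10³ examples, ~10⁶ parameters); it is not a general training
  framework.
* Dropout is available in the configuration but defaults to 0 — at
  benchmark scale early stopping alone governs overfitting, and a nonzero
  rate would make run-to-run comparisons depend on one more seed stream.
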