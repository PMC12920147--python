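# Methods

## Overview

`somno` implements a channel-agnostic multimodal encoder for overnight
polysomnography (PSG) together with the training objectives and evaluation
machinery needed to use it for clinical prediction: leave-one-out
contrastive pretraining across the four PSG modalities (BAS = EEG/EOG,
ECG, EMG, respiratory), Cox proportional-hazards fine-tuning for
time-to-event disease prediction over phecode-derived labels, sleep-stage
and apnea-severity classification heads, and rank-based evaluation with
patient-level bootstrap uncertainty. A synthetic-cohort generator with
fully known ground truth makes every stage testable at desk scale with no
data download.

## Preprocessing

Each channel is resampled to a common 128 Hz grid. Downsampling applies a
fourth-order low-pass Butterworth filter in a zero-phase (forward-backward)
setting before interpolation; the cutoff is 0.9 x the target Nyquist
(57.6 Hz), a standard guard band — the filter order and zero-phase
application are fixed design constraints, the cutoff is our choice.
Upsampling uses plain linear interpolation with no filter. Signals are then
z-scored *per channel over the whole recording* (channels carry
incommensurate units, so per-channel scope is the only defensible reading),
grouped into modalities with per-modality channel caps (BAS 10, ECG 2,
EMG 4, respiratory 7; a deterministic canonical channel order decides
truncation), and segmented into non-overlapping 5-s tokens of 640 samples.
Trailing partial tokens are dropped during pretraining; zero-padding is
reserved for the 9-h context standardization (6,480 tokens; long recordings
keep their initial segment, short ones are padded with masked zero tokens).
The pipeline order — resample, standardize, group, segment — is contractual
and tested: z-scoring per token instead of per recording would erase
cross-token amplitude structure.

EDF I/O: EDF stores per-channel sampling rates, but general-purpose
uniform-rate readers resample low-rate channels up to the fastest channel on
load, which would silently bypass our resampling path. The package therefore
carries a minimal EDF reader/writer pair; the reader is cross-checked
against `mne.io.read_raw_edf` on uniform-rate files, where the two agree to
16-bit quantization. Round-trips through EDF reproduce in-memory token
arrays to ~1e-3 (the 16-bit amplitude resolution), which is the tolerance
used in tests.

## Encoder

Per modality stream: a six-block 1-D conv tokenizer (feature maps
1-4-8-16-32-64-128; each block Conv -> BatchNorm -> ELU -> LayerNorm),
adaptive average pooling over the remaining temporal axis and a linear map
to the fixed 128-d token embedding; a channel-pooling stage (one
transformer-encoder layer attending across the channel axis per 5-s
segment, then a masked mean over channels) that makes the model agnostic to
channel count and order; a temporal transformer (sinusoidal positions,
three encoder layers, eight heads) over at most one 5-min context window
(60 tokens); and learned-query attention pooling over valid tokens giving
one 128-d embedding per modality. Full-night inference processes
consecutive non-overlapping 5-min windows with no cross-window attention,
matching the pretraining context.

Choices the architecture description leaves open, and how we fixed them:

* **Conv kernel/stride.** Kernel 3 with stride 3 and same-padding
  (640 -> 214 -> 72 -> 24 -> 8 -> 3 -> 1), so the temporal resolution falls
  monotonically to the adaptive-pool stage. Stride was chosen jointly for
  this property and single-CPU training throughput; the parameter count is
  kernel-dependent but stride-independent.
* **Feed-forward width 2048 and per-modality streams.** With a 2048-wide
  transformer feed-forward (the PyTorch `TransformerEncoderLayer` default)
  and per-modality tokenizer + channel-pool streams over a shared temporal
  transformer, the default model has 4.37M learnable parameters and the
  fine-tuning head 0.93M — both within 2% of the intended ~4.44M/~0.91M
  scale, which narrower widths miss by 3x. Narrow shared-stream variants
  remain available (`desk_config()`, feed-forward 512) and are what the
  desk-scale training studies use.
* **Block normalization order.** Conv -> BatchNorm -> ELU -> LayerNorm
  (over feature maps); the three components are fixed, their order is ours.
* **Temporal depth 3.** Where descriptions disagree (two vs three encoder
  layers), three is used; the count is config-selectable.
* **Token-level embeddings for downstream heads** are taken *after* the
  temporal transformer (contextualized), not before.

## Pretraining (LOO-CL)

For batch sample k and modality i, the target is the mean of the other
present modalities' pooled embeddings, x̄_k^{-i}. The loss term is the
InfoNCE-style ratio

    L_{i,k} = -log [ exp(sim(x_k^i, x̄_k^{-i}) / τ)
                   / Σ_{m=1..N} exp(sim(x_k^i, x̄_m^{-i}) / τ) ],

with sim = cosine on L2-normalized vectors (similarity family is free;
cosine chosen), τ fixed at 0.1 by default (not learned; the value is
unspecified upstream and exposed as a flag). The reported loss is the mean
over all contributing (i, k); under uniform similarities it is exactly
ln N, which the tests pin for N ∈ {2, 4, 8, 32}. Only the
modality-as-query direction is computed — exactly the printed definition —
and a sample missing modality i is excluded both as query and from other
modalities' leave-one-out means. The denominator runs over all batch
samples including m = k, as written. Optimization: Adam, batch 32 windows,
learning rate 1e-3, per-epoch reshuffling under the run seed, gradient-norm
clipping at 1.0 (ours, for stability on small corpora). A loop-based scalar
implementation of the same definition ships alongside and the vectorized
loss must match it to 1e-6; analytic gradients must match central finite
differences to 1e-4.

## Fine-tuning

Embeddings come from the frozen encoder (a checksum test guarantees
fine-tuning never mutates it). The per-patient input is the (4 x S x 128)
modality/token matrix with masks, plus z-scored age (training-split
statistics) and sex in {0, 1}. The full head is: attention fusion across
modalities per token (transformer layer with four heads + masked mean) ->
two-layer bidirectional LSTM (hidden 64, i.e. 128 per token) -> masked
temporal mean over valid tokens -> concatenation with age/sex -> linear
output layer. Because context padding is always a suffix, the recurrence
runs over the valid prefix only, which makes mask-insensitivity exact. A
linear probe variant (fusion + masked mean + linear, or a linear layer on
concatenated pooled modality embeddings) is provided for cheap evaluation,
and a demographics-only MLP (4 -> 128 -> out) serves as the floor baseline.

### Survival objective

The per-condition loss is the negative log Cox partial likelihood

    L = -(1/N_e) Σ_i δ_i ( h_i - log Σ_{j: t_j ≥ t_i} exp(h_j) ),

computed by sorting descending in time and accumulating a cumulative
log-sum-exp; the inclusive risk set (t_j ≥ t_i) is exactly the Breslow tie
convention, so Breslow is the implemented convention (Efron is not). The
multilabel extension computes the loss independently per condition —
patients excluded for a condition (prevalent disease) drop out of that
condition's terms; conditions with no in-batch events contribute zero
without gradient — and sums over conditions. At cohort scale the loss is
evaluated on minibatches of 32 patients whose risk sets are restricted to
the batch; patients are sorted by event time in descending order *within
each batch* for the cumulative computation. (Reading that sort as a global
sort chunked into batches fills each batch with near-tied times and
empirically collapses the ranking signal — coefficients shrink several-fold
and no longer match a reference Cox fit; the within-batch reading recovers
them.) The exact full-cohort loss is available for diagnostics
(`batch_size=None`) and equals the batched loss when one batch covers the
cohort.

### Classification heads

Sleep staging is a per-token linear layer over the five AASM stages
(30-s annotations are expanded to six 5-s tokens each; R&K stages 3/4 merge
into N3 before expansion). Apnea severity (4 classes), sex (1 logit) and
age (absolute-error regression) use linear layers on the pooled state.

## Labels

ICD events map to phecodes through a caller-supplied mapping table (the
official phecode map is external reference data and is not redistributed; a
toy mapping is generated in tests). A phecode's timestamp is the earliest
mapped ICD date per patient. Incident cases require the first instance
strictly more than 7 days after the sleep study (t = event - PSG days);
patients with an instance at or before day 7 — including pre-study — are
excluded for that condition by default (prevalent disease; treating them as
censored is available via a flag), everyone else is censored at last
contact, which the caller supplies. Conditions below 1.5% prevalence
(computed on the training split only) are dropped, and the retained list is
persisted for evaluation. Every generated label set asserts the no-leakage
invariant (all event times > 7 days). AHI severity bins are half-open
exactly as defined: none < 5 ≤ mild < 15 ≤ moderate < 30 ≤ severe, with
"presence" = moderate-or-severe.

## Evaluation

* **Harrell's C-index**: comparable pairs are (i, j) with t_i < t_j and
  δ_i = 1; score ties earn 0.5; undefined (reported as NaN with a warning)
  when no pair is comparable. Verified exactly against an O(n²)
  pair-enumeration oracle on 1,000 random small instances.
* **Horizon AUROC** (default 6 years, horizons 1-6 supported): positives
  are events within the horizon, negatives are patients followed beyond it,
  and patients censored before the horizon are excluded (an
  inverse-censoring-weighted estimator is out of scope). Computed by the
  midrank Mann-Whitney statistic; also oracle-verified.
* **Bootstrap**: 1,000 patient-level resamples, 95% percentile interval;
  degenerate resamples are skipped and counted, and more than 50% aborts.
  p-values against a null value (0.5 for rank metrics) use a two-sided
  normal approximation on the bootstrap standard error — the upstream
  p-value construction is unspecified, so this choice is ours and is
  flagged as such.
* **Bonferroni**: flag_i = p_i < α/m at α = 0.01.
* **Classification**: row-normalized percentage confusion matrices and
  macro F1 (classes absent from the truth are excluded from the macro mean
  with a warning); age reports MAE in years plus Pearson correlation.

## Synthetic cohorts

A hidden five-state Markov chain at 30-s resolution (states mapped 1:1 to
Wake/N1/N2/N3/REM; rows of the default transition matrix encode realistic
stage persistence) drives all modalities simultaneously:

* **BAS**: band-limited oscillations whose per-band amplitudes are
  stage-conditional, with a distinct dominant band per stage (Wake-beta,
  N1-theta, N2-sigma, N3-delta, REM-alpha). REM's alpha dominance is a
  synthetic identifiability cue, not sleep physiology; it makes the
  stage-decoding contract testable by periodogram.
* **ECG**: Gaussian-bump pulse train with stage-dependent heart rate
  (55-76 bpm) and 4% beat-interval jitter.
* **EMG**: white noise with stage-dependent level, highest in Wake and
  collapsing in REM (atonia).
* **RESP**: a 0.25-Hz breathing oscillation whose envelope (i) drops to
  10% during injected apnea events — exactly round(AHI x hours) events per
  recording, 10-20 s each, so the injected count reproduces the drawn AHI —
  and (ii) carries a continuous slow irregularity proportional to AHI/30,
  so severity remains visible in windows too short to contain many discrete
  events. AHI is drawn lognormal(log 10, 0.8): clinic-like median 10/h with
  a heavy tail.

Channels within a modality are noisy copies of the modality source
(`noise_sd`, default 0.3); native rates are heterogeneous (BAS/EMG 256 Hz,
ECG 200 Hz, RESP 64 Hz) so both resampling paths are exercised. Survival
outcomes are exponential proportional hazards λ0·exp(β'z) with
λ0 = 5e-4/day; z's first component is the standardized log-AHI and the rest
are independent normals; default conditions are "coupled" (β = (1.0, 0.5))
and "unrelated" (β = 0). Censoring: a `censor_rate` fraction of patients
(default 0.3) receives an independent uniform censoring time on [0, 10
years]; `censor_rate=0` therefore yields all-events cohorts exactly. Age
and sex are drawn independently of z by default; `demo_coupling` correlates
age with latent risk for confounding experiments. Everything is
deterministic given (seed, patient_seed), and large cohorts can be
simulated with `keep_signals=False`, which releases raw signals after each
patient and regenerates any recording bit-identically on demand.

What the generator deliberately does **not** emulate: real PSG waveform
morphology (spindle/K-complex shapes, EOG deflections, ECG morphology),
inter-night variability, artifacts, or ICD coding noise. Passing tests
therefore demonstrate that the machinery — preprocessing, architecture,
objectives, metrics — is correct and learnable on data with the assumed
statistical structure, not that the model attains any particular clinical
performance on real recordings.

## Desk-scale reference studies

Real-scale pretraining (hundreds of thousands of hours on GPUs) is out of
scope; two fixed studies exercise the full pipeline on one CPU:

* **Pretraining study**: 16 patients x 1 h, one channel per modality,
  desk encoder configuration, 200 steps at batch 32. Checks: initial loss
  ≈ ln 32, final loss below initial, batch-32 cross-modal top-1 retrieval
  above 3x chance. (Observed in development: loss ~3.5 -> ~0.4 and
  retrieval ~0.4-0.6 against chance 0.031.)
* **Survival study**: 1,500 patients x 5 min (exactly one context window)
  at the generator's default channel counts, embedded by the frozen
  pretrained encoder; a linear Cox head on concatenated per-modality pooled
  embeddings plus age/sex (the linear-probe configuration) is trained on a
  random half and evaluated on the other half with 1,000-resample bootstrap
  C-index intervals. The AHI-coupled condition's interval must exclude 0.5;
  the zero-coefficient condition's must not. Short recordings are the
  study's problem-size choice; the generator's continuous severity cue is
  what keeps apnea burden identifiable in a single window.

## Numerical infrastructure

No deep-learning framework is part of the dependency set; the networks run
on a compact reverse-mode autodiff engine over numpy arrays written for
this package (`somno._autograd`, `somno._nn`), with float32 working
precision by default and a float64 mode used by the finite-difference
gradient checks. The conv tokenizer uses channels-last gemm-based
convolutions and fused compiled kernels (numba) for the
BatchNorm/ELU/LayerNorm chain, validated in float64 against the composed
reference ops and against finite differences. Every layer family
(linear, conv, both norms, attention, LSTM, pooling) is gradient-checked;
Adam and gradient clipping follow the standard formulations. Degenerate
inputs are contracts, not accidents: constant signals standardize to zeros
under an ε-guard, batches without events return a gradient-free zero Cox
loss, metrics with empty comparison sets report NaN with a warning rather
than a number.

## Known limitations

* Breslow ties only; Efron is not implemented (reference fitters that
  default to Efron are used only on tie-free cases, scikit-survival's
  Breslow mode otherwise).
* The horizon AUROC discards early-censored patients rather than weighting
  them; with heavy early censoring it is biased relative to IPCW
  estimators.
* Batch-restricted risk sets are an approximation to the full partial
  likelihood; the exact loss is available but quadratic-cost at scale.
* The synthetic generator's stage signatures are deliberately separable;
  real staging is far harder, and macro-F1 numbers on synthetic cohorts do
  not transfer.
* Desk-scale pretraining (200 steps, 16 patients) demonstrates learnability
  of the objective, not representation quality at corpus scale.
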