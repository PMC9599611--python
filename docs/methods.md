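# Methods

## Problem and pipeline

The package classifies resting-state fMRI scans into disease stages from the
*dynamics* of functional connectivity (FC). Input is one matrix per scan of
BOLD amplitudes, N regions of interest (ROIs) × T timepoints, plus a cohort
manifest mapping scans to subjects and diagnostic labels. The pipeline has
two trained stages wrapped in a Model/Results interface
(`LSRNet(manifest, recordings, config).fit() -> LSRNetResult`):

1. **dFC construction + latent compression.** Each ROI series is z-scored,
   `f(t) = (t − μ)/σ`, and cut into M overlapping windows of
   `window_length` timepoints advancing by `step`. Each window yields a
   Pearson correlation matrix; its strict upper triangle (D = N(N−1)/2
   values in [−1, 1]) is the window's feature vector. A fully connected
   autoencoder — each hidden affine map followed by a normalisation layer
   and tanh — compresses each D-vector to an H-dimensional latent code and
   is trained with mean squared reconstruction error on the pooled,
   shuffled windows of all training scans.
2. **Multi-perspective classification.** The scan's M × H latent matrix is
   read two ways: K *global features* from a convolution whose kernel spans
   the full M × H matrix (each kernel reduces the scan to one scalar), and
   *dynamic features* from a bidirectional LSTM over the M latent rows
   (concatenated final hidden states, 2 × hidden values). A fusion network
   concatenates both, compresses through one hidden tanh layer and
   classifies with softmax; it is trained end-to-end with cross-entropy
   while the stage-1 encoder stays frozen.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_length` | 30 timepoints | sliding-window width |
| `step` | 2 timepoints | window stride; with T=137 gives M=54 |
| `encoder_dims` | (2048, 1024, 512) | encoder widths; latent H is the last |
| `normalization` | batch | per-layer normalisation (running stats at inference); `layer` selectable |
| `n_kernels` (K) | 64 | number of full-size global kernels |
| `lstm_hidden` | 32 | BiLSTM hidden size per direction (DF dim 64) |
| `fusion_hidden` | 32 | width of the fusion compression layer |
| `ae_/stage2_epochs` | 100 | training epochs (early stopping, patience 10) |
| learning rate | 1e-3 | Adam, both stages |
| `val_fraction` | 0.15 | training subjects moved to validation |

At the published operating point N=116 ROIs and T=137 retained timepoints,
so D=6670 and M=54. `small_cohort_config()` is the same pipeline at widths
(64, 32, 16), K=16, hidden 16 — appropriate for cohorts of tens of subjects
with ~20 ROIs, and the scale used throughout the tests and the acceptance
script so a full 5-fold run finishes in about a minute on one CPU.

Unstated details were fixed as package design choices: "normalisation"
after each fully connected layer is batch-style with running inference
statistics (layer-wise selectable by config); the output layer carries only
tanh, keeping reconstructions in the Pearson range; the optimiser is Adam;
the global convolution's activation is tanh for consistency with the latent
range; the fusion head is one hidden tanh layer before softmax; dynamic
features use the final hidden states (all-step stacking is available via
`df_mode="all_steps"`); the stage-1 model is retrained inside every fold so
no test subject ever influences the encoder; argmax ties break to the lower
class id.

## Normalisation conventions

z-scoring and Pearson correlation use the population (1/W) convention;
correlation is invariant to the choice. A constant ROI within a window has
no defined correlation; it is set to 0 against all other ROIs (1 with
itself) with a warning so downstream tensors stay finite. Correlation
matrices are clipped to [−1, 1], symmetrised and given an exactly unit
diagonal before vectorisation. Window indexing is 0-based and half-open:
window k covers columns [k·step, k·step + window_length), and
M = ⌊(T − w)/s⌋ + 1 generalises the published count to arbitrary T.

## Evaluation protocol

Cross-validation is strictly subject-independent: subjects possessing a
baseline scan are shuffled and split into k near-equal parts (remainder
spread one per fold); fold f tests on part f and trains on the rest plus
every subject without a baseline scan; 15% of the training subjects (at
least one) are moved to a validation set used only for early stopping.
Accuracies are computed at scan level — overall, per class, per fold, both
pooled over folds and as the mean of fold accuracies — with an optional
subject-level majority-vote metric. Binary tasks subset the manifest to the
two named classes before splitting.

Seven pipelines run under identical folds: `ROIs+SVM` (flattened z-scored
BOLD → linear SVM, C=1, features standardised on the training fold only),
`sFC+SVM` (full-length correlation upper triangle → linear SVM),
`dFC+BiLSTM` and `dFC+GCNN` (windowed vectors fed directly to one
perspective, no autoencoder), `LSRNet-G` and `LSRNet-B` (latent codes, one
perspective), and full `LSRNet`. Because training is deterministic given
the seed, the single-perspective latent variants provably share an
identical stage-1 checkpoint per fold (verified by parameter checksums).

## Synthetic cohorts

Real multi-site rs-fMRI cohorts of this kind are access-restricted, so the
generator reproduces only the statistical features the method depends on:

* a shared AR(1)-Toeplitz correlation backbone (ρ = 0.45) across classes;
* class-specific offsets on a fixed set of off-band edges whose magnitude
  grows with class index (emulating progressive connectivity loss across
  disease stages), repaired to the nearest valid correlation matrix
  (Higham-style projection via statsmodels) whenever an offset breaks
  positive definiteness;
* within-scan temporal state switching with geometric (memoryless) dwell
  times — each state perturbs a random quarter of the edges — so windowed
  correlations genuinely vary over time;
* per-subject random offsets on the perturbed edges shared by all of a
  subject's scans, making scans of one subject more alike than scans of
  different subjects; this is what makes subject-independent splitting
  genuinely harder than scan-level splitting, and what the label-permuted
  control relies on;
* timepoints drawn i.i.d. from a zero-mean multivariate normal with the
  state's correlation matrix plus independent observation noise
  (`noise_sd` 0.2).

Defaults: 2 temporal states, mean dwell 20 timepoints, subject effect
scale 0.05. The reference test condition is a 2-class cohort with a 0.6
correlation shift on 10 edges, 20 subjects per class, 2 scans each, N=20,
T=137 (window 30 / step 2, preserving M=54).

The generator does **not** model hemodynamic response, autocorrelated
noise, physiological artefacts, site effects or class imbalance. Passing
tests therefore show that the pipeline recovers class-specific, time-varying
correlation structure under the stated protocol — not that it attains any
particular accuracy on clinical data.

## Numerical implementation

All networks are implemented in NumPy with hand-written backward passes
(dense, batch/layer normalisation, tanh, LSTM with full backpropagation
through time) and an Adam optimiser; every backward pass is verified in the
test suite against central finite differences, and the LSTM against a
scalar step-by-step reference of the recurrences. The full-size-kernel
convolution is stored as a dense map over the flattened latent matrix,
which is the identical linear operation. All randomness flows from explicit
`numpy.random.Generator` objects, so training, splitting and generation are
bit-reproducible given a seed. Because stage 2 contains no batch-dependent
layers and stage-1 inference uses running statistics, predicting scans
singly equals predicting them batched.

## Known limitations

* Accuracies on real clinical cohorts cannot be reproduced here; the
  synthetic recovery condition is deliberately strongly separated.
* The mean-squared objective treats all connectivity edges equally; no
  edge sparsification or tapered windows are offered.
* Small cohorts with unstratified folds can produce single-class training
  sets, which are rejected with an error rather than silently handled.
* The SVM baselines use a linear kernel with C=1; no hyperparameter search
  is performed for any variant.
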