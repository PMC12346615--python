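# Methods

## Problem and data model

The package predicts a binary slide-level treatment outcome — pathologic
complete response (pCR) vs residual disease (non-pCR) after neoadjuvant
chemotherapy — from pre-treatment biopsy slides represented as *feature
bags*. A bag is the set of embeddings of all tissue patches of one slide
(`N x d` float32 matrix, typically `d = 1536` from a pathology foundation
model, with 0-based (row, col) patch-grid coordinates). Only the bag
carries a label; no patch is annotated. This is the standard
multiple-instance learning (MIL) setting of weakly supervised
computational pathology: the label-relevant signal is assumed to live in
an unknown subset of patches ("witnesses"), and the model must both
classify the bag and localize the signal.

Patch extraction and feature encoding are out of scope: bags enter
through a pluggable I/O boundary (one HDF5 file per slide, CSV manifest,
PNG mask grids), and the synthetic generator produces them directly.

## Model

Attention scoring, softmax normalization, attention-weighted pooling,
and a sigmoid head, exactly as stated in the README:

- `score_k = w^T tanh(V h_k)` with `V (L x d)`, `w (L,)`; softmax over
  the bag gives `alpha` (strictly positive, sums to 1).
- `z = sum_k alpha_k h_k`; `p = sigmoid(u^T z + b)`.

The attention is the plain (non-gated) tanh form; gated variants exist
in the MIL literature but are deliberately not used. The classifier head
is a single affine layer `d -> 1`; the pooled representation is already
a learned convex combination, and a deeper head adds capacity the small
cohorts this targets cannot support.

The attention hidden width `L` defaults to 256 for full-scale
(`d = 1536`) bags and is configurable; the bundled small-cohort studies
use `L = 64` against `d = 16` features.

## Loss and class weighting

Class-weighted binary cross-entropy with weights `w_c = N / (2 N_c)`
computed **from the training split only**. The weights satisfy
`w_pcr·N_pcr = w_nonpcr·N_nonpcr = N/2`; in floating point the identity
holds to a few ulps (e.g. `(174/162)·81 = 87 + 1.4e-14`), and tests
assert it at relative tolerance 1e-12. Probabilities are clipped to
`[1e-7, 1 - 1e-7]` before the logs; a cohort with an empty class is
rejected rather than given an infinite weight.

## Training protocol

Plain SGD (no momentum), batch size one bag, learning rate 1e-4, L2
weight decay 1e-3 applied to all parameters, up to 1024 epochs with
early stopping at patience 50 on the validation loss; the returned
parameters are the snapshot from the epoch with minimum validation loss.
A *strictly* lower validation loss resets patience; an equal loss does
not (so a frozen model stops after exactly `patience + 1` epochs).
Parameters initialize uniformly in `±1/sqrt(fan_in)` from the config
seed; bag order is reshuffled every epoch from the same generator, so a
run is bit-reproducible on one thread. Non-finite train or validation
loss aborts with the epoch index.

An optional feature-space jitter (additive Gaussian noise on the
embeddings, redrawn per bag per epoch) stands in for image-space
augmentation, which cannot be applied once patches are encoded; it is
off by default.

The exact objective SGD follows — mean weighted BCE plus
`(wd/2)·||theta||^2` — is exposed as `full_objective` /
`full_objective_grad`, and the analytic gradient (closed-form
backpropagation through softmax attention) is pinned to central finite
differences at relative error ≤ 1e-4 in the tests.

## Evaluation protocol

**Splits.** Stratified patient-level k-fold (default k=5): within each
class, patients are shuffled once from the seed and dealt round-robin
into k test folds, so per-fold class counts deviate from proportional by
at most one. Each fold's remaining patients are split train/validation
per class at `val_fraction` (default 0.1, minimum one validation patient
per class — small cohorts would otherwise get an empty validation set).
Train/val/test disjointness is asserted at run time (leakage guard).
Per-fold training seeds derive as `seed + fold_index`.

**Metrics.** Confusion counts at threshold 0.5 (predicted positive iff
score ≥ threshold; the threshold is a convention, ROC/AUC are
threshold-free). Accuracy, precision, recall/sensitivity, specificity
and F1 follow the textbook formulas; AUC is the Mann–Whitney rank
statistic with ties counted 1/2 (computed via scikit-learn, verified
against an all-pairs count in the tests). A zero-denominator metric is
reported as 0 and flagged `undefined` instead of raising, which keeps
fold aggregation total.

**Aggregation.** Mean and *sample* (n−1) standard deviation across
folds, with 2-decimal roundings exposed for table rendering; std is 0
for a single fold. Published fold tables in this area are not always
internally consistent (per-fold F1 vs its own precision/recall, ± values
that match neither sample nor population std), so the convention is
fixed here and only column means (plus the accuracy std) are treated as
reproducible anchors.

**External cohorts.** The k fold-models are evaluated as an ensemble of
independent runs on the full external cohort — per-model metrics plus
mean ± std across models — rather than retraining a single model on the
pooled data.

## Attention maps and biomarker overlap

Attention weights are spatialized on the patch grid, min-max scaled per
slide (`(alpha - min)/(max - min)`; a constant bag, including N=1, maps
to all 1). Binarization rules:

- **median**: cell on iff its patch weight ≥ the median over *patches*
  (so the mask always covers at least half the patches);
- **top-k%**: the `ceil(f·N)` highest-attention patches, ties at the
  cutoff broken toward the lower patch index.

The overlap statistic against a binary marker grid is the coverage
fraction `|marker ∧ attention| / |marker|` — implemented exactly in this
asymmetric form (marker area in the denominator) because that is the
statistic used in practice, despite frequently being labeled "IoU"; a
symmetric Jaccard index is provided as a clearly separate function.
Slides with an empty marker mask are excluded from per-marker means (the
statistic is undefined there, not zero). Median binarization is the
default for overlap reports; top-k masks serve hotspot reporting and can
be configured as the overlap mask instead. Pixel-resolution marker masks
are down-projected to the patch grid by any-positive pooling (a cell is
positive if any pixel in it is).

Because the median mask covers ≥ half the patches, a *random* attention
assignment already yields coverage ≈ 0.5; overlap values are therefore
always interpreted against the permuted-attention null the package
computes alongside (same mask rule, patch weights shuffled within the
slide).

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
matching the targeted clinical setting: 174 patients at prevalence
81/174, `d = 1536`, 50–2000 patches per bag (patch counts per biopsy
slide are not well documented; this range is a configuration default,
not a claim about any cohort).

- Exactly `round(n_patients · prevalence)` positive patients.
- Background patch features i.i.d. `Normal(0, noise_sd^2)` per dimension;
  positive bags contain `round(witness_rate · N)` witness patches whose
  first `min(signal_dims, d)` dimensions (default 32) are shifted by
  `signal_shift`. Isotropic Gaussian with a mean shift is the simplest
  model under which attention localization is testable.
- Patches occupy the first N grid cells in row-major order
  (deterministic coordinate bookkeeping); witness positions are drawn
  uniformly among patch indices.
- Each marker grid sets a witness cell positive with probability
  `mask_colocalization` (default 0.9) and a background cell with
  probability `background_positive_rate` (default 0.02, capped at 0.05).
- Every patient draws from an independent child of the seed
  (`SeedSequence.spawn`), so cohorts are reproducible and invariant to
  ordering; witness flags and masks are written to files separate from
  the bags so the classifier path cannot consume ground truth.

Two named study conditions are used throughout tests and the acceptance
script, sized for single-CPU runs:

- `demo_spec`: 60 patients, `d = 16`, bags of 50–100 patches, 30%
  witnesses shifted by 2 noise sd — a strong, separable signal for
  verifying the full protocol (CV there reaches AUC ≈ 1.0).
- `sparse_witness_spec`: same, but 5% witnesses shifted by 3 sd — a
  hotspot-like condition for localization checks. Enrichment of
  attention mass on witnesses is bounded above by `1/witness_rate`, so a
  ≥ 5× enrichment criterion is only meaningful when witnesses are rare;
  at a 30% witness rate the bound (3.3×) makes the criterion
  unattainable by construction, which is why localization is assessed on
  this sparse condition.

What the generator does **not** emulate: feature correlation structure
and batch effects of real encoders, heterogeneous witness phenotypes,
spatial clustering of tumor regions (witnesses are scattered, not
contiguous), staining variation, and label noise. Passing the synthetic
recovery tests shows the pipeline is correct and can localize a planted
signal; it says nothing about attainable performance on clinical
cohorts.

## Numerical choices

- Stable (max-subtracted) softmax everywhere; attention weights sum to 1
  within 1e-9.
- Loss clipping eps = 1e-7; float64 internally, bags stored as float32.
- Early-stopping ties: only strict improvement resets patience.
- Min-max scaling of a constant attention vector is defined as all 1.
- Top-k ties break deterministically by patch index (stable argsort).
- Sample (ddof=1) std for all fold/model aggregation.
- Checkpoints are zip archives of CSV arrays plus a JSON header — text
  only, diffable, no pickle.

## Limitations

- Single affine head and non-gated attention only; no multi-class
  outputs, no GPU path (deliberate: the reference sizes run in seconds
  on one CPU).
- The CLI runs one process; fold-level parallelism is not implemented
  (per-fold seeds are already independent, so it could be added without
  changing results).
- No confidence intervals or significance tests on metrics (means ± std
  only); no calibration analysis.
- Real-slide ingestion (WSI formats, tiling, stain normalization) is out
  of scope by design; bags must be produced upstream.
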