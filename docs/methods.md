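# Methods

## The model

`legnet` predicts a scalar behavioral score (a 0–100 language-ability quotient
in the motivating application) from two per-subject inputs defined on an
N-ROI brain parcellation:

- **X** (N × N): functional connectivity, the element-wise exponential of the
  Pearson correlation matrix of ROI mean time series, where each ROI mean is
  computed over the ROI's *non-lesioned* gray-matter voxels.  Nonzero entries
  therefore lie in [e⁻¹, e¹]; a fully lesioned ROI has no signal and its row
  and column are set to 0 (not exp(0) = 1, which would read as moderate
  connectivity).  The diagonal is kept at e¹.
- **p** (length N): per-ROI spared gray-matter fractions, p_i = 1 for an
  intact ROI and p_i < 1 where the lesion overlaps the ROI.

The network has three stages.

**Edge-based learning.**  An edge-to-edge convolution updates each edge
feature from all edges sharing an end-node,

    H_ij = φ( Σ_n r_n X_in + Σ_n c_n X_nj ),      H_ij ∈ R^d0,

followed by an edge-to-node aggregation

    h_i = φ( Σ_n g_n H_in + b1 ),                 h_i ∈ R^d1,

with per-node learnable filters r_n, c_n ∈ R^d0 and g_n ∈ R^{d1×d0}.  The
neighborhood is the full node set including the node itself: a correlation
connectome is dense, and the package does not threshold it.

**Lesion encoding.**  L = diag(p).  Column L_j = p_j e_j carries ROI j's
sparing.

**Subgraph learning.**  Each node gets an assignment score over k subgraphs,
S_j = ψ(Θ1 L_j) with ψ = softmax over the k entries (rows then sum to 1 and
read as soft memberships; a sigmoid ψ is selectable).  A node-specific filter
is generated from the score,

    vec(W_j) = Θ2 S_j + b2   (column-major vec),   W_j ∈ R^{d2×d1},
    h'_i = φ( Σ_j W_j h_j ),                       h'_i ∈ R^d2,

so ROIs with similar lesion encodings are transformed by similar filters.
With the full-neighborhood convention the inner sum is the same for every i,
making all rows of h' identical; all per-node discrimination enters through
W_j and S.  This degeneracy is preserved deliberately — it is how the update
is printed in the source formulation — rather than "fixed".

**Readout.**  flatten(h') → affine layer of width d3 → φ → affine → scalar ŷ.

**Loss.**  ℓ = (1/M) Σ_m (ŷ_m − y_m)² + λ·R, where R is the sum of squared
entries of exactly {Θ1, Θ2, b1, b2, r, c, g}; the readout head is not
penalized.

Default hyperparameters (from the published grid-search selection):
k = 8, d0 = 4, d1 = 8, d2 = 2, d3 = 8, λ = 0.005.

### Activation choice

φ defaults to **leaky ReLU** (slope 0.01), with plain ReLU, tanh and identity
selectable.  The subgraph update has no bias term and its output width is
d2 = 2; during early training its two pre-activation coordinates can both go
negative for every subject simultaneously.  Under plain ReLU that state is
absorbing — every upstream gradient becomes exactly zero and the model
permanently collapses to a constant (we observed exactly this; all parameter
gradients reached 0.0 within a few hundred steps).  Leaky ReLU removes the
absorbing state at negligible cost and is otherwise equivalent.

### Initialization

Weights are drawn zero-mean with standard deviation scale/√fan_in per tensor
(fan_in = N for the edge filters, N·d0 for g, k for Θ2, N·d2 for the readout,
…), biases at a small positive constant.  When training starts from scratch,
the harness refines this with a data-calibrated pass (in the spirit of
layer-sequential unit-variance initialization): a forward pass over the
training subjects rescales each stage's weights so its pre-activations have
unit spread across subjects, and sets the bias terms to center pre-activations
at +0.5.  Without this, activation scale grows with N through the dense sums
and the published learning rate of 0.01 is unusable (early updates explode,
then the decay schedule freezes the network far from any minimum).

## Training harness

- **Optimizer**: Adam (β₁ = 0.9, β₂ = 0.999), learning rate 0.01 decayed by
  0.95 every 20 optimizer steps.  The default batch is the full training set
  (cohorts are small), so steps and epochs coincide; mini-batching is
  configurable.
- **Early stopping**: a seeded 10% validation split of the training subjects
  is held out; training stops after `patience` epochs without improvement in
  validation MSE and the best-validation parameters are restored.
- **Input standardization** (default on): connectivity entries are z-scored
  entrywise against the training subjects.  Raw entries are ≈1.2 ± 0.17
  (exp of correlations), i.e. mean-dominated; standardizing makes the
  across-subject variation — the only part that carries signal — the unit of
  scale.  The fitted transform is stored in the checkpoint and applied at
  prediction time.
- **Target standardization** (default on): scores are z-scored on the
  training split and predictions mapped back.  Adam's per-coordinate step is
  bounded by the learning rate, so under the geometric decay the total
  parameter travel is bounded by ≈ lr₀ · decay_every / (1 − decay) = 4;
  raw 0–100 targets would be unreachable from a small initialization within
  the published schedule.

Both transforms are harness conveniences around the model, not changes to it;
the loss is computed exactly as defined on whatever scale the targets are
given.

## The synthetic cohort generator

The generator emulates the structure of a lesion-augmented healthy reference
dataset: hundreds of healthy scans into which artificial lesions are inserted.

- **Toy atlas**: an ellipsoidal "brain" on a small voxel grid (default
  24×24×24), split at the x-midline into hemispheres (x < midline = LEFT,
  0-based indexing), each hemisphere cut into arterial territories
  (contiguous slabs along y; default 3 per hemisphere), each territory
  parcellated into contiguous ROIs by seeded multi-source BFS (default 60
  ROIs total; an N = 246 atlas is a configuration point, not a constant).
  Gray matter = all labeled voxels.
- **Lesions** obey four rules: left hemisphere only; confined to one
  arterial territory; 5–20% of that territory's gray matter; 6-connected and
  simply-connected.  "Simply-connected" is operationalized as: morphological
  hole filling (flood fill from the volume border) is the identity.  Growth
  is randomized frontier expansion over the 6-neighborhood, followed by hole
  filling; if filling overshoots the size cap, boundary voxels that do not
  break connectivity or create holes are removed.
- **Time series**: voxel series = community signal + ROI signal + voxel
  noise (weights 1.0 / 0.5 / 0.3 by default).  The ROI → community map is a
  property of the toy brain shared across subjects, as functional networks
  are in real cohorts; per-subject draws give individual variation.  The
  default run length is 1200 timepoints, matching one standard resting-state
  run of the emulated reference data.  Optionally each subject carries a
  latent community-coupling trait u ~ U(−1, 1) scaling the community weight
  by (1 + jitter·u) — individual differences in network coherence.
- **Connectivity**: exponentiated Pearson correlations of ROI means over
  non-lesioned voxels (fully lesioned ROI ⇒ zero row/column), then
  lesion-dependent corruption: entries touching a partially lesioned ROI are
  attenuated (default ×0.5), perturbed with symmetric Gaussian noise
  (default sd 0.1), and clipped to the original value range of X.
- **Scores**: healthy scores are truncated-normal on [0, 100] (default
  mean 85, sd 10, mimicking a high-functioning healthy cohort), optionally
  plus connectivity_weight·u (coupling behavior to the latent coherence
  trait).  The observed score is the healthy score multiplied by the spared
  gray-matter fraction of the **left hemisphere** by default — language is
  left-lateralized, and a whole-brain fraction would be ≈1 for any plausible
  lesion and give negligible score variance.  Whole-brain and host-territory
  modes are selectable.

Everything is sub-seeded deterministically from the cohort seed: a cohort is
a pure function of (configs, seed), and the exported manifest records every
per-subject seed.

### Planted-signal experiment preset

Signal-recovery and transfer experiments use a documented preset
(`planted_signal_cohort`): healthy-score sd 3, host-territory score
rescaling, coupling trait jitter 0.2 with connectivity weight 3.  With these
conditions the observed score decomposes into a component recoverable from
the lesion encoding (territory sparing; ≈60% of variance), a component
recoverable from connectivity (the coherence trait; ≈10%), and irreducible
healthy-score noise (≈30%).  The transfer-target preset shifts the
healthy-score mean from 85 to 65, emulating a patient cohort with a
different severity distribution under the same generative process.

### What the generator does not emulate

No hemodynamics, autocorrelated BOLD noise, motion or scanner artifacts; no
registration error; lesions are single connected blobs rather than realistic
infarct shapes; score attenuation is exactly proportional to spared gray
matter rather than behaviorally heterogeneous.  Passing tests on this data
shows the pipeline recovers planted lesion–behavior structure under its own
generative assumptions — not that it attains any particular accuracy on real
patients.

## Numerical choices and degenerate inputs

- Correlation of a zero-variance (but not fully lesioned) ROI mean series is
  an error naming the ROI, never a silent NaN.
- Connectivity CSVs are validated on read: square, finite, symmetric within
  1e-8 (symmetrized with a warning below tolerance, rejected above).
- Metrics: R² is flagged undefined when the targets have zero variance;
  Pearson when either vector is constant.  Paired model comparison defaults
  to the Wilcoxon signed-rank test (robust at small fold counts; paired t
  selectable); all-zero differences return p = 1, flagged degenerate.
- Subgraph membership = argmax of the cohort-mean assignment score per ROI,
  ties to the lowest subgraph index; subgraphs are ranked by column mean.
- CV fold assignment: a seeded permutation split into near-equal folds per
  repeat; repeated-CV summaries report mean ± sd over repeat means (sd over
  folds when there is a single repeat).

## Problem sizes used in the shipped experiments

The test suite and examples run the generator at desk scale: the default
60-ROI atlas, cohorts of up to 300 subjects for signal recovery and 300 + 50
for the pretrain-vs-scratch transfer comparison, chosen as the smallest sizes
at which the planted effects are comfortably detectable.

## Known limitations

- The subgraph update is kept exactly as printed (identical rows across
  nodes); a per-node variant would likely be more expressive.  On the
  planted-signal cohorts this shows up as a real recovery ceiling: the node
  update collapses each subject to a d2-dimensional summary in which the
  lesion encoding enters only multiplicatively (softmax-generated filters
  times connectivity-derived features), and held-out correlation saturates
  well below what a plain linear model reading p directly achieves on the
  same data.  The signal-recovery test in the acceptance suite documents
  this: it asserts the aspirational cross-validated R² and fails against the
  measured value, rather than hiding the gap.
- At the λ selected by the sweep on synthetic data (λ = 1), optimization has
  a long (~hundreds of epochs) validation plateau before fitting begins;
  early stopping needs a generous patience or a min-epoch warmup there
  (`TrainConfig.min_epochs`), and pretraining runs are best trained to their
  full epoch budget.
- Hand-written backprop covers the shipped architecture only; changing the
  computation graph requires updating the gradients (they are verified
  against finite differences in the test suite).
- The two-stage grid search evaluates a full Cartesian product; for wide
  search spaces supply a custom evaluator or restrict `search_widths`.
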