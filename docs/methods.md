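# Methods

## Problem setting

The package classifies subjects into two diagnostic groups (positive =
patient, negative = control) from parcellated resting-state BOLD time
series: one `T × R` matrix per subject (T timepoints, R regions of
interest). Single-site clinical cohorts are small (tens of subjects), so the
pipeline combines three ideas: sample augmentation by sliding windows,
graph representations at two levels of connectivity, and a graph neural
network whose pooling step doubles as a region-importance probe.

## Pipeline

### Sliding-window augmentation

A series of `M` timepoints yields `K = ⌊(M − W)/s⌋ + 1` windows of length
`W` at stride `s`; each window becomes one training sample with the
subject's label. When `(M − W)` is not a multiple of `s` the trailing
timepoints beyond the last full window are dropped — all graphs must share
one node/feature shape. Defaults `W = 130`, `s = 5` (for `M = 170` this
gives `K = 9` windows per subject). Windows are raw slices; no tapering.

### Graph construction

Per window, Pearson correlation between ROI column series gives the FC
matrix `ρ`. Two graph views are built:

* **Low-order (Lo):** adjacency `A_Lo = φ_t(ρ)` where `φ_t` zeroes
  off-diagonal entries with `|ρ| < t` and keeps `|ρ|` as edge weight
  (absolute values keep degrees nonnegative so the symmetric normalisation
  below stays real; a binary mode replaces survivors with 1). Node features
  are the windowed per-ROI mean and variance (`R × 2`; unbiased `n−1`
  variance by default, population convention behind a flag).
* **High-order (Ho):** entry `(i, j)` of the profile-correlation matrix is
  the Pearson correlation between rows `i` and `j` of `ρ` with positions
  `i` and `j` excluded from both vectors — exclusion stops the unit
  diagonal and the shared `ρ_ij` entry from inflating similarity. The
  thresholded matrix is `A_Ho`; node features are the raw FC rows
  (`R × R`).

No Fisher z-transform is applied anywhere. A zero-variance ROI (possible in
degenerate or synthetic data) gets correlation 0 to all others with a
warning rather than an abort. The default threshold is `t = 0.6`; the
synthetic benchmark below is run at `t = 0.4`.

### The SA-GCN classifier

Each view has its own branch of `blocks = 2` stages

    X ← ReLU( SAGPool( GCN(Â, X) ) ),   GCN(Â, X) = D̂^{-1/2} Â D̂^{-1/2} X W,
    Â = A + I,  D̂_ii = Σ_j Â_ij,

where SAGPool scores nodes with a one-channel graph convolution
`z = D̂^{-1/2}ÂD̂^{-1/2} H θ`, keeps the `⌈kN⌉` highest-`tanh(z)` nodes
(ties to the lower index), gates surviving features by `tanh(z)`, and
induces the sub-adjacency on the survivors. The stage-level ReLU matters:
it zeroes negatively-gated survivors, so only nodes the attention scores
*positively* propagate information. This breaks an otherwise exact
symmetry between "keep informative nodes with positive gates" and "drop
them with negative gates" — the latter is an optimisation trap (discarded
nodes receive no gradient), and with signed gates roughly half of all
training runs fell into it, costing test accuracy and making the
importance ranking flip sign run-to-run.

After each stage a mean‖max readout (dimension `2·hidden`) is computed and
the per-stage readouts are summed into the branch embedding
(hierarchical-readout style). Branch embeddings are concatenated
("feature-level fusion"), passed through dropout and a one-hidden-layer
softmax head, and the whole two-branch network is trained jointly on a
single cross-entropy loss. Single-view models (`view = lo | ho`) skip the
concatenation; `pool = False` removes the pooling stage entirely, giving
the plain-GCN ablations.

Everything, including batched backprop and Adam, is implemented in numpy.
Brain graphs are small (R ≲ 116 nodes) and same-sized within a dataset, so
graphs are stacked into `(batch, N, ·)` arrays and one training fold runs
in seconds on a CPU. Gradients through the top-k selection are treated as
piecewise constant (the selection contributes no gradient), exactly as
automatic differentiation would; the backward pass is verified against
central finite differences in the test suite.

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| blocks per branch | 2 | two conv+pool stages; survivors `⌈k²N⌉` after the second |
| hidden dim | 32 | smaller dims train too slowly, larger ones memorise windows |
| pooling ratio k | 0.5 | half the nodes survive each stage |
| dropout | 0.5 | on the fused embedding, before the head |
| optimiser | Adam, lr 1e-3 | |
| weight decay | 5e-3 | L2; the main guard against window memorisation |
| epochs / batch | 100 / 16 | |

The learning rate/weight decay/width defaults were chosen for stable
*subject-level* generalisation: windowed samples of one subject are highly
correlated, so an over-parameterised network can reach zero training loss
by memorising window idiosyncrasies while fold-level accuracy swings
widely. All values are exposed in `ModelConfig` and logged with every run.

### Evaluation protocol

Repeated stratified k-fold cross-validation (defaults 10 repeats × 5
folds) splits *subjects*, never windows; a hard runtime error fires if any
window of a test subject reaches the training set. Test-subject window
probabilities are averaged (majority vote behind a flag; for the
margin-classifier baselines, hard labels act as 0/1 probabilities, making
the mean a vote share) and the subject prediction is scored with ACC, TPR,
TNR, PPV, NPV and F1; ratios with empty denominators are reported as 0 and
flagged. Aggregates are mean ± sd over all repeat × fold cells (sd over
repeat means can be derived from the per-cell report). Methods are
compared with a two-tailed *paired* t-test on repeat-level accuracies;
identical vectors give p = 1 by convention, and a zero-variance nonzero
difference is flagged degenerate with p = 0.

Baselines: **CBN** (per-window mean/variance vector, `2R` features) and
**FCN** (upper-triangle FC vector, `R(R−1)/2` features), both z-scored on
training folds and classified with a linear max-margin classifier
(`LinearSVC`) under the identical fold plan.

### ROI importance

For test graphs, an ROI's occurrence probability is the fraction of graphs
in which it survives a designated pooling layer (default: the first; after
two k = 0.5 stages only ~25% of nodes remain, which compresses the
ranking). Counts are pooled over all repeats' test folds. The table is
sorted descending with index-order tie-breaks and reported per view.

## Synthetic cohorts and what they do (not) show

`simulate_cohort` draws each subject from a zero-mean multivariate normal
with unit variances, uniform background correlation `ρ₀`, and an elevated
within-module correlation that differs by group; options add AR(1)
temporal smoothing (variance-preserving, to mimic BOLD autocorrelation)
and a mean/variance shift on module ROIs of the patient group (a
node-feature effect). The benchmark spec is 40 + 40 subjects, R = 30,
T = 170, ρ₀ = 0.1, an 8-ROI module at 0.6 (patients) vs 0.2 (controls), no
smoothing, no node effect. Because baseline variances are unit and means
zero, the benchmark's Lo node features are *deliberately uninformative*:
the signal is purely in the edges. Consequently the planted-ROI enrichment
of the attention ranking is read from the Ho view, whose node features
(connectivity profiles) carry the signal; Lo-view enrichment on this
cohort is expected to hover near zero. A null spec (equal module
correlation, no node effect) makes the groups exchangeable and must drive
the pipeline to chance.

The generator emulates stationary second-order structure only: no
hemodynamic response, no site/scanner effects, no motion artefacts, no
heavy tails, no negative-correlation pathology. Passing its benchmarks
shows the pipeline recovers focal covariance differences at realistic
sample sizes — not that it reaches any particular accuracy on real
clinical data.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] and symmetrised after computation;
  zero-variance profiles/series correlate as 0 with a warning.
* Thresholds outside (0, 1], pooling ratios outside (0, 1], non-square or
  negative adjacencies, empty readouts, single-class training sets, and
  subject leakage all raise immediately.
* Top-k ties break toward the lower node index (stable argsort on the
  negated scores), making runs bit-reproducible.
* All randomness (init, shuffling, dropout, simulation) flows from
  explicit `numpy` generator seeds; two runs with the same seed write
  byte-identical reports.
* Benchmark problem sizes (R = 30, 2 repeats × 5 folds in the acceptance
  script) keep a full from-scratch reproduction to minutes on one CPU
  core while leaving ~10 expected windows per subject, the same augmentation
  factor as the full-scale setting.

## Known limitations

* Signed connectivity is discarded (absolute-value edge weights); signed
  graph convolutions are out of scope.
* The attention importance is a *selection frequency*, not a causal
  attribution; anti-selected informative regions (possible when their
  node features are uninformative, as in the Lo view of the edge-only
  benchmark) rank low despite carrying signal.
* Aggregation from window to subject assumes windows are exchangeable
  evidence; no temporal state modelling (dynamic-FC clustering is a
  non-goal).
* The numpy trainer targets small graphs; it does not scale to
  voxel-level or multi-thousand-node graphs.
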