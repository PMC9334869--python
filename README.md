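# sagcn — multi-view brain-network classification with self-attention graph pooling

`sagcn` classifies subjects (e.g., autism spectrum disorder vs. typical
controls) from resting-state fMRI ROI time series by building two functional
graph views per sliding window and feeding them to a two-branch graph
convolutional network with self-attention pooling. It is aimed at
neuroimaging researchers who have parcellated BOLD series (a `T × R` matrix
per subject, such as 170 timepoints × 116 AAL regions) and want a
subject-level diagnosis pipeline plus an attention-based ranking of which
brain regions drive the decision.

## Method

1. **Sliding-window augmentation.** Each subject's series of `M` timepoints
   is cut into `K = ⌊(M − W)/s⌋ + 1` overlapping windows of length `W` at
   stride `s`. Every window becomes an independent training sample carrying
   the subject's label (defaults `W = 130`, `s = 5`).
2. **Low-order functional graph (Lo-FGN).** For each window, the Pearson
   functional-connectivity matrix `ρ_ij` is sparsified by a threshold `t`
   (entries with `|ρ| < t` are zeroed; survivors keep their magnitude as edge
   weight) and used as the adjacency `A_Lo`; node features are each ROI's
   windowed mean and variance, `X_Lo ∈ R^{R×2}`.
3. **High-order functional graph (Ho-FGN).** "Correlation of correlation":
   `A_Ho` thresholds the Pearson correlation between pairs of connectivity
   profiles (rows of the FC matrix, self-entries excluded), and the node
   features are the raw FC rows, `X_Ho ∈ R^{R×R}`.
4. **SA-GCN.** Each branch stacks blocks of graph convolution
   `X ← ReLU(D̂^{-1/2}(A + I)D̂^{-1/2} X W)` followed by self-attention graph
   pooling: a one-channel graph convolution scores every node, the top
   `⌈kN⌉` nodes survive, and surviving features are gated by `tanh(score)`.
   A mean‖max readout after each block is summed into a branch embedding;
   the Lo and Ho embeddings are concatenated (feature-level fusion) and
   classified by a softmax head. The whole network — including backprop and
   Adam — is implemented in numpy; brain graphs are small enough that CPU
   training takes seconds.
5. **Evaluation.** Repeated stratified 5-fold cross-validation split at the
   *subject* level (windows of a test subject never appear in training; a
   hard error guards this). Window probabilities are averaged into one
   subject prediction and scored with ACC/TPR/TNR/PPV/NPV/F1; methods are
   compared with a paired t-test over repeat-level accuracies.
6. **ROI importance.** On test graphs, the fraction of graphs in which an
   ROI survives the first pooling layer is its occurrence probability; the
   ranked table names the regions the attention found discriminative.

## Worked example

The package ships a seeded generator of two-group cohorts whose groups
differ in the correlation level inside a planted 8-ROI module (patients 0.6,
controls 0.2, background 0.1) — the kind of focal connectivity difference
the classifier is designed to detect:

```bash
sagcn simulate --out cohort --seed 7
sagcn evaluate --manifest cohort/manifest.csv --out report.csv \
    --methods cbn,sagcn-fused --repeats 2 --folds 5 -t 0.4 --seed 0
```

which prints a method × metric summary (mean ± sd in percent over the
2 × 5 = 10 fold cells; exact values for this seed):

```
     method           ACC           TPR           TNR           PPV           NPV            F1  p_vs_ref
        cbn 53.1 +/- 11.9 51.2 +/- 17.1 55.0 +/- 15.8 52.8 +/- 14.7 53.1 +/- 11.7 51.4 +/- 15.1  0.105137
sagcn-fused 90.6 +/- 20.3 88.8 +/- 23.9 92.5 +/- 16.9 90.8 +/- 21.7 90.4 +/- 19.5 89.7 +/- 22.9       NaN
```

The fused SA-GCN recovers the planted connectivity signal (most fold cells
score 100%, an occasional training run lands in a poorer optimum — hence
the wide sd), while the conventional-brain-network baseline (per-ROI
mean/variance features, linear SVM) stays at chance: by design the planted
effect lives in the *edges*, not in single-ROI statistics. The ranked
Ho-view ROI importances (`sagcn importance --view ho ...`) put the planted
module at the top of the table.

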