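# Methods

This note documents the models and procedures implemented in `fcnfusion`,
the parameters that matter, the synthetic data used to validate them, and
the design choices made where the procedure was genuinely open.

## Step 1 — functional connectivity networks

**Correlation views.** `pearson_matrix` is the ordinary Pearson correlation
of ROI time courses (symmetrized, unit diagonal, entries clipped to
[−1, 1] against floating-point drift); any zero-variance ROI row is an
error naming the region, since its correlation is undefined. `fisher_z`
applies arctanh entry-wise; because arctanh diverges at |r| = 1, inputs are
clipped to ±(1 − 10⁻⁷) — the unit diagonal therefore maps to the clipped
maximum rather than infinity, keeping the matrix finite for the classifier.
Off-diagonal clips are rare in real data and emit a warning.

**Embeddings.** Each ROI is one point whose feature vector is its full
time course (so co-fluctuating regions embed nearby); three 2-D spaces are
offered: linear (PCA, deterministic), stochastic (t-SNE, perplexity capped
at (R−1)/3 for small inputs) and topological (UMAP with `n_neighbors=15`,
`min_dist=0.1`, the standard visualization settings). Stochastic methods
take an explicit seed and are bit-reproducible from it.

**Mapper.** The 2-D embedding is covered by `n_intervals²` rectangles
(default 10×10). Each base interval is expanded by
`overlap_fraction × base_width` on *each side* (default 30%), so
neighbouring bins share a band two overlap-widths wide; this pad width is
what makes sparse configurations (tens of points, as with ROI embeddings)
actually place points in the shared bands — with narrower pads adjacent
clusters routinely share no member and the nerve disintegrates. Points
within a bin are clustered by single linkage cut at a distance threshold
(default: the median nearest-neighbour distance of the whole embedding;
ties at the cutoff merge, via a 10⁻⁹ relative slack) or by DBSCAN
(`clusterer="density"`). Duplicate clusters and clusters properly contained
in another are dropped: a subset cluster witnesses no overlap its superset
does not, but would inflate nerve degrees. Two ROIs are adjacent in the
resulting FCN when they co-occur in a cluster, and additionally (default
on, toggleable) when their clusters overlap through a shared member. The
nerve graph itself is exposed (`build_mapper`) for topological checks.

The default clustering cutoff is a *scale* heuristic: for point clouds
whose nearest-neighbour distances vary widely (e.g. Gaussian blobs), half
the points exceed the median by definition, so an explicit `cluster_param`
at the geometry's natural scale is the right control. The cover and
clustering parameters do not claim to replicate any particular published
graph; they are exposed in `MapperConfig`.

## Step 2 — attention classification and group representation

**Model.** A single multi-head self-attention layer over R tokens (one per
ROI, feature vector = that ROI's row of the input matrix), linearly
projected to width `H·d_k`; H heads of scaled dot-product attention
(softmax(QKᵀ/√d_k)·V), concatenated, output-projected, passed through a
one-hidden-layer ReLU perceptron of the model width, mean-pooled over
tokens (preserving permutation symmetry), and mapped to two logits.
Defaults: H = 128, d_k = 2 (found robust in a head-count search over
{16, 32, 64, 128}), batch 8, dropout 0.9 on the perceptron hidden layer,
Adam at learning rate 0.01, cross-entropy loss, 10-fold stratified
cross-validation. The value dimension equals d_k per head. Depth is one
attention layer — the extracted distribution averages the heads of that
layer, which pins the architecture.

The network is implemented in NumPy with hand-derived reverse-mode
gradients (verified against central differences to ~10⁻⁷ relative error)
and a standard Adam optimizer; the architecture is a fixed shallow graph,
so explicit backprop is both transparent and fast at these sizes.

**Training protocol.** Within each CV fold, early stopping (patience 10,
up to 100 epochs by default) monitors a stratified 20% validation split
carved out of the *training* fold; the held-out fold is touched only for
the reported accuracy. Monitoring the held-out fold itself would select
the best epoch on the scored subjects and visibly inflates accuracy under
label permutation. After cross-validation, a final model is trained on the
full cohort (early stopping on training loss) and every subject is passed
through it in evaluation mode — dropout off — to extract the per-subject
attention distribution matrix (mean of the H row-stochastic head weights;
itself row-stochastic by convexity).

**Group representation.** Per subject and ROI, the coefficient of
variation (population σ divided by mean; both the σ convention and
row-vs-column orientation are exposed as options, row + population σ being
the default) of the ROI's attention row measures how unevenly that region
distributes its attention. Subjects × ROI CVs form the group
representative matrix. ROI selection combines per-ROI mean CV and per-ROI
mean attention by unweighted rank sum (average ranks for ties) and keeps
the best ⌊0.25·R⌋ — 29 regions of the 116-ROI atlas. Ties break by higher
mean attention, then label, so the list is deterministic. An
intersection-of-quartiles mode is provided as an alternative reading of
"top 25% in both statistics"; rank-sum is the default because it always
returns exactly the quartile count.

## Step 3 — latent-space item-response model

**Model.** `y_ij ~ Normal(θ_j + β_i − ||u_j − v_i||, σ²)` for subject i
and ROI j, with θ_j ~ N(0, σ_θ²), σ_θ² ~ Inv-Gamma(a, b),
β_i ~ N(0, 1), and 2-D latent positions u_j, v_i with standard-normal
priors. A strong subject–ROI association pulls the pair's positions
together; a ROI that associates strongly with *all* subjects can only sit
near the centroid of the subject cloud — hence "near the origin" flags
group-representative regions.

**Sampler.** Metropolis-within-Gibbs: random-walk Metropolis for each
θ_j, β_i, u_j, v_i, conjugate Gibbs draws for σ_θ²
(Inv-Gamma(a + R/2, b + ½Σθ_j²)) and for σ² (same Inv-Gamma(0.001, 0.001)
treatment, a choice mirrored from the σ_θ² prior since the likelihood
variance needs one). Because the likelihood factorizes over rows (β, v)
and columns (θ, u), each block's component-wise updates are evaluated
vectorized — one O(N·R) pass per block per iteration — which makes the
default 55,000-iteration protocol run in seconds at desk scale.
Initial values are drawn from the priors with the run seed; any block can
be frozen at supplied values (used by the conjugate-reduction test, which
checks the θ chain against the closed-form Normal posterior). A
literal independent-proposal variant (proposals drawn from the priors,
Hastings ratio reducing to the likelihood ratio) is kept behind
`proposal="independent"` for comparison; the random-walk scheme is the
default because small fixed jump scales only make sense for random walks.

Default jump scales are 0.005 (θ, β, u) and 0.003 (v) — appropriate for
the small dynamic range of CV-valued response matrices. They are *scale
parameters*: on synthetic fixtures with latent positions at ±2 they yield
~0.98 acceptance and a random-walk span far below the configuration scale,
so the validation fixtures configure 0.1 for all blocks (acceptance
0.08–0.27, i.e. healthy mixing). Chains retain every `thin`-th state after
burn-in: (55,000 − 5,000)/5 = 10,000 draws under the default protocol.

**Identifiability.** The likelihood is invariant under joint rigid motions
of (U, V) (tested to machine precision), so retained draws are aligned by
orthogonal Procrustes to the first retained draw (rotation/reflection;
optional recentering). The posterior-mean ROI configuration can further be
oblimin-rotated: the quartimin criterion (oblimin γ = 0) is minimized by
an oblique gradient-projection loop, with the criterion value and origin
distances recorded before and after so the (non-rigid) transformation is
auditable. Origin proximity is computed on aligned posterior means by
default; the near-origin flag marks the lowest quartile of norms, or an
explicit radius when configured.

**Convergence caveat.** Single chains occasionally mix slowly from a poor
prior draw (on the standard recovery fixture, true-vs-estimated distance
correlations across seeds range ~0.78–0.98); multi-chain diagnostics
beyond acceptance rates and stored traces are out of scope.

## Summary networks and categorization

A group's summary FCN weights edge (j, k) by the fraction of the group's
subjects whose FCN contains it, then keeps edges with ratio ≥ threshold
(default 0.2; weak inequality, so ties at the threshold survive — for
binary FCNs this is equivalent to presence in ≥ ⌈t·N⌉ subjects, checked
exhaustively in the tests). An optional top-percentile mode thresholds by
ratio quantile instead; the absolute cutoff is primary because 0.2 is the
stated operating point. Categorization across the two groups follows a
fixed decision table: in both top-quartile lists and near-origin in both
fits → `both`; in both lists but near-origin in exactly one →
`more_reactive_<group>`; in exactly one list → `only_<group>`; otherwise
`none`. Each categorized ROI is reported with its direct neighbors in the
thresholded summary network as a lettered cluster (A, B, C… in atlas
order), and a plotting routine renders the colored network to SVG
(saturated category colors for selected ROIs, dimmed for their neighbors).

## Synthetic data

**Cohorts** (`simulate_cohort`): zero-mean stationary Gaussian AR(1)
series whose cross-sectional covariance is a block compound-symmetry
correlation matrix; the two groups share the block partition and differ
only in within-block correlation levels. This targets exactly the
statistic the pipeline consumes (between-ROI correlation) and encodes the
group difference in connectivity, not amplitude. Positive-definiteness of
every block is verified at construction with an error naming the offending
block. Defaults mirror a 116-ROI, 200-time-point acquisition; the
validation cohort uses 20 ROIs, 150 time points, 15 subjects per group and
a single 8-ROI block at correlation 0.6 vs 0.1 (gap 0.5) — effect sizes
chosen for testability, not clinical realism. What passing tests show:
the pipeline detects planted covariance differences; what they do not
show: robustness to hemodynamic confounds, motion artifacts, scanner
effects or atlas misregistration, none of which are simulated.

**Item-response matrices** (`simulate_item_response`): direct draws from
the LSIRM with ROI positions planted around configurable cluster centers,
returning the full ground truth for recovery tests. The standard recovery
fixture is 60 subjects × 30 ROIs, noise SD 0.1, two ROI clusters at
distance 4.

## Numerical and reproducibility choices

- Softmax and cross-entropy use max-shift / log-sum-exp stabilization.
- All stochastic stages take explicit seeds; the pipeline fans one global
  seed out to stages by fixed offsets, so stage-level reruns reproduce the
  full run's artifacts. Reports serialize with sorted keys; identical
  seeds give byte-identical reports.
- Degenerate inputs: all-identical embedding coordinates produce one
  Mapper cluster (complete FCN); a degenerate all-equal Procrustes
  reference falls back to the identity with a warning; an isolated
  categorized ROI yields a singleton cluster; non-finite sampler states
  abort with the iteration index.
- Problem sizes in the validation suite (tens of ROIs and subjects,
  2,000–30,000 MCMC iterations) were chosen so every oracle-backed check
  runs at desk scale while exercising the same code paths as the
  full-atlas protocol, whose bookkeeping (10,000 retained draws, 29
  selected regions at R = 116) is asserted directly.

## Known limitations

- Binary group comparison only; the multi-class extension is future work.
- The binary-response LSIRM variant is not implemented (the continuous
  likelihood is the one used here).
- No NIfTI/DICOM ingestion: inputs are preprocessed ROI × time tables.
- Mapper cover/cluster defaults are principled but not calibrated to any
  external reference graphs.
- No pretrained weights are shipped; training is always from scratch.
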