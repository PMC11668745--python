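# fcnfusion

Fusion framework for discovering **group-discriminative brain-region
connectivity** from resting-state fMRI time series. Given per-subject
ROI × time BOLD matrices for two cohorts (e.g. two stages of cognitive
impairment over the 116 AAL atlas regions), the package identifies the
regions whose connectivity patterns distinguish the groups, in three steps:

1. **Functional connectivity networks (FCNs).** Per subject, ROIs are
   either correlated directly (Pearson *r*, Fisher *z*) or embedded into 2-D
   — linear (PCA), stochastic (t-SNE) or topological (UMAP, `n_neighbors=15`,
   `min_dist=0.1`) — and connected by the Mapper: the embedding is covered
   with overlapping rectangles, points are clustered within each rectangle,
   and ROIs sharing a cluster (or lying in overlapping clusters) are joined.

2. **Self-attention classification.** A single-layer multi-head
   self-attention binary classifier (*H* = 128 heads, *d_k* = 2, batch 8,
   dropout 0.9, Adam at 0.01, cross-entropy, 10-fold CV) is trained on the
   subjects' matrices; each ROI is one token. For every subject the
   **attention distribution matrix**

   `attnM(Q, K) = (1/H) Σ_h softmax(Q W_h^Q (K W_h^K)ᵀ / √d_k)`

   is extracted in evaluation mode — a row-stochastic R × R matrix whose
   row *j* says how ROI *j* attends to every region. Per subject and ROI,
   the coefficient of variation (CV = σ/μ) of the attention row is
   computed; stacking subjects of a group gives the **group representative
   matrix** X ∈ ℝ^{N_g × R}, and ROIs in the top 25% on both mean CV and
   mean attention (unweighted rank sum; 29 of 116 regions) are the group's
   candidates.

3. **Latent-space item-response model (LSIRM).** The group matrix is
   modeled as `y_ij ~ Normal(θ_j + β_i − ||u_j − v_i||, σ²)` with ROIs as
   items and subjects as respondents, fit by Metropolis-within-Gibbs MCMC
   (55,000 iterations, 5,000 burn-in, thinning 5 → 10,000 draws; jump
   scales 0.005 for θ/β/u and 0.003 for v; Inv-Gamma(0.001, 0.001)
   hyperpriors). Draws are Procrustes-aligned and the mean configuration
   oblimin-rotated. ROIs whose latent position sits **near the origin**
   interact consistently with all subjects; combined with the top-quartile
   lists of both groups this yields a three-way categorization (meaningful
   in both groups / more reactive in one / only in one), rendered on group
   **summary FCNs** (edges kept when ≥ 20% of subjects share them).

The attention classifier is implemented directly in NumPy (analytic
gradients, Adam); the sampler, Mapper and oblimin rotation are likewise
first-class implementations with oracle-backed tests.

## Worked example

A fully synthetic run — two 8-subject groups over 16 ROIs whose first six
regions form a connectivity block with within-block correlation 0.6 in
group A versus 0.1 in group B:

```python
from fcnfusion.attention import AttnConfig
from fcnfusion.lsirm import McmcConfig
from fcnfusion.mapper import MapperConfig
from fcnfusion.pipeline import PipelineConfig, run_pipeline
from fcnfusion.synthetic import CohortSpec

cfg = PipelineConfig(
    output_dir="runall", seed=7,
    cohort=CohortSpec(
        n_rois=16, n_timepoints=100,
        n_subjects_per_group={"A": 8, "B": 8},
        block_partition=[list(range(6))],
        within_block_corr_by_group={"A": [0.6], "B": [0.1]},
    ),
    input_kind="pearson", embedding_method="linear",
    mapper=MapperConfig(n_intervals=4, overlap_fraction=0.3, cluster_param=2.0),
    attention=AttnConfig(n_heads=8, d_k=2, max_epochs=30, cv_folds=4),
    mcmc=McmcConfig(n_iterations=2500, burn_in=500, thin=2,
                    jump_theta=0.1, jump_beta=0.1, jump_u=0.1, jump_v=0.1),
)
report = run_pipeline(cfg)
```

The run prints a JSON report (`runall/report.json`) containing, among
other entries:

```
"cv_accuracy": 1.0
"top_rois":   {"A": ["ROI_003", "ROI_006", "ROI_002", "ROI_005"],
               "B": ["ROI_003", "ROI_016", "ROI_007", "ROI_005"]}
"category_counts": {"none": 12, "only_A": 2, "only_B": 2}
"lsirm": {"A": {"n_retained": 1000,
                "acceptance_rates": {"theta": 0.3166, "beta": 0.2384,
                                     "U": 0.2753, "V": 0.1582}, ...}}
```

Reading: the planted connectivity difference is perfectly classifiable
(cross-validated accuracy 1.0); each group's top quartile (4 of 16 ROIs)
leans on block members (ROI_002/003/005/006); ROIs selected for exactly
one group are categorized `only_A`/`only_B` and reported with their
direct-neighbor clusters in each group's thresholded summary network.
Acceptance rates confirm the sampler moved (all blocks inside (0.05,
0.95)), and `n_retained` equals (iterations − burn-in)/thinning. The same
stages are available as CLI subcommands (`fcnfusion simulate | build-fcn |
train | group-matrix | lsirm | summarize | run-all`) so each step's
artifacts can be inspected before the next runs.

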