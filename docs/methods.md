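# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the limits of what the test suite shows.

## Synthetic cohort model

The generator (`matriscope.simulate`) draws a cohort of
`n_types × subtypes_per_type` subtypes with `n_samples_per_subtype`
patients each. Defaults — five tumor types, two subtypes per type (ten
subtypes in five meta-clusters), 50 patients per subtype, 120 matrisome
genes — represent a desk-scale cohort: large enough for every stage to
have power, small enough for a full pipeline run in seconds. The smallest
real subtypes in pan-cancer compendia have on the order of ten patients,
which is why `n_samples_per_subtype` may be set as low as 10 and the
eligibility rules use that floor.

**Background expression** is log-scale Gaussian: gene means jittered
around `base_mean = 8` with `base_sd = 2`, truncated at zero. Only the
rank and threshold statistics of the pipeline touch these values, so any
positive log-like scale is equivalent.

**Meta-cluster structure** is induced by shifting a random 10% of the
non-marker genes by `metacluster_shift_sd` (default 2) background SDs in
each meta-cluster's samples. At this magnitude the clusters are linearly
well separated yet the per-gene overlap is large, which is the regime the
embedding/GMM stage is meant for.

**Planted markers.** Each subtype receives `n_planted_markers_per_subtype`
(default 5) marker genes, disjoint across subtypes and excluded from the
meta-cluster shift genes. Marker genes are bimodal: background samples
follow N(μ, σ²); the marked subtype is shifted upward by Δ. The effect
size `marker_effect_sd` (default 3) is expressed in *cohort*-SD units:
because the shift itself inflates the marginal cohort SD, Δ solves the
self-consistency Δ = e·σ/√(1 − f(1−f)e²) with f the marked fraction; the
denominator is floored at 0.25 (amplification capped at 2×) so the shift
stays finite when f·e is large. The default count of five markers per
subtype matches the minimum coexpression-module size, so planted markers
can form a module — one marker alone is not what the cluster track is
designed to find.

**Regulator layers.** TF, gene-program and miRNA scores are standard
normal (already-normalised activities); copy number is a five-level
discrete variable (±2 with 3%, ±1 with 12%); methylation is Beta(2,2);
mutations are Bernoulli(0.2); the stromal fraction is 1 − purity with
purity uniform on [0.4, 0.9]. Each marker gene carries
`n_links_per_marker` (default 2) planted links cycling through
{tf, program, cna, methylation}; within the marked subtype the gene is
baseline + Σ effect·z + ε with standardized regulator values z,
`regulator_effect = 1` and `noise_sd = 0.5`. CNA/methylation/mutation
links are cis (the gene's own row), as in real regulatory genomics.

**Survival** is exponential with proportional hazards: the subtype's
first marker gene is prognostic with `hazard_log_hr = 1` per within-
subtype SD of expression, baseline hazard 1/1000 per day, and independent
exponential censoring tuned to a 30% censoring fraction.

What the generator does **not** emulate: read-count noise, batch effects,
copy-number segment structure, probe-level methylation, correlated
regulator activity across layers, non-proportional hazards, or informative
censoring. Passing recovery tests therefore demonstrate the pipeline's
logic and calibration, not its performance on raw consortium data.

## Meta-clustering

t-SNE uses PCA initialisation, perplexity ≈ n/100 bounded to [30, 500]
(and below (n−1)/3), learning rate n/12 — the standard large-data
recommendations. The Gaussian-mixture component count is chosen by BIC
over 1..10 (1 is included so a single blob is not force-split). GMM
labels are authoritative; UMAP and density clustering (HDBSCAN) are
diagnostics. Subtypes inherit cluster labels by majority vote, ties to
the lowest label.

With default markers the subtype substructure is as strong as the
meta-cluster separation, so BIC may legitimately resolve ten subtype
clusters instead of five meta-clusters. The pipeline is robust to this:
when a cluster contains a single subtype, the coexpression-module stage
(which needs within-scope contrast) falls back to the whole cohort, and
the background-exclusion rule simply excludes nothing extra. A
precomputed subtype → cluster table can be supplied to bypass clustering.

## Landmark selection

*Screen.* Two-sided Mann–Whitney U per gene, exact for small tie-free
samples, tie-corrected normal approximation otherwise; BH correction
across genes within a subtype; significance requires q < α (default 0.05)
and subtype median above background. Subtypes in the focal meta-cluster
are excluded from the background except in the largest cluster, whose
members are treated as mutually uncorrelated.

*Coexpression modules.* Signed adjacency ((1+r)/2)^β with β the smallest
power in 1..20 reaching a scale-free fit R² ≥ 0.8 (fallback 6);
topological-overlap dissimilarity; average-linkage clustering cut at 96%
of the tree height; modules below 5 genes stay unassigned. Module
eigengenes (first PC scores, oriented with mean expression) are
correlated with the subtype indicator (point-biserial), BH-corrected
across modules; cluster-level candidates are screen-significant genes in
associated modules (q < α).

*Adaptive lasso.* Ridge pilot (γ = 1), penalty weights 1/|β̃| applied as
column scaling, L1 logistic path cross-validated on deviance. The
intercept-only model competes in the CV and the **one-SE rule** picks the
strongest penalty within one standard error of the minimum: shuffled
labels then select nothing, while the min-deviance rule would keep
several noise genes. Complete separation is handled by the penalty.

*Subtype track.* Each gene's two-component EM fit (deterministic sorted
two-means initialisation, tolerance 1e-8, ≤ 1000 iterations, monotone
log-likelihood) is retained as a bimodality diagnostic; allocation uses
the subtype mean ≥ cohort mean + 2 SD rule, boundary inclusive. The
subtype mean (not per-sample values) is compared because allocation is a
per-subtype decision. A constant gene is degenerate and only allocated on
a strict mean excess.

Landmarks are the per-subtype intersection of the two tracks, with
provenance flags retained.

## Regulator inference

The per-task design stacks: the gene's own CNA, methylation and mutation
rows (cis features), all TF/program/miRNA regulators (restricted by
TF→target / miRNA→target maps when supplied), and the stromal fraction.
Constant columns are dropped; continuous columns standardized; binary
mutation columns left 0/1. Selection is invariant to column order and,
after standardization, to affine rescaling of continuous regressors.

*Sparse principal-component regression* is supervised: each component
direction is the covariance vector of the (deflated) design with the
(deflated) response, restricted to its dominant support (|cov| ≥ 50% of
the maximum) and normalised; response and design are deflated between
components. The component count is chosen over 0..5 by 5-fold CV of the
MSE with the one-SE rule — the zero-component model competes, so pure
noise selects nothing. Finally the supported columns are refitted by OLS
and only coefficients passing a BH check at FDR 1% across the support are
selected; this debiasing step calibrates the expected false-selection
fraction, which the raw component supports do not control. Estimating
the loadings jointly with the response (rather than from the design
alone) is essential: with independent regressor columns, unsupervised
sparse PCs are unrelated to the response and would never recover a
planted link.

*Random-forest regression* augments the design with an equal-width block
of shadow features (independently permuted copies), fits a forest
(default 500 trees) and computes permutation importances (mean MSE
increase, batched predictions). A regressor is selected when its
importance strictly exceeds the maximum shadow importance **and** reaches
10% of the top real importance; tasks whose 10-fold CV R² (smaller
auxiliary forests) is ≤ 0 select nothing. The relative-importance floor
matters: with ~W real and ~W shadow columns, exceeding the shadow maximum
alone is expected ~W/(W+1) ≈ 1 false selection per task.

The two methods specialise — the linear method on linear links, the
forest on threshold-shaped links invisible to correlation — and their
union, tagged by source, forms the candidate triplets.

## Robustness filter and prognostics

Each triplet's logistic model uses {gene, regulator, interaction term} so
the model literally encodes the interaction; training and evaluation use
the same full cohort deliberately (a CV option exists but is off by
default for fidelity to the original design). AUC is computed as the
Mann–Whitney concordance probability with ties counted ½ and is invariant
under monotone transforms of the scores; the keep rule is AUC ≥ 0.8,
boundary inclusive.

Prognostic scanning mean-splits each landmark gene within its subtype
(boundary to the high group, groups below 2 samples skipped), applies the
two-group log-rank test (equal to the Cox score test at β = 0 without
ties) and a Cox model with Efron ties on {split, age}. Exactly collinear
designs are refitted with a small ridge penalty (0.1) and a warning.
"Recursively stratified" is read as "for each gene in turn"; there is no
tree partitioning. α = 0.05 throughout.

## Problem sizes and determinism

Stage seeds are spawned from the master seed via `SeedSequence`, so every
stage is independently reproducible and a fixed seed yields bit-identical
bundles. The repeated recovery benchmark (`matriscope.benchmark`) runs
the pipeline with desk-scale settings — 60-tree forests with 3-fold CV
and one permutation repeat, 5-fold lasso CV, shortened t-SNE — chosen so
a 20-cohort benchmark completes in minutes on one CPU; the cohort
conditions themselves (ten subtypes, 50 patients per subtype, 3 cohort-SD
markers, unit regulator slopes) are never reduced. Library defaults keep
the full sizes (500 trees, 10 folds).

## Known limitations

- The packaged catalog is a synthetic stand-in: real division/category
  totals, generated gene symbols.
- The whole-cohort WGCNA fallback makes the cluster track slightly more
  permissive when clustering resolves singleton subtypes; the 2-SD track
  restores specificity in the intersection.
- Train-equals-test AUC validation overstates absolute discrimination
  (by design, for fidelity); kept-set precision derives from the
  selection stages, not from this gate.
- Percentage reporting rounds half-up to one decimal; source tallies in
  the literature occasionally truncate instead, so isolated one-ulp
  differences in printed percentages are expected.
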