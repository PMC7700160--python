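# matriscope

Discovery of tumor-subtype-specific ("landmark") matrisome genes and
machine-learning reconstruction of their regulatory interactions, at desk
scale.

## The problem

The matrisome — the ~1000 genes encoding extracellular-matrix proteins,
ECM-associated proteins, ECM regulators and secreted factors — shapes the
tumor microenvironment, and individual matrisome genes can mark precise
clinical and molecular tumor subtypes. Identifying which matrisome gene
marks which subtype, and which of the many candidate regulators (copy
number, mutations, methylation, miRNAs, transcription factors, gene
programs, stromal content) explains its expression, is a multi-stage
inference problem over stacked multi-omics layers.

`matriscope` implements that inference chain as a tested, reusable Python
package, driven by a synthetic multi-omics cohort generator with planted
ground truth so every stage can be benchmarked for recovery. It is aimed
at computational biologists who want to exercise, extend or stress-test
this class of marker-mining pipeline without a terabyte of consortium
data.

## The pipeline

1. **Meta-clustering.** Samples are embedded in 2-D (t-SNE with PCA
   initialisation and size-scaled perplexity, or UMAP) and clustered with
   a Gaussian mixture whose component count is chosen by BIC; tumor
   subtypes inherit cluster labels by majority vote.
2. **Landmark selection**, two tracks intersected:
   - *Cluster level*: per subtype, an FDR-corrected Mann–Whitney U screen
     of every matrisome gene against the rest of the cohort (subtypes
     sharing the focal meta-cluster are excluded from the background,
     except in the largest cluster), cross-checked against weighted gene
     coexpression modules (signed adjacency `((1+r)/2)^β`, topological
     overlap, module eigengenes) associated with the subtype, then pruned
     by 10-fold cross-validated adaptive-lasso logistic regression.
   - *Subtype level*: each gene is fitted to a two-component Gaussian
     mixture by EM (bimodality diagnostic) and allocated to a subtype
     when the subtype mean expression ≥ cohort mean + 2 SD.
3. **Regulator inference.** For each eligible (subtype, gene) task
   (≥ 10 patients, ≥ 10 non-zero values), the gene's expression is
   regressed on the stacked regulator layers by supervised sparse
   principal-component regression (linear) and by shadow-calibrated
   random-forest regression (nonlinear); selected regressors become
   candidate (subtype, gene, regulator) triplets.
4. **Robustness filter.** Every triplet is re-tested cohort-wide in a
   logistic model {gene, regulator, gene×regulator} of subtype
   membership; triplets with ROC AUC ≥ 0.8 are kept.
5. **Prognostics.** Each landmark gene is mean-split within its subtype,
   tested by the log-rank test, and checked for age independence with a
   Cox proportional-hazards model.

## Worked example

```python
from matriscope import (CohortConfig, PipelineConfig, generate_cohort,
                        run_pipeline, make_report)

cohort = generate_cohort(CohortConfig(seed=7))   # 10 subtypes, 500 samples
config = PipelineConfig(seed=7, rfr_trees=60, rfr_cv_trees=20, rfr_folds=3,
                        rfr_permutation_repeats=1, lasso_folds=5)
bundle = run_pipeline(cohort, config)
report = make_report(bundle)
print(report["n_landmark_genes"], report["n_interactions"],
      round(bundle["interaction_summary"]["auc_mean"], 3))
print(bundle["interactions"].head(4).to_string(index=False))
```

prints

```
50 109 1.0
subtype    gene  regulator       layer source  auc  kept
   T1.a SSEC023    SSEC023         cna   both  1.0  True
   T1.a SSEC023    SSEC023 methylation   both  1.0  True
   T1.a SSEC026 PROGRAM003     program   both  1.0  True
   T1.a SSEC026      TF009          tf   both  1.0  True
```

All 50 planted markers (5 per subtype) are recovered as landmarks and all
100 planted regulator links appear among the 109 kept interactions (the
few extras are chance-correlated regressors); kept interactions validate
at mean AUC 1.0 because planted markers separate their subtype sharply.
`SSEC023` is explained by its own copy-number and methylation rows (cis
effects); `SSEC026` by a gene program and a transcription factor.

A thin CLI mirrors the library:

```bash
matriscope simulate --out cohort/ --seed 7
matriscope run --cohort cohort/ --out run1/ --seed 7
matriscope report --run-dir run1/
```

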