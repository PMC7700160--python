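"""Planted-truth recovery benchmark shared by the test suite and the
acceptance script.

Runs the full pipeline on the default synthetic cohort (five
meta-clusters, ten subtypes, 50 patients per subtype, 3 cohort-SD marker
effect, unit regulator slope) and scores the recovered landmarks and
kept interactions against the planted truth.  The fast configuration
trims the forest and embedding sizes to desk scale; cohort conditions
are never reduced.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pipeline import PipelineConfig, run_pipeline
from .simulate import CohortConfig, generate_cohort


def fast_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale pipeline settings for repeated benchmark runs."""
    return PipelineConfig(
        tsne_max_iter=350,
        lasso_folds=5,
        rfr_trees=60,
        rfr_cv_trees=20,
        rfr_folds=3,
        rfr_permutation_repeats=1,
        run_prognostics=False,
        seed=seed,
    )


def recovery_metrics(bundle: dict, truth) -> dict:
    """Recall/precision of landmarks and kept interactions vs truth."""
    found = bundle["landmarks"].pairs()
    planted = set(truth.markers)
    lm_recall = len(found & planted) / len(planted) if planted else float("nan")
    lm_precision = len(found & planted) / len(found) if found else 0.0

    kept = bundle["interactions"]
    kept_keys = {
        (r.subtype, r.gene, r.layer, r.regulator) for r in kept.itertuples()
    }
    planted_links = truth.link_pairs()
    int_recall = (
        len(kept_keys & planted_links) / len(planted_links)
        if planted_links
        else float("nan")
    )
    int_precision = (
        len(kept_keys & planted_links) / len(kept_keys) if kept_keys else 0.0
    )
    return {
        "landmark_recall": lm_recall,
        "landmark_precision": lm_precision,
        "interaction_recall": int_recall,
        "interaction_precision": int_precision,
        "n_landmarks": len(found),
        "n_kept_interactions": len(kept_keys),
    }


def run_recovery(seed: int, prognostics: bool = False) -> dict:
    """One full pipeline run on the default cohort at ``seed``."""
    cohort = generate_cohort(CohortConfig(seed=seed))
    config = fast_config(seed=seed)
    if prognostics:
        config = replace(config, run_prognostics=True)
    bundle = run_pipeline(cohort, config)
    metrics = recovery_metrics(bundle, cohort.truth)
    if prognostics and "prognostics" in bundle and len(bundle["prognostics"]):
        prog = bundle["prognostics"]
        flagged = {
            (r.subtype, r.gene) for r in prog.itertuples() if r.prognostic
        }
        planted = {(s, g) for s, g, _ in cohort.truth.prognostic}
        metrics["prognostic_recall"] = (
            len(flagged & planted) / len(planted) if planted else float("nan")
        )
    metrics["bundle"] = bundle
    metrics["truth"] = cohort.truth
    return metrics


def recovery_over_seeds(n_seeds: int, base_seed: int = 0) -> dict:
    """Mean recovery metrics over ``n_seeds`` independent cohorts."""
    keys = (
        "landmark_recall", "landmark_precision",
        "interaction_recall", "interaction_precision",
    )
    acc = {k: [] for k in keys}
    for i in range(n_seeds):
        m = run_recovery(base_seed + i)
        for k in keys:
            acc[k].append(m[k])
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["per_seed"] = {k: v for k, v in acc.items()}
    return out
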