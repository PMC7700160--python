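"""End-to-end orchestration: meta-clustering -> landmark selection ->
regulator inference -> robustness filtering -> prognostics -> summaries.

Every stage draws its randomness from a per-stage seed spawned from the
master seed, so stages are independently reproducible and the whole
bundle is idempotent under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import MatrisomeCatalog, breakdown, interaction_breakdown, \
    load_catalog, top_quartile_enrichment
from .landmarks import (
    adaptive_lasso_prune,
    cluster_level_genes,
    coexpression_modules,
    intersect_landmarks,
    mwu_screen,
    subtype_level_genes,
)
from .metacluster import assign_subtype_clusters, cluster_samples, embed_samples
from .prognosis import prognostic_scan
from .regulators import (
    RegulatorLayers,
    assemble_design,
    eligibility_filter,
    extract_triplets,
    rfr_fit,
    spcr_fit,
)
from .robustness import filter_and_summarize, validate_triplets
from .simulate import Cohort

log = logging.getLogger(__name__)

_STAGES = ("metacluster", "screen", "modules", "lasso", "spcr", "rfr", "validate")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage integer seeds (< 2^31) spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """All stage thresholds in one place; defaults are the published
    constants (min 10 patients, min 10 non-zero values, AUC >= 0.8)."""

    alpha: float = 0.05
    auc_threshold: float = 0.8
    min_patients: int = 10
    min_nonzero: int = 10
    embed_method: str = "tsne"
    tsne_max_iter: int = 750
    gmm_k_range: tuple[int, int] = (1, 10)
    lasso_folds: int = 10
    min_module_size: int = 5
    wgcna_power: int | None = None
    spcr_k_max: int = 5
    spcr_threshold_frac: float = 0.5
    spcr_cv: int = 5
    rfr_trees: int = 500
    rfr_cv_trees: int = 100
    rfr_folds: int = 10
    rfr_permutation_repeats: int = 2
    rfr_importance_floor: float = 0.1
    run_prognostics: bool = True
    seed: int = 0
    # optional precomputed subtype -> cluster assignment (bypasses clustering)
    fixed_assignment: dict[str, object] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gmm_k_range" in raw:
            raw["gmm_k_range"] = tuple(raw["gmm_k_range"])
        return cls(**raw)


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    catalog: MatrisomeCatalog | None = None,
) -> dict:
    """Execute all stages on an in-memory cohort; returns the result bundle."""
    config = config or PipelineConfig()
    catalog = catalog or load_catalog()
    seeds = stage_seeds(config.seed)
    expression, annotation, layers = (
        cohort.expression, cohort.annotation, cohort.layers,
    )
    bundle: dict = {"manifest": {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "fixed_assignment"
        },
        "stage_counts": {},
    }}
    counts = bundle["manifest"]["stage_counts"]

    def _stage(name):
        log.info("stage: %s", name)

    # --- meta-clustering -------------------------------------------------
    _stage("metacluster")
    try:
        if config.fixed_assignment is not None:
            clusters = dict(config.fixed_assignment)
            assignment = None
        else:
            emb = embed_samples(
                expression, method=config.embed_method,
                random_state=seeds["metacluster"],
                max_iter=config.tsne_max_iter,
            )
            sample_labels = cluster_samples(
                emb, method="gmm", k_range=config.gmm_k_range,
                random_state=seeds["metacluster"],
            )
            assignment = assign_subtype_clusters(sample_labels, annotation)
            clusters = assignment.labels
            bundle["embedding"] = emb
        bundle["clusters"] = clusters
        counts["n_clusters"] = len(set(clusters.values()))
    except Exception as exc:
        raise RuntimeError(f"stage metacluster failed: {exc}") from exc

    subtypes = sorted(annotation["subtype"].unique())
    cluster_of = {s: clusters[s] for s in subtypes}
    sizes = pd.Series(list(cluster_of.values())).value_counts()
    no_excl = {sizes.idxmax()}

    # --- landmark selection ---------------------------------------------
    _stage("landmarks")
    try:
        screens = {}
        for st in subtypes:
            screens[st] = mwu_screen(
                expression, annotation, cluster_of, st,
                alpha=config.alpha, no_exclusion_clusters=no_excl,
            )
        # coexpression modules are scoped to the focal cluster's samples;
        # a cluster resolving to a single subtype has no within-cluster
        # contrast, so those fall back to the whole cohort
        modules_by_cluster = {}
        scope_members: dict[object, list[str]] = {}
        whole_mods = None
        for cl in sorted(set(cluster_of.values()), key=str):
            members = [s for s, c in cluster_of.items() if c == cl]
            if len(members) < 2:
                members = subtypes
                if whole_mods is None:
                    whole_mods = coexpression_modules(
                        expression,
                        power=config.wgcna_power,
                        min_module_size=config.min_module_size,
                    )
                modules_by_cluster[cl] = whole_mods
            else:
                samples = annotation.index[annotation["subtype"].isin(members)]
                modules_by_cluster[cl] = coexpression_modules(
                    expression.loc[:, samples],
                    power=config.wgcna_power,
                    min_module_size=config.min_module_size,
                )
            scope_members[cl] = members
        cluster_sets = {}
        for st in subtypes:
            mods = modules_by_cluster[cluster_of[st]]
            members = scope_members[cluster_of[st]]
            scope = annotation.loc[annotation["subtype"].isin(members)]
            candidates = cluster_level_genes(
                screens[st], mods, scope, st, alpha=config.alpha
            )
            if candidates:
                labels = (annotation["subtype"] == st).to_numpy(int)
                cluster_sets[st] = adaptive_lasso_prune(
                    expression.loc[sorted(candidates)], labels,
                    folds=config.lasso_folds, random_state=seeds["lasso"],
                )
            else:
                cluster_sets[st] = set()
        subtype_sets = {
            st: subtype_level_genes(
                expression, annotation, st, min_samples=config.min_patients
            )
            for st in subtypes
        }
        landmark_set = intersect_landmarks(cluster_sets, subtype_sets)
        bundle["screens"] = screens
        bundle["landmarks"] = landmark_set
        counts["n_landmark_pairs"] = len(landmark_set.pairs())
    except Exception as exc:
        raise RuntimeError(f"stage landmark_selection failed: {exc}") from exc

    # --- regulator inference --------------------------------------------
    _stage("regulators")
    try:
        landmarks = landmark_set.landmarks
        tasks = eligibility_filter(
            annotation, expression, landmarks,
            min_patients=config.min_patients, min_nonzero=config.min_nonzero,
        )
        counts["n_tasks"] = len(tasks)
        spcr_results, rfr_results = {}, {}
        for i, (st, gene) in enumerate(tasks):
            try:
                X = assemble_design(layers, annotation, st, gene)
            except ValueError:
                continue
            samples = X.index
            y = expression.loc[gene, samples].to_numpy(float)
            spcr_results[(st, gene)] = spcr_fit(
                y, X, k_max=config.spcr_k_max,
                threshold_frac=config.spcr_threshold_frac, cv=config.spcr_cv,
                random_state=seeds["spcr"] + i,
            )
            rfr_results[(st, gene)] = rfr_fit(
                y, X, folds=config.rfr_folds,
                n_estimators=config.rfr_trees,
                cv_n_estimators=config.rfr_cv_trees,
                n_permutation_repeats=config.rfr_permutation_repeats,
                importance_floor_frac=config.rfr_importance_floor,
                random_state=seeds["rfr"] + i,
            )
        triplets = extract_triplets(spcr_results, rfr_results)
        bundle["triplets"] = triplets
        counts["n_triplets"] = len(triplets)
    except Exception as exc:
        raise RuntimeError(f"stage regulator_inference failed: {exc}") from exc

    # --- robustness filter ----------------------------------------------
    _stage("validate")
    try:
        validated = validate_triplets(
            triplets, expression, layers, annotation,
            threshold=config.auc_threshold,
        )
        kept, summary = filter_and_summarize(validated, catalog)
        bundle["validated"] = validated
        bundle["interactions"] = kept
        bundle["interaction_summary"] = summary
        counts["n_kept_interactions"] = len(kept)
    except Exception as exc:
        raise RuntimeError(f"stage robustness_filter failed: {exc}") from exc

    # --- prognostics ------------------------------------------------------
    if config.run_prognostics and {"time", "event", "age"} <= set(
        annotation.columns
    ):
        _stage("prognostics")
        try:
            bundle["prognostics"] = prognostic_scan(
                landmarks, expression,
                annotation[["subtype", "time", "event", "age"]],
                alpha=config.alpha,
            )
            counts["n_prognostic"] = (
                int(bundle["prognostics"]["prognostic"].sum())
                if len(bundle["prognostics"])
                else 0
            )
        except Exception as exc:
            raise RuntimeError(f"stage prognostics failed: {exc}") from exc

    # --- bookkeeping summaries -------------------------------------------
    _stage("summaries")
    landmark_genes = {g for gs in landmarks.values() for g in gs}
    bundle["landmark_breakdown"] = breakdown(landmark_genes, catalog)
    bundle["interaction_breakdown"] = interaction_breakdown(
        bundle["interactions"], catalog
    )
    bundle["top_quartile"] = top_quartile_enrichment(
        landmarks, expression, annotation
    )
    return bundle


def make_report(bundle: dict) -> dict:
    """Deterministic JSON-serialisable summary of a pipeline bundle."""
    landmarks = bundle.get("landmarks")
    pairs = sorted(landmarks.pairs()) if landmarks is not None else []
    interactions = bundle.get(
        "interactions", pd.DataFrame(columns=["subtype", "auc"])
    )
    report: dict = {
        "n_landmark_pairs": len(pairs),
        "n_landmark_genes": len({g for _, g in pairs}),
        "n_interactions": int(len(interactions)),
        "n_unique_regulators": int(interactions["regulator"].nunique())
        if len(interactions)
        else 0,
        "per_subtype_interactions": interactions.groupby("subtype")
        .size()
        .to_dict()
        if len(interactions)
        else {},
        "interaction_summary": bundle.get("interaction_summary", {}),
        "manifest": bundle.get("manifest", {}),
    }
    lb = bundle.get("landmark_breakdown")
    if lb is not None:
        report["landmark_breakdown"] = [
            {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for row in lb.to_dict("records")
        ]
    prog = bundle.get("prognostics")
    if prog is not None and len(prog):
        report["n_prognostic"] = int(prog["prognostic"].sum())
        report["n_age_independent"] = int(prog["age_independent"].sum())
    return report


def write_bundle(bundle: dict, directory: str | Path) -> None:
    """Write the TSV/JSON artifacts of a run under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    landmarks = bundle["landmarks"]
    landmarks.table.to_csv(directory / "landmarks.tsv", sep="\t", index=False)
    bundle["triplets"].to_csv(directory / "triplets.tsv", sep="\t", index=False)
    bundle["validated"].to_csv(
        directory / "interactions.tsv", sep="\t", index=False
    )
    if "prognostics" in bundle:
        bundle["prognostics"].to_csv(
            directory / "prognostics.tsv", sep="\t", index=False
        )
    report = make_report(bundle)
    (directory / "manifest.json").write_text(json.dumps(report, indent=1,
                                                        default=str))
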