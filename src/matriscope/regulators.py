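"""Regulator-layer handling and regulatory-interaction inference.

Candidate explanations for a landmark gene's expression come from stacked
information layers: transcription-factor expression, gene-program scores,
miRNA expression, gene-level methylation, copy-number alteration, binary
mutation status and the stromal fraction (1 - tumor purity).  For each
eligible (subtype, gene) task a per-gene design matrix is assembled and
two regressions are fitted independently — a supervised sparse
principal-component regression (linear) and a shadow-feature random-forest
regression (nonlinear) — whose selected regressors become candidate
(subtype, gene, regulator) triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import SparseComponentRegressor, ShadowForestSelector

#: layers whose rows are indexed by gene symbol (cis features)
GENE_INDEXED_LAYERS = frozenset({"cna", "methylation", "mutation"})

_UNIT_INTERVAL_LAYERS = frozenset({"methylation", "stromal"})


@dataclass
class RegulatorLayers:
    """Stacked regulator matrices (regulator x sample), one per layer."""

    layers: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        samples = None
        for name, frame in self.layers.items():
            if samples is None:
                samples = frame.columns
            elif not frame.columns.equals(samples):
                raise ValueError(f"layer {name!r} has a different sample axis")
            vals = frame.to_numpy(float)
            if name == "mutation" and not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("mutation layer must be 0/1")
            if name in _UNIT_INTERVAL_LAYERS and (
                (vals < 0).any() or (vals > 1).any()
            ):
                raise ValueError(f"{name} layer must lie in [0, 1]")

    @property
    def samples(self) -> pd.Index:
        return next(iter(self.layers.values())).columns

    def __iter__(self):
        return iter(self.layers.items())


@dataclass(frozen=True)
class Triplet:
    """A candidate (subtype, matrisome gene, regulator) interaction."""

    subtype: str
    gene: str
    regulator: str
    layer: str
    source: str  # "spcr" | "rfr" | "both"
    score: float

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("triplet score must be finite")
        if self.source not in {"spcr", "rfr", "both"}:
            raise ValueError(f"unknown source {self.source!r}")


def _targets_of(target_map, gene: str) -> set[str] | None:
    """Regulators annotated for ``gene`` in a two-column (regulator, target)
    map; None means no restriction."""
    if target_map is None:
        return None
    if isinstance(target_map, pd.DataFrame):
        reg_col, tgt_col = target_map.columns[:2]
        return set(target_map.loc[target_map[tgt_col] == gene, reg_col])
    # dict regulator -> iterable of targets
    return {r for r, tg in target_map.items() if gene in set(tg)}


def assemble_design(
    layers: RegulatorLayers,
    annotation: pd.DataFrame,
    subtype: str,
    gene: str,
    tf_targets=None,
    mirna_targets=None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Column-stacked regressor matrix for one (subtype, gene) task.

    Gene-indexed layers contribute the focal gene's own row; TF and miRNA
    layers are restricted to annotated regulators of the gene when a
    target map is supplied.  Constant columns are dropped; continuous
    columns are standardized (binary mutation columns stay 0/1).
    """
    samples = annotation.index[annotation["subtype"] == subtype]
    if len(samples) == 0:
        raise ValueError(f"subtype {subtype!r} has no samples")
    cols: dict[str, np.ndarray] = {}
    binary: set[str] = set()
    for name, frame in layers:
        sub = frame.loc[:, samples]
        if name in GENE_INDEXED_LAYERS:
            if gene not in sub.index:
                continue
            rows = [gene]
        elif name == "tf":
            allowed = _targets_of(tf_targets, gene)
            rows = [r for r in sub.index if allowed is None or r in allowed]
        elif name == "mirna":
            allowed = _targets_of(mirna_targets, gene)
            rows = [r for r in sub.index if allowed is None or r in allowed]
        else:
            rows = list(sub.index)
        for r in rows:
            key = f"{name}:{r}"
            cols[key] = sub.loc[r].to_numpy(float)
            if name == "mutation":
                binary.add(key)
    X = pd.DataFrame(cols, index=samples)
    keep = X.std(axis=0) > 0
    X = X.loc[:, keep]
    if X.shape[1] == 0:
        raise ValueError(
            f"no informative regressors remain for ({subtype}, {gene})"
        )
    if standardize:
        for c in X.columns:
            if c not in binary:
                X[c] = (X[c] - X[c].mean()) / X[c].std()
    return X


def eligibility_filter(
    annotation: pd.DataFrame,
    expression: pd.DataFrame,
    landmarks: dict[str, set[str]],
    min_patients: int = 10,
    min_nonzero: int = 10,
) -> list[tuple[str, str]]:
    """Modelling tasks: subtypes with >= ``min_patients`` patients and genes
    with >= ``min_nonzero`` non-zero expression values within the subtype."""
    tasks = []
    for subtype, genes in sorted(landmarks.items()):
        samples = annotation.index[annotation["subtype"] == subtype]
        if len(samples) < min_patients:
            continue
        sub = expression.loc[sorted(set(genes) & set(expression.index)), samples]
        nz = (sub != 0).sum(axis=1)
        tasks.extend((subtype, g) for g in nz.index[nz >= min_nonzero])
    return tasks


def spcr_fit(
    y: np.ndarray,
    X: pd.DataFrame,
    k_max: int = 5,
    threshold_frac: float = 0.5,
    cv: int = 5,
    random_state: int | None = None,
) -> dict[str, float]:
    """Sparse principal-component regression selections for one task.

    Returns regressor -> aggregate coefficient (loading x component
    regression weight summed over retained components); empty when the
    cross-validated component count is zero.
    """
    est = SparseComponentRegressor(
        n_components_max=k_max,
        threshold_frac=threshold_frac,
        cv=cv,
        random_state=random_state,
    )
    est.fit(X.to_numpy(float), np.asarray(y, float))
    return {
        X.columns[j]: float(est.feature_coef_[j]) for j in est.selected_idx_
    }


def rfr_fit(
    y: np.ndarray,
    X: pd.DataFrame,
    folds: int = 10,
    n_estimators: int = 500,
    cv_n_estimators: int = 100,
    n_permutation_repeats: int = 2,
    importance_floor_frac: float = 0.1,
    random_state: int | None = None,
) -> dict[str, float]:
    """Random-forest regression selections (shadow-feature criterion).

    Tasks whose ``folds``-fold CV R^2 is <= 0 yield no selections.
    """
    est = ShadowForestSelector(
        n_estimators=n_estimators,
        cv=folds,
        cv_n_estimators=cv_n_estimators,
        n_permutation_repeats=n_permutation_repeats,
        importance_floor_frac=importance_floor_frac,
        random_state=random_state,
    )
    est.fit(X.to_numpy(float), np.asarray(y, float))
    return {X.columns[j]: float(est.importances_[j]) for j in est.selected_idx_}


def extract_triplets(
    spcr_results: dict[tuple[str, str], dict[str, float]],
    rfr_results: dict[tuple[str, str], dict[str, float]],
) -> pd.DataFrame:
    """Union of sPCR and RFR selections tagged by source, stably ordered."""
    rows = []
    for task in sorted(set(spcr_results) | set(rfr_results)):
        subtype, gene = task
        s = spcr_results.get(task, {})
        r = rfr_results.get(task, {})
        for key in sorted(set(s) | set(r)):
            layer, reg = key.split(":", 1)
            if key in s and key in r:
                source, score = "both", s[key]
            elif key in s:
                source, score = "spcr", s[key]
            else:
                source, score = "rfr", r[key]
            rows.append((subtype, gene, reg, layer, source, score))
    df = pd.DataFrame(
        rows, columns=["subtype", "gene", "regulator", "layer", "source", "score"]
    )
    return df.sort_values(
        ["subtype", "gene", "layer", "regulator"], kind="stable"
    ).reset_index(drop=True)
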