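"""Pan-cancer logistic validation of candidate regulatory triplets.

Every candidate (subtype, gene, regulator) triplet is re-tested cohort
wide: a logistic model with predictors {gene expression, regulator value,
their product} is trained on all samples with the focal-subtype
membership as outcome and scored by ROC AUC on the same cohort.  Triplets
with AUC >= 0.8 ("at least 0.8", boundary inclusive) are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .catalog import MatrisomeCatalog
from .regulators import GENE_INDEXED_LAYERS, RegulatorLayers

log = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney concordance probability (ties count ½)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ValidatedInteraction:
    subtype: str
    gene: str
    regulator: str
    layer: str
    source: str
    auc: float
    coefficients: tuple[float, ...]
    kept: bool

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _regulator_values(
    layers: RegulatorLayers, layer: str, regulator: str
) -> np.ndarray | None:
    frame = layers.layers.get(layer)
    if frame is None or regulator not in frame.index:
        return None
    return frame.loc[regulator].to_numpy(float)


def triplet_logistic_auc(
    triplet,
    expression: pd.DataFrame,
    layers: RegulatorLayers,
    annotation: pd.DataFrame,
    threshold: float = 0.8,
    include_interaction: bool = True,
) -> ValidatedInteraction | None:
    """Validate one triplet cohort-wide; None when the regulator is not
    observable across the cohort (dropped with a log entry)."""
    g = expression.loc[triplet.gene].to_numpy(float)
    r = _regulator_values(layers, triplet.layer, triplet.regulator)
    if r is None:
        log.warning(
            "dropping triplet (%s, %s, %s:%s): regulator not observable "
            "cohort-wide", triplet.subtype, triplet.gene, triplet.layer,
            triplet.regulator,
        )
        return None
    y = (annotation["subtype"] == triplet.subtype).to_numpy(int)
    cols = [g, r]
    if include_interaction:
        cols.append(g * r)
    X = np.column_stack(cols)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    model = LogisticRegression(max_iter=2000).fit(X, y)
    scores = model.decision_function(X)
    a = auc(scores, y)
    return ValidatedInteraction(
        subtype=triplet.subtype,
        gene=triplet.gene,
        regulator=triplet.regulator,
        layer=triplet.layer,
        source=triplet.source,
        auc=a,
        coefficients=tuple(float(c) for c in model.coef_.ravel()),
        kept=bool(a >= threshold),
    )


def validate_triplets(
    triplets: pd.DataFrame,
    expression: pd.DataFrame,
    layers: RegulatorLayers,
    annotation: pd.DataFrame,
    threshold: float = 0.8,
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Validate every triplet row; returns the table with auc and kept."""
    rows = []
    for t in triplets.itertuples():
        v = triplet_logistic_auc(
            t, expression, layers, annotation, threshold, include_interaction
        )
        if v is not None:
            rows.append(
                (v.subtype, v.gene, v.regulator, v.layer, v.source, v.auc, v.kept)
            )
    return pd.DataFrame(
        rows,
        columns=["subtype", "gene", "regulator", "layer", "source", "auc", "kept"],
    )


def filter_and_summarize(
    validated: pd.DataFrame, catalog: MatrisomeCatalog | None = None
) -> tuple[pd.DataFrame, dict]:
    """Kept interactions (AUC >= threshold flag) plus summary tallies."""
    kept = validated.loc[validated["kept"].astype(bool)].reset_index(drop=True)
    summary: dict = {
        "n_candidates": int(len(validated)),
        "n_kept": int(len(kept)),
        "per_subtype": kept.groupby("subtype").size().to_dict(),
        "per_layer": kept.groupby("layer").size().to_dict(),
    }
    if len(kept):
        summary["auc_mean"] = float(kept["auc"].mean())
        summary["auc_min"] = float(kept["auc"].min())
        summary["auc_max"] = float(kept["auc"].max())
    if catalog is not None and len(kept):
        cats = kept["gene"].map(catalog.entries["category"])
        summary["per_category"] = cats.value_counts().to_dict()
    return kept, summary
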