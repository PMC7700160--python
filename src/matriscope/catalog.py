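"""Matrisome gene annotation and bookkeeping summaries.

The matrisome divides into the *core* matrisome (collagens, proteoglycans,
ECM glycoproteins) and *matrisome-associated* genes (ECM-affiliated
proteins, ECM regulators, secreted factors).  This module houses the
catalog container, a loader for the packaged (synthetic stand-in) catalog
or a user-supplied TSV, and the breakdown tables used to summarise
landmark-gene sets and regulatory interactions by division and category.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

CORE_CATEGORIES = frozenset({"collagens", "proteoglycans", "ECM glycoproteins"})
ASSOCIATED_CATEGORIES = frozenset(
    {"ECM-affiliated proteins", "ECM regulators", "secreted factors"}
)
CATEGORIES = tuple(sorted(CORE_CATEGORIES)) + tuple(sorted(ASSOCIATED_CATEGORIES))

_PACKAGED_CATALOG = "matrisome_catalog_synthetic.tsv"


def round_pct(k: float, n: float, decimals: int = 1) -> float:
    """Percentage 100*k/n rounded half-up to ``decimals`` places."""
    if n == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100.0 * k / n).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MatrisomeCatalog:
    """Gene symbol -> (division, category) annotation table."""

    entries: pd.DataFrame  # index: gene, columns: division, category

    def __post_init__(self) -> None:
        df = self.entries
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols in catalog: {dups[:5]}")
        bad = set(df["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown matrisome categories: {sorted(bad)}")
        expected = df["category"].map(
            lambda c: "core" if c in CORE_CATEGORIES else "associated"
        )
        mism = df.index[df["division"] != expected]
        if len(mism):
            raise ValueError(
                f"division inconsistent with category for: {list(mism[:5])}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries.index

    @property
    def genes(self) -> pd.Index:
        return self.entries.index

    def division(self, gene: str) -> str:
        return self.entries.at[gene, "division"]

    def category(self, gene: str) -> str:
        return self.entries.at[gene, "category"]


def load_catalog(path: str | Path | None = None) -> MatrisomeCatalog:
    """Load the packaged synthetic stand-in catalog, or a user TSV.

    The TSV needs columns ``gene``, ``division`` and ``category``.  The
    packaged default has exactly 1027 entries with the published
    division/category totals but synthetic gene symbols.
    """
    if path is None:
        ref = importlib.resources.files("matriscope").joinpath(
            "data", _PACKAGED_CATALOG
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty matrisome catalog: {path or _PACKAGED_CATALOG}")
    missing = {"gene", "division", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return MatrisomeCatalog(df.set_index("gene")[["division", "category"]])


def breakdown(genes, catalog: MatrisomeCatalog) -> pd.DataFrame:
    """Division and category counts/percentages for a gene set.

    Genes absent from the catalog are reported in the ``absent`` row and
    excluded from the denominator.  An empty intersection yields an
    all-zero table.
    """
    genes = pd.Index(sorted(set(genes)))
    present = genes.intersection(catalog.genes)
    n = len(present)
    sub = catalog.entries.loc[present]
    rows = []
    for div in ("core", "associated"):
        k = int((sub["division"] == div).sum())
        rows.append(("division", div, k, round_pct(k, n)))
    for cat in CATEGORIES:
        k = int((sub["category"] == cat).sum())
        rows.append(("category", cat, k, round_pct(k, n)))
    rows.append(("absent", "absent", len(genes) - n, np.nan))
    return pd.DataFrame(rows, columns=["level", "group", "count", "pct"])


def interaction_breakdown(
    triplets: pd.DataFrame, catalog: MatrisomeCatalog
) -> pd.DataFrame:
    """Per-category interaction counts overall and per tumor type.

    ``triplets`` needs columns ``subtype`` and ``gene``; the tumor type is
    the part of the subtype label before the first ``.``.
    """
    if triplets.empty:
        return pd.DataFrame(
            columns=["tumor_type", "level", "group", "count", "pct"]
        )
    t = triplets.copy()
    t["tumor_type"] = t["subtype"].astype(str).str.split(".").str[0]
    t["division"] = t["gene"].map(catalog.entries["division"])
    t["category"] = t["gene"].map(catalog.entries["category"])
    if t["division"].isna().any():
        missing = sorted(t.loc[t["division"].isna(), "gene"].unique())
        raise ValueError(f"triplet genes not in catalog: {missing[:5]}")
    out = []
    scopes = [("all", t)] + [(tt, g) for tt, g in t.groupby("tumor_type")]
    for scope, grp in scopes:
        n = len(grp)
        for div in ("core", "associated"):
            k = int((grp["division"] == div).sum())
            out.append((scope, "division", div, k, round_pct(k, n)))
        for cat in CATEGORIES:
            k = int((grp["category"] == cat).sum())
            out.append((scope, "category", cat, k, round_pct(k, n)))
    return pd.DataFrame(
        out, columns=["tumor_type", "level", "group", "count", "pct"]
    )


def top_quartile_enrichment(
    landmarks: dict[str, set[str]],
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Do landmark genes sit in the top quarter of matrisome expression?

    For each subtype with at least one landmark, genes are ranked by their
    median expression across the subtype's samples; the top quarter is the
    highest 25% of ranks.  The flag is a one-sided comparison: the fraction
    of landmark genes in the top quarter exceeds the fraction of
    non-landmark genes there.
    """
    rows = []
    for subtype, genes in landmarks.items():
        genes = set(genes) & set(expression.index)
        if not genes:
            continue
        samples = annotation.index[annotation["subtype"] == subtype]
        med = expression.loc[:, samples].median(axis=1)
        ranks = med.rank(ascending=False, method="first")
        n_top = max(1, int(np.ceil(len(med) / 4)))
        in_top = ranks <= n_top
        lm = med.index.isin(genes)
        lm_frac = float(in_top[lm].mean())
        other_frac = float(in_top[~lm].mean()) if (~lm).any() else 0.0
        rows.append(
            (subtype, len(genes), lm_frac, other_frac, lm_frac > other_frac)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subtype",
            "n_landmarks",
            "landmark_top_quartile_frac",
            "other_top_quartile_frac",
            "enriched",
        ],
    )
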