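"""Two-track landmark matrisome gene selection.

Track 1 (cluster level): per subtype, an FDR-corrected Mann-Whitney
screen of every matrisome gene against the rest of the cohort (subtypes
sharing the focal meta-cluster are removed from the background, except
for the largest cluster whose members are mutually uncorrelated), cross-
checked against weighted gene coexpression modules associated with the
subtype, then pruned by a 10-fold cross-validated adaptive-lasso logistic
regression.

Track 2 (subtype level): each gene is fitted to a two-component Gaussian
mixture (bimodality diagnostic) and allocated to a subtype when the
subtype's mean expression reaches the cohort mean + 2 SD.

Genes passing both tracks are the subtype's landmark genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .estimators import AdaptiveLassoLogistic, BimodalGaussianMixture


# ---------------------------------------------------------------- screening

def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    """Per-gene Mann-Whitney screen for one subtype."""

    subtype: str
    table: pd.DataFrame  # index gene; columns U, p, q, direction
    excluded_subtypes: tuple[str, ...]
    alpha: float = 0.05

    @property
    def significant(self) -> set[str]:
        t = self.table
        return set(t.index[(t["q"] < self.alpha) & (t["direction"] > 0)])


def mwu_screen(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    clusters: dict[str, object],
    subtype: str,
    alpha: float = 0.05,
    no_exclusion_clusters: set | None = None,
) -> ScreenResult:
    """Two-sided Mann-Whitney U of the subtype vs the remaining cohort.

    Subtypes sharing the focal subtype's meta-cluster are removed from
    the background unless the cluster is listed in
    ``no_exclusion_clusters`` (by default the largest cluster by subtype
    count, mirroring the adenomatous/sarcomatous exception).  P-values
    use the exact distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise; q-values are BH across
    genes; the significant set additionally requires the subtype median
    to exceed the background median.
    """
    focal_cluster = clusters[subtype]
    if no_exclusion_clusters is None:
        sizes = pd.Series(list(clusters.values())).value_counts()
        no_exclusion_clusters = {sizes.idxmax()}
    excluded = tuple(
        s
        for s, c in clusters.items()
        if s != subtype
        and c == focal_cluster
        and focal_cluster not in no_exclusion_clusters
    )
    sub = annotation["subtype"]
    focal_samples = annotation.index[sub == subtype]
    if len(focal_samples) < 2:
        raise ValueError(f"subtype {subtype!r} has < 2 samples")
    bg_samples = annotation.index[
        (sub != subtype) & ~sub.isin(excluded)
    ]
    if len(bg_samples) == 0:
        raise ValueError(
            f"background empty after excluding cluster {focal_cluster!r}"
        )
    x = expression.loc[:, focal_samples].to_numpy(float)
    yv = expression.loc[:, bg_samples].to_numpy(float)
    method = "auto" if min(x.shape[1], yv.shape[1]) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(
        x, yv, axis=1, alternative="two-sided", method=method
    )
    q = benjamini_hochberg(res.pvalue)
    direction = np.sign(np.median(x, axis=1) - np.median(yv, axis=1))
    table = pd.DataFrame(
        {"U": res.statistic, "p": res.pvalue, "q": q, "direction": direction},
        index=expression.index,
    )
    return ScreenResult(subtype, table, excluded, alpha)


# ------------------------------------------------------------- coexpression

@dataclass
class CoexpressionModules:
    """Weighted-coexpression modules with eigengenes.

    ``membership`` maps gene -> module label (0 = unassigned);
    ``eigengenes`` holds the first-PC score of each module per sample.
    """

    membership: pd.Series
    eigengenes: pd.DataFrame  # modules x samples
    power: int
    dropped_constant: tuple[str, ...] = ()

    def genes_in_associated_modules(
        self, annotation: pd.DataFrame, subtype: str, alpha: float = 0.05
    ) -> set[str]:
        assoc = self.subtype_association(annotation, subtype)
        good = set(assoc.index[assoc["q"] < alpha])
        return set(self.membership.index[self.membership.isin(good)])

    def subtype_association(
        self, annotation: pd.DataFrame, subtype: str
    ) -> pd.DataFrame:
        """Point-biserial eigengene/subtype-indicator correlation, BH over
        modules."""
        ind = (
            annotation.loc[self.eigengenes.columns, "subtype"] == subtype
        ).to_numpy(float)
        rows = {}
        for m in self.eigengenes.index:
            e = self.eigengenes.loc[m].to_numpy(float)
            if ind.std() == 0 or e.std() == 0:
                rows[m] = (0.0, 1.0)
                continue
            r, p = stats.pearsonr(e, ind)
            rows[m] = (r, p)
        df = pd.DataFrame(rows, index=["r", "p"]).T
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        return df


def _scale_free_r2(k: np.ndarray) -> float:
    """R^2 of log p(k) vs log k for binned connectivity."""
    k = k[k > 0]
    if k.size < 10:
        return 0.0
    hist, edges = np.histogram(k, bins=10)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = hist > 0
    if keep.sum() < 3:
        return 0.0
    lx, ly = np.log10(centers[keep]), np.log10(hist[keep] / hist.sum())
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r * r)


def coexpression_modules(
    expression: pd.DataFrame,
    power: int | None = None,
    min_module_size: int = 5,
    cut_height: float = 0.96,
) -> CoexpressionModules:
    """Signed weighted-coexpression modules on a gene x sample matrix.

    Adjacency ``((1 + cor)/2)^power`` with the power chosen as the
    smallest in 1..20 whose connectivity distribution fits a scale-free
    law with R^2 >= 0.8 (fallback 6); modules come from average-linkage
    clustering of topological-overlap dissimilarity cut at
    ``cut_height``; clusters below ``min_module_size`` stay unassigned
    (label 0).  Eigengenes are first-PC scores per module, oriented to
    correlate positively with mean module expression.
    """
    X = expression.to_numpy(float)
    sd = X.std(axis=1)
    dropped = tuple(expression.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant genes from WGCNA")
        expression = expression.loc[sd > 0]
        X = expression.to_numpy(float)
    n_genes, n_samples = X.shape
    if n_samples < 20 or n_genes < 10:
        raise ValueError("need >= 20 samples and >= 10 genes")
    cor = np.corrcoef(X)
    base = (1.0 + cor) / 2.0
    if power is None:
        power = 6
        for b in range(1, 21):
            adj = base**b
            np.fill_diagonal(adj, 0.0)
            if _scale_free_r2(adj.sum(axis=1)) >= 0.8:
                power = b
                break
    adj = base**power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    l = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (l + adj) / denom
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    diss = 0.5 * (diss + diss.T)
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height * link[:, 2].max(),
                             criterion="distance")
    membership = pd.Series(0, index=expression.index, dtype=int)
    next_label = 1
    for c in np.unique(raw):
        idx = np.flatnonzero(raw == c)
        if len(idx) >= min_module_size:
            membership.iloc[idx] = next_label
            next_label += 1
    eig = {}
    for m in range(1, next_label):
        sub = X[membership.to_numpy() == m]
        subz = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(
            axis=1, keepdims=True
        )
        u, s, vt = np.linalg.svd(subz, full_matrices=False)
        e = vt[0] * s[0]
        if np.corrcoef(e, subz.mean(axis=0))[0, 1] < 0:
            e = -e
        eig[m] = e
    eigengenes = pd.DataFrame(eig, index=expression.columns).T
    if not eigengenes.empty and (eigengenes.var(axis=1) <= 0).any():
        raise ValueError("degenerate eigengene with zero variance")
    return CoexpressionModules(membership, eigengenes, power, dropped)


def cluster_level_genes(
    screen: ScreenResult,
    modules: CoexpressionModules,
    annotation: pd.DataFrame,
    subtype: str,
    alpha: float = 0.05,
) -> set[str]:
    """Screen-significant genes that sit in a subtype-associated module."""
    in_assoc = modules.genes_in_associated_modules(annotation, subtype, alpha)
    return screen.significant & in_assoc


def adaptive_lasso_prune(
    expression: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 10,
    random_state: int | None = None,
) -> set[str]:
    """Prune candidate genes with adaptive-lasso logistic regression.

    ``expression`` is genes x samples for the candidates only; ``labels``
    flags the focal subtype's samples.  A single candidate passes through
    untested; zero-variance genes are never selected.
    """
    genes = list(expression.index)
    if len(genes) == 0:
        return set()
    if len(genes) == 1:
        return set(genes)
    X = expression.T.to_numpy(float)
    y = np.asarray(labels).astype(int)
    est = AdaptiveLassoLogistic(cv=folds, random_state=random_state).fit(X, y)
    return {g for g, keep in zip(genes, est.get_support()) if keep}


# ------------------------------------------------------------ subtype track

@dataclass
class BimodalFit:
    """Two-component fit of one gene plus the cohort mean/SD."""

    gene: str
    means: tuple[float, float]
    sds: tuple[float, float]
    weight: float  # mixing weight of the upper component
    log_likelihood: float
    n_iter: int
    converged: bool
    cohort_mean: float
    cohort_sd: float

    @property
    def separation(self) -> float:
        """(mu2 - mu1) / pooled SD — a bimodality diagnostic."""
        pooled = np.sqrt(0.5 * (self.sds[0] ** 2 + self.sds[1] ** 2))
        return (self.means[1] - self.means[0]) / pooled


def fit_bimodal(values, gene: str = "") -> BimodalFit:
    """EM fit of a two-component univariate normal mixture to one gene."""
    x = np.asarray(values, float).ravel()
    est = BimodalGaussianMixture().fit(x)
    return BimodalFit(
        gene=gene,
        means=(float(est.means_[0]), float(est.means_[1])),
        sds=(float(est.sds_[0]), float(est.sds_[1])),
        weight=float(est.weights_[1]),
        log_likelihood=float(est.log_likelihood_),
        n_iter=est.n_iter_,
        converged=est.converged_,
        cohort_mean=float(x.mean()),
        cohort_sd=float(x.std()),
    )


def two_sd_select(
    gene: str,
    subtype: str,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    min_samples: int = 10,
) -> bool:
    """Allocate ``gene`` to ``subtype`` iff the subtype mean expression is
    >= cohort mean + 2 cohort SD ("equal or bigger").

    A constant gene (SD = 0) is degenerate and selected only when the
    subtype mean strictly exceeds the cohort mean.
    """
    samples = annotation.index[annotation["subtype"] == subtype]
    if len(samples) < min_samples:
        return False
    v = expression.loc[gene].to_numpy(float)
    m, s = v.mean(), v.std()
    sub_mean = expression.loc[gene, samples].mean()
    if s == 0:
        return bool(sub_mean > m)
    return bool(sub_mean >= m + 2.0 * s)


def subtype_level_genes(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    subtype: str,
    min_samples: int = 10,
) -> set[str]:
    """Vectorised mean + 2SD allocation for every gene at once."""
    samples = annotation.index[annotation["subtype"] == subtype]
    if len(samples) < min_samples:
        return set()
    v = expression.to_numpy(float)
    m = v.mean(axis=1)
    s = v.std(axis=1)
    sub_mean = expression.loc[:, samples].to_numpy(float).mean(axis=1)
    sel = np.where(s == 0, sub_mean > m, sub_mean >= m + 2.0 * s)
    return set(expression.index[sel])


# ------------------------------------------------------------- intersection

@dataclass
class LandmarkSet:
    """Per-subtype landmark genes with selection provenance."""

    table: pd.DataFrame  # columns subtype, gene, cluster_pass, subtype_pass

    @property
    def landmarks(self) -> dict[str, set[str]]:
        t = self.table[self.table["cluster_pass"] & self.table["subtype_pass"]]
        return {
            str(s): set(g["gene"]) for s, g in t.groupby("subtype")
        }

    def pairs(self) -> set[tuple[str, str]]:
        return {
            (r.subtype, r.gene)
            for r in self.table.itertuples()
            if r.cluster_pass and r.subtype_pass
        }


def intersect_landmarks(
    cluster_sets: dict[str, set[str]], subtype_sets: dict[str, set[str]]
) -> LandmarkSet:
    """Landmarks are genes passing both the cluster and subtype tracks."""
    rows = []
    for subtype in sorted(set(cluster_sets) | set(subtype_sets)):
        cs = cluster_sets.get(subtype, set())
        ss = subtype_sets.get(subtype, set())
        for gene in sorted(cs | ss):
            rows.append((subtype, gene, gene in cs, gene in ss))
    return LandmarkSet(
        pd.DataFrame(
            rows, columns=["subtype", "gene", "cluster_pass", "subtype_pass"]
        )
    )
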