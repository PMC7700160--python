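"""Meta-clustering of tumor samples on matrisome expression.

Samples are embedded in 2-D (t-SNE with PCA initialization and
sample-size-scaled perplexity/learning rate, or UMAP) and clustered with
a Gaussian mixture whose component count is chosen by BIC; subtypes are
then assigned to meta-clusters by majority vote of their samples.  GMM
labels are authoritative; a density-based clustering is available as an
agreement diagnostic.  A precomputed subtype -> cluster table may be
supplied downstream to bypass clustering entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture


@dataclass
class MetaclusterAssignment:
    """Subtype -> meta-cluster labels with provenance and agreement."""

    labels: dict[str, int]
    method: str
    agreement: dict[str, float]  # majority fraction per subtype

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subtype": list(self.labels),
                "cluster": list(self.labels.values()),
                "agreement": [self.agreement[s] for s in self.labels],
            }
        )


def embed_samples(
    expression: pd.DataFrame,
    method: str = "tsne",
    random_state: int | None = 0,
    perplexity: float | None = None,
    max_iter: int = 750,
    n_pca: int = 50,
) -> pd.DataFrame:
    """2-D embedding of samples (columns of ``expression``).

    t-SNE follows the large-dataset recommendations: PCA initialization,
    perplexity ~ n/100 bounded to [30, 500] (and below the sample-count
    ceiling), learning rate n/12.
    """
    n = expression.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples to embed")
    X = expression.T.to_numpy(float)
    X = X - X.mean(axis=0)
    if method == "tsne":
        if perplexity is None:
            perplexity = min(max(n / 100.0, 30.0), 500.0, (n - 1) / 3.0)
        if perplexity >= n:
            raise ValueError(
                f"perplexity ({perplexity}) must be < n samples ({n}); "
                "lower it or supply more samples"
            )
        if X.shape[1] > n_pca:
            X = PCA(n_components=n_pca, random_state=random_state).fit_transform(X)
        emb = TSNE(
            n_components=2,
            init="pca",
            perplexity=perplexity,
            learning_rate=max(n / 12.0, 50.0),
            max_iter=max_iter,
            random_state=random_state,
        ).fit_transform(X)
    elif method == "umap":
        import umap

        emb = umap.UMAP(
            n_components=2, random_state=random_state
        ).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=expression.columns, columns=["dim1", "dim2"])


def cluster_samples(
    embedding: pd.DataFrame,
    method: str = "gmm",
    k_range: tuple[int, int] = (1, 10),
    random_state: int | None = 0,
) -> pd.Series:
    """Cluster samples on an embedding (or any sample x feature table).

    ``gmm`` fits Gaussian mixtures over ``k_range`` components and keeps
    the BIC-minimising model; ``density`` runs HDBSCAN (noise points are
    attached to the nearest cluster mean).
    """
    X = embedding.to_numpy(float)
    if method == "gmm":
        best, best_bic = None, np.inf
        for k in range(k_range[0], min(k_range[1], len(X)) + 1):
            gm = GaussianMixture(
                n_components=k, n_init=3, random_state=random_state
            ).fit(X)
            bic = gm.bic(X)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        labels = best.predict(X)
    elif method == "density":
        from sklearn.cluster import HDBSCAN

        labels = HDBSCAN(min_cluster_size=max(5, len(X) // 50)).fit_predict(X)
        if (labels == -1).any() and (labels != -1).any():
            means = {
                c: X[labels == c].mean(axis=0) for c in np.unique(labels[labels != -1])
            }
            for i in np.flatnonzero(labels == -1):
                labels[i] = min(
                    means, key=lambda c: np.linalg.norm(X[i] - means[c])
                )
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=embedding.index, name="cluster")


def assign_subtype_clusters(
    sample_labels: pd.Series, annotation: pd.DataFrame, method: str = "gmm"
) -> MetaclusterAssignment:
    """Majority-vote subtype labels; ties break to the lowest cluster index."""
    if sample_labels.isna().any():
        raise ValueError("every sample must carry a cluster label")
    labels: dict[str, int] = {}
    agreement: dict[str, float] = {}
    for subtype, samples in annotation.groupby("subtype").groups.items():
        counts = sample_labels.loc[samples].value_counts()
        top = counts.max()
        winner = min(int(c) for c in counts.index[counts == top])
        labels[str(subtype)] = winner
        agreement[str(subtype)] = float(top / counts.sum())
    return MetaclusterAssignment(labels=labels, method=method, agreement=agreement)


def clustering_agreement(a: pd.Series, b: pd.Series) -> float:
    """Adjusted Rand index between two sample partitions."""
    common = a.index.intersection(b.index)
    return float(adjusted_rand_score(a.loc[common], b.loc[common]))
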