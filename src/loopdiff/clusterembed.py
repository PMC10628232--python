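"""Sample-level clustering and 2-D embedding of contact profiles.

Balanced contact matrices (typically 100-kb resolution, bounded separation)
become per-sample feature vectors over a shared bin-pair universe; rows can
be K-means clustered, samples hierarchically clustered on correlation
distance with average linkage, or embedded in 2-D with t-SNE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from loopdiff.contacts import ContactMatrix
from loopdiff.diffint import enumerate_universe

__all__ = [
    "contact_feature_vectors",
    "kmeans_rows",
    "hcluster_samples",
    "embed_samples",
]


def contact_feature_vectors(
    matrices: dict[str, ContactMatrix],
    max_sep: int = 10_000_000,
    target_sum: float = 1e6,
) -> pd.DataFrame:
    """Per-sample balanced contact vectors over the shared bin-pair universe.

    Each column is depth-normalized to sum to ``target_sum``. Matrices must
    be balanced and share layout and resolution.
    """
    samples = list(matrices)
    first = matrices[samples[0]]
    for s in samples[1:]:
        if (
            matrices[s].layout != first.layout
            or matrices[s].resolution != first.resolution
        ):
            raise ValueError("matrices have mixed layouts or resolutions")
    universe = enumerate_universe(first.layout, first.resolution, max_sep)
    cols = {}
    for s in samples:
        m = matrices[s]
        if not m.balanced:
            raise ValueError(f"matrix {s!r} is not balanced")
        vals = m.balanced_values()
        ser = pd.Series(
            vals,
            index=pd.MultiIndex.from_arrays(
                [m.pixels["chrom"], m.pixels["bin1"], m.pixels["bin2"]],
                names=["chrom", "bin1", "bin2"],
            ),
        )
        v = ser.reindex(universe).fillna(0.0)
        total = v.sum()
        if total <= 0:
            raise ValueError(f"matrix {s!r} has zero balanced mass")
        cols[s] = v * (target_sum / total)
    return pd.DataFrame(cols)


def kmeans_rows(
    profile: pd.DataFrame, k: int = 10, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, float]:
    """K-means over bin-pair rows; returns (labels, inertia)."""
    if k > len(profile):
        raise ValueError("K exceeds the number of rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(profile.values)
    return pd.Series(labels, index=profile.index, name="cluster"), float(km.inertia_)


def hcluster_samples(profile: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree of samples on 1 - Pearson correlation distance."""
    if profile.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    stds = profile.std(axis=0, ddof=0)
    if (stds == 0).any():
        bad = list(stds.index[stds == 0])
        raise ValueError(f"constant contact profile for samples {bad}")
    corr = np.corrcoef(profile.values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


def embed_samples(
    profile: pd.DataFrame, perplexity: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """t-SNE embedding of samples; deterministic given seed."""
    n = profile.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples to embed")
    if perplexity >= n:
        raise ValueError("perplexity must be below the number of samples")
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    )
    coords = ts.fit_transform(profile.values.T.astype(np.float64))
    return pd.DataFrame(coords, index=profile.columns, columns=["tsne1", "tsne2"])
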