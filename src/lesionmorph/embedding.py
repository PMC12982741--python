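"""Standardization, 2-D embedding and agglomerative clustering.

The morphological map is a t-SNE embedding of the standardized feature
table; morphological clusters come from hierarchical agglomeration of the
embedded (or raw standardized) coordinates. The embedding is treated as a
contract — deterministic under a fixed seed, locality-preserving for
well-separated structure — rather than as re-implemented machinery; it is
backed by scikit-learn's exact/Barnes-Hut t-SNE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.manifold import TSNE

from .errors import ParameterError
from .features import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "Partition",
    "standardize_impute",
    "embed",
    "agglomerative_cluster",
    "DEFAULT_EMBEDDING_PARAMS",
]

DEFAULT_EMBEDDING_PARAMS = {"perplexity": 30.0, "max_iter": 1000, "init": "pca"}

VALID_LINKAGES = ("ward", "complete", "average", "single")


@dataclass
class Embedding:
    """2-D coordinates for each lesion, plus the parameters that made them."""

    lesion_ids: list[str]
    coords: np.ndarray
    params_used: dict
    seed: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.lesion_ids), 2):
            raise ParameterError("embedding coords must be (n_lesions, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("embedding produced non-finite coordinates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lesion_id": self.lesion_ids, "dim1": self.coords[:, 0], "dim2": self.coords[:, 1]}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass
class Partition:
    """Cluster label per lesion."""

    lesion_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (len(self.lesion_ids),):
            raise ParameterError("partition labels must align with lesion ids")

    @property
    def k(self) -> int:
        return int(np.unique(self.labels).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lesion_id": self.lesion_ids, "cluster": self.labels})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def standardize_impute(table: FeatureTable) -> FeatureTable:
    """Median-impute missing values, then z-score every feature column.

    The per-feature median is computed before standardization; all-missing
    and zero-variance columns carry no information for clustering and are
    dropped with a logged warning. Remaining columns have mean 0, SD 1.
    """
    if len(table.lesion_ids) < 2:
        raise ParameterError("standardization needs at least two lesions")
    values = table.values.copy()
    n_col = values.shape[1]
    keep = np.ones(n_col, dtype=bool)
    for j in range(n_col):
        col = values[:, j]
        missing = ~np.isfinite(col)
        if missing.all():
            keep[j] = False
            continue
        if missing.any():
            col[missing] = np.median(col[~missing])
            values[:, j] = col
        sd = col.std()
        if sd == 0:
            keep[j] = False
            continue
        values[:, j] = (col - col.mean()) / sd
    dropped = [m.name for m, k in zip(table.metas, keep) if not k]
    if dropped:
        log.warning("standardize_impute: dropped %d uninformative columns: %s",
                    len(dropped), ", ".join(dropped[:8]) + ("..." if len(dropped) > 8 else ""))
    if not keep.any():
        raise ParameterError("no informative feature columns remain")
    return FeatureTable(
        lesion_ids=list(table.lesion_ids),
        metas=[m for m, k in zip(table.metas, keep) if k],
        values=values[:, keep],
    )


def embed(table: FeatureTable, params: dict | None = None, seed: int = 0) -> Embedding:
    """t-SNE embedding of a standardized feature table into 2-D.

    Deterministic for a fixed ``seed`` and parameter set. Raises
    :class:`ParameterError` when the cohort is smaller than the perplexity
    allows.
    """
    p = dict(DEFAULT_EMBEDDING_PARAMS)
    if params:
        p.update(params)
    n = len(table.lesion_ids)
    if n <= p["perplexity"]:
        raise ParameterError(
            f"perplexity {p['perplexity']} requires more than {p['perplexity']:.0f} lesions, got {n}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=float(p["perplexity"]),
        max_iter=int(p["max_iter"]),
        init=p["init"],
        random_state=int(seed),
    )
    coords = tsne.fit_transform(table.values)
    return Embedding(lesion_ids=list(table.lesion_ids), coords=coords, params_used=p, seed=seed)


def agglomerative_cluster(
    points: np.ndarray,
    k: int,
    linkage: str = "ward",
    metric: str = "euclidean",
    lesion_ids: list[str] | None = None,
) -> Partition:
    """Bottom-up hierarchical clustering cut at ``k`` clusters.

    Repeatedly merges the two least-distant clusters under the linkage rule.
    Ward linkage requires the Euclidean metric. Deterministic for a given
    input order (distance ties break by the backend's fixed merge order).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ParameterError("points must be a 2-D array (n_samples, n_dims)")
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} out of range for n={n}")
    if linkage not in VALID_LINKAGES:
        raise ParameterError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ParameterError("ward linkage requires the Euclidean metric")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        z = scipy_linkage(x, method=linkage, metric=metric)
        labels = fcluster(z, t=k, criterion="maxclust")
    ids = lesion_ids if lesion_ids is not None else [str(i) for i in range(n)]
    return Partition(lesion_ids=list(ids), labels=labels)
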