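"""Concordance statistics: adjusted Rand index, silhouette, bootstrap inference.

These are the quantities the morphology-vs-ground-truth comparison rests on, so
they are implemented here from their definitions rather than delegated:

* :func:`adjusted_rand_index` follows the Hubert–Arabie chance-corrected form
  ``(Index - E[Index]) / (Max - E[Index])`` computed from the contingency table
  of the two labelings.
* :func:`silhouette` is the plain Rousseeuw mean of ``(b - a)/max(a, b)`` with
  Euclidean distances and the usual ``s = 0`` convention for singleton clusters.
* :func:`bootstrap_concordance` resamples lesions with replacement and
  recomputes both ARIs on each draw (paired: one index draw serves both
  labelings), yielding means, percentile CIs and a one-sided add-one p-value
  for "concordance with labeling B exceeds labeling A".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "adjusted_rand_index",
    "silhouette",
    "bootstrap_concordance",
    "bootstrap_concordance_refit",
    "contingency",
    "ConcordanceResult",
    "ContingencyTable",
]


def _comb2(x):
    """Number of unordered pairs, elementwise: C(x, 2)."""
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Returns 1.0 for identical partitions, ~0 for independent ones. When the
    normalizer vanishes (``Max == E[Index]``, e.g. both labelings put every
    item in one class, or both are all-singletons) the index is defined as 0.

    Parameters
    ----------
    labels_a, labels_b : array-like of shape (n,)
        Cluster/class labels; any hashable dtype. Label names are irrelevant,
        only the induced partition matters.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.ndim != 1 or a.shape != b.shape:
        raise ParameterError(
            f"label vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    n = a.size
    if n < 2:
        raise ParameterError("ARI needs at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n_b = int(bi.max()) + 1
    cont = np.bincount(ai * n_b + bi, minlength=(int(ai.max()) + 1) * n_b)
    cont = cont.reshape(-1, n_b)
    index = _comb2(cont).sum()
    sum_a = _comb2(cont.sum(axis=1)).sum()
    sum_b = _comb2(cont.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 0.0
    return float((index - expected) / (max_index - expected))


def silhouette(points, labels) -> float:
    """Mean silhouette width of a partition in Euclidean coordinate space.

    For each point, ``a`` is its mean distance to the other members of its own
    cluster and ``b`` the smallest mean distance to the members of another
    cluster; the width is ``(b - a) / max(a, b)``, 0 for points in singleton
    clusters. Raises :class:`ParameterError` if fewer than two clusters.
    """
    x = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != lab.shape[0]:
        raise ParameterError("points must be (n, d) aligned with labels")
    uniq, inv = np.unique(lab, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ParameterError("silhouette needs at least two clusters")
    n = x.shape[0]
    d = cdist(x, x)
    sizes = np.bincount(inv, minlength=k)
    # mean distance from each point to each cluster
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = d[:, inv == c].sum(axis=1)
    own = inv
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a_i = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, c2] / sizes[c2] for c2 in range(k) if c2 != c]
        b_i = min(other)
        s[i] = 0.0 if max(a_i, b_i) == 0 else (b_i - a_i) / max(a_i, b_i)
    return float(s.mean())


@dataclass
class ConcordanceResult:
    """Paired bootstrap comparison of cluster concordance with two labelings.

    Labeling A is conventionally the tumor type (lineage) and labeling B the
    anatomical environment; ``p_value`` tests H1: concordance with B exceeds A.
    """

    ari_a_boot: np.ndarray
    ari_b_boot: np.ndarray
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    mean_diff: float
    ci_diff: tuple[float, float]
    p_value: float
    ari_a_full: float
    ari_b_full: float
    n_boot: int
    seed: int
    label_a: str = "tumor_type"
    label_b: str = "environment"
    n_degenerate: int = 0

    def to_dict(self, include_vectors: bool = True) -> dict:
        d = {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "ci_a": list(self.ci_a),
            "ci_b": list(self.ci_b),
            "mean_diff": self.mean_diff,
            "ci_diff": list(self.ci_diff),
            "p_value": self.p_value,
            "ari_a_full": self.ari_a_full,
            "ari_b_full": self.ari_b_full,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
        }
        if include_vectors:
            d["ari_a_boot"] = [float(v) for v in self.ari_a_boot]
            d["ari_b_boot"] = [float(v) for v in self.ari_b_boot]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def bootstrap_concordance(
    partition_labels,
    labels_a,
    labels_b,
    n_boot: int = 100,
    seed: int = 0,
    label_a: str = "tumor_type",
    label_b: str = "environment",
) -> ConcordanceResult:
    """Bootstrap ARI distributions of a fixed partition against two labelings.

    Each replicate draws ``n`` lesion indices with replacement; the SAME draw
    resamples the partition and both ground-truth labelings, so the difference
    ``ARI_B - ARI_A`` is a paired comparison. The one-sided p-value uses the
    finite-B add-one rule ``(1 + #{diff <= 0}) / (B + 1)`` and is therefore
    bounded below by ``1/(B+1)``.
    """
    part = np.asarray(partition_labels)
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if not (part.shape == a.shape == b.shape) or part.ndim != 1:
        raise ParameterError("partition and label vectors must be aligned 1-D arrays")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    n = part.size
    rng = np.random.default_rng(seed)
    ari_a = np.empty(n_boot)
    ari_b = np.empty(n_boot)
    n_degen = 0
    for rep in range(n_boot):
        idx = rng.integers(0, n, size=n)
        p_r = part[idx]
        if np.unique(p_r).size < 2:
            n_degen += 1
        ari_a[rep] = adjusted_rand_index(p_r, a[idx])
        ari_b[rep] = adjusted_rand_index(p_r, b[idx])
    if n_degen:
        log.warning("bootstrap: %d/%d replicates had a single-cluster resample", n_degen, n_boot)
    diff = ari_b - ari_a
    p = (1.0 + int(np.sum(diff <= 0))) / (n_boot + 1.0)
    ci = lambda v: tuple(float(q) for q in np.percentile(v, [2.5, 97.5]))
    return ConcordanceResult(
        ari_a_boot=ari_a,
        ari_b_boot=ari_b,
        mean_a=float(ari_a.mean()),
        mean_b=float(ari_b.mean()),
        ci_a=ci(ari_a),
        ci_b=ci(ari_b),
        mean_diff=float(diff.mean()),
        ci_diff=ci(diff),
        p_value=float(p),
        ari_a_full=adjusted_rand_index(part, a),
        ari_b_full=adjusted_rand_index(part, b),
        n_boot=n_boot,
        seed=seed,
        label_a=label_a,
        label_b=label_b,
        n_degenerate=n_degen,
    )


def bootstrap_concordance_refit(
    points,
    labels_a,
    labels_b,
    cluster_fn,
    n_boot: int = 100,
    seed: int = 0,
    label_a: str = "tumor_type",
    label_b: str = "environment",
) -> ConcordanceResult:
    """Sensitivity variant: re-cluster each bootstrap resample.

    Instead of resampling a fixed partition, each replicate re-runs
    ``cluster_fn`` (e.g. agglomerative clustering at the selected
    hyperparameters) on the resampled coordinate rows before computing both
    ARIs. The full-data ARIs use ``cluster_fn`` on the original points.
    """
    pts = np.asarray(points, dtype=float)
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if pts.shape[0] != a.shape[0] or a.shape != b.shape:
        raise ParameterError("points and label vectors must be aligned")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    n = pts.shape[0]
    rng = np.random.default_rng(seed)
    ari_a = np.empty(n_boot)
    ari_b = np.empty(n_boot)
    n_degen = 0
    for rep in range(n_boot):
        idx = rng.integers(0, n, size=n)
        labels = np.asarray(cluster_fn(pts[idx]))
        if np.unique(labels).size < 2:
            n_degen += 1
        ari_a[rep] = adjusted_rand_index(labels, a[idx])
        ari_b[rep] = adjusted_rand_index(labels, b[idx])
    full = np.asarray(cluster_fn(pts))
    diff = ari_b - ari_a
    p = (1.0 + int(np.sum(diff <= 0))) / (n_boot + 1.0)
    ci = lambda v: tuple(float(q) for q in np.percentile(v, [2.5, 97.5]))
    return ConcordanceResult(
        ari_a_boot=ari_a,
        ari_b_boot=ari_b,
        mean_a=float(ari_a.mean()),
        mean_b=float(ari_b.mean()),
        ci_a=ci(ari_a),
        ci_b=ci(ari_b),
        mean_diff=float(diff.mean()),
        ci_diff=ci(diff),
        p_value=float(p),
        ari_a_full=adjusted_rand_index(full, a),
        ari_b_full=adjusted_rand_index(full, b),
        n_boot=n_boot,
        seed=seed,
        label_a=label_a,
        label_b=label_b,
        n_degenerate=n_degen,
    )


@dataclass
class ContingencyTable:
    """Cluster x ground-truth cross-tabulation with a row-percentage view.

    Rows are ground-truth classes, columns are clusters; ``row_percent``
    normalizes each ground-truth class across clusters (rows sum to 100).
    """

    counts: pd.DataFrame
    row_percent: pd.DataFrame = field(init=False)

    def __post_init__(self):
        totals = self.counts.sum(axis=1)
        self.row_percent = self.counts.div(totals.replace(0, np.nan), axis=0) * 100.0
        self.row_percent = self.row_percent.fillna(0.0)

    @property
    def n(self) -> int:
        return int(self.counts.values.sum())


def contingency(partition_labels, gt_labels) -> ContingencyTable:
    """Cross-tabulate a clustering against a ground-truth labeling."""
    part = np.asarray(partition_labels)
    gt = np.asarray(gt_labels)
    if part.shape != gt.shape or part.ndim != 1:
        raise ParameterError("partition and labels must be aligned 1-D arrays")
    counts = pd.crosstab(pd.Series(gt, name="ground_truth"), pd.Series(part, name="cluster"))
    return ContingencyTable(counts=counts)
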