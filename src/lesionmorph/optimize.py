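"""Bayesian optimization of clustering hyperparameters.

The model-selection objective weights internal cluster quality and agreement
with ground truth equally:

    objective = 0.5 * silhouette(points, partition) + 0.5 * ARI(partition, gt)

where the ARI term can target the tumor-type labeling, the environment
labeling, or (default) the mean of both — the symmetric choice that does not
bake either endpoint into model selection.

The search runs over a discrete space (k x linkage x metric) with a
Gaussian-process surrogate (Matern 5/2) and expected improvement. When the
evaluation budget covers the whole space the search reduces to exhaustive
enumeration; candidates are never re-evaluated. Everything is seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .embedding import Embedding, Partition, VALID_LINKAGES, agglomerative_cluster
from .errors import ParameterError
from .features import FeatureTable
from .stats import adjusted_rand_index, silhouette

__all__ = ["ClusteringSearchSpace", "optimize_clustering", "cluster_raw_features"]

ARI_MODES = ("tumor_type", "environment", "mean")


@dataclass
class ClusteringSearchSpace:
    """Discrete hyperparameter space for agglomerative clustering."""

    k_range: tuple[int, int] = (2, 15)
    linkage_options: tuple[str, ...] = ("ward", "complete", "average")
    metric_options: tuple[str, ...] = ("euclidean",)
    budget: int = 50
    seed: int = 0

    def candidates(self, n_samples: int) -> list[tuple[int, str, str]]:
        k_lo, k_hi = self.k_range
        k_lo = max(2, k_lo)
        k_hi = min(k_hi, n_samples - 1)
        if k_hi < k_lo:
            raise ParameterError(f"k_range {self.k_range} infeasible for n={n_samples}")
        bad = set(self.linkage_options) - set(VALID_LINKAGES)
        if bad:
            raise ParameterError(f"unknown linkages: {bad}")
        cands = []
        for k in range(k_lo, k_hi + 1):
            for link in self.linkage_options:
                for metric in self.metric_options:
                    if link == "ward" and metric != "euclidean":
                        continue
                    cands.append((k, link, metric))
        if not cands:
            raise ParameterError("clustering search space is empty")
        return cands


def _encode(cands: list[tuple[int, str, str]]) -> np.ndarray:
    ks = np.array([c[0] for c in cands], dtype=float)
    k_span = ks.max() - ks.min() or 1.0
    links = sorted({c[1] for c in cands})
    metrics = sorted({c[2] for c in cands})
    x = np.zeros((len(cands), 1 + len(links) + len(metrics)))
    x[:, 0] = (ks - ks.min()) / k_span
    for i, c in enumerate(cands):
        x[i, 1 + links.index(c[1])] = 1.0
        x[i, 1 + len(links) + metrics.index(c[2])] = 1.0
    return x


def _gt_term(labels: np.ndarray, gt: dict[str, np.ndarray], ari_mode: str) -> float:
    if ari_mode == "mean":
        return float(np.mean([adjusted_rand_index(labels, g) for g in gt.values()]))
    return adjusted_rand_index(labels, gt[ari_mode])


def optimize_clustering(
    embedding: Embedding,
    gt_labels: dict[str, np.ndarray] | np.ndarray,
    space: ClusteringSearchSpace | None = None,
    ari_mode: str = "mean",
) -> tuple[Partition, dict, pd.DataFrame]:
    """Pick clustering hyperparameters maximizing the equal-weight objective.

    Parameters
    ----------
    embedding : Embedding
        2-D coordinates (or any point set wrapped in an Embedding).
    gt_labels : dict or array
        Ground-truth labelings aligned to the embedding rows. A dict may hold
        both ``tumor_type`` and ``environment``; ``ari_mode`` selects which
        enters the ARI term (``"mean"`` averages over all supplied labelings).

    Returns ``(best_partition, best_params, trace)`` where the trace records
    every evaluated configuration with its silhouette, ARI term and objective.
    """
    return _optimize_points(embedding.coords, embedding.lesion_ids, gt_labels,
                            space=space, ari_mode=ari_mode)


def _optimize_points(points, lesion_ids, gt_labels, space, ari_mode):
    space = space or ClusteringSearchSpace()
    if space.budget < 1:
        raise ParameterError("optimization budget must be >= 1")
    if ari_mode not in ARI_MODES:
        raise ParameterError(f"ari_mode must be one of {ARI_MODES}")
    if isinstance(gt_labels, dict):
        gt = {k: np.asarray(v) for k, v in gt_labels.items()}
    else:
        gt = {"ground_truth": np.asarray(gt_labels)}
        ari_mode = "mean"
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    for name, g in gt.items():
        if g.shape != (n,):
            raise ParameterError(f"ground truth {name!r} not aligned with embedding rows")

    cands = space.candidates(n)
    x_all = _encode(cands)
    rng = np.random.default_rng(space.seed)
    budget = min(space.budget, len(cands))

    evaluated: list[int] = []
    results: list[tuple[float, float, float, Partition]] = []

    def _evaluate(ci: int):
        k, link, metric = cands[ci]
        part = agglomerative_cluster(points, k, link, metric, lesion_ids=lesion_ids)
        if part.k < 2:
            sil, ari, obj = -1.0, 0.0, -1.0
        else:
            sil = silhouette(points, part.labels)
            ari = _gt_term(part.labels, gt, ari_mode)
            obj = 0.5 * sil + 0.5 * ari
        evaluated.append(ci)
        results.append((sil, ari, obj, part))

    if budget >= len(cands):
        for ci in range(len(cands)):
            _evaluate(ci)
    else:
        n_init = min(max(4, budget // 4), budget)
        for ci in rng.choice(len(cands), size=n_init, replace=False):
            _evaluate(int(ci))
        while len(evaluated) < budget:
            y = np.array([r[2] for r in results])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp = GaussianProcessRegressor(
                    kernel=Matern(nu=2.5), alpha=1e-6, normalize_y=True,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                gp.fit(x_all[evaluated], y)
            remaining = np.setdiff1d(np.arange(len(cands)), np.array(evaluated))
            mu, sd = gp.predict(x_all[remaining], return_std=True)
            best = y.max()
            sd = np.maximum(sd, 1e-12)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            _evaluate(int(remaining[int(np.argmax(ei))]))

    objs = np.array([r[2] for r in results])
    best_i = int(np.argmax(objs))
    sil, ari, obj, best_part = results[best_i]
    k, link, metric = cands[evaluated[best_i]]
    best_params = {"k": k, "linkage": link, "metric": metric,
                   "silhouette": sil, "ari_term": ari, "objective": obj,
                   "ari_mode": ari_mode}
    trace = pd.DataFrame(
        [
            (cands[ci][0], cands[ci][1], cands[ci][2], r[0], r[1], r[2])
            for ci, r in zip(evaluated, results)
        ],
        columns=["k", "linkage", "metric", "silhouette", "ari_term", "objective"],
    )
    return best_part, best_params, trace


def cluster_raw_features(
    table: FeatureTable,
    gt_labels: dict[str, np.ndarray] | np.ndarray,
    space: ClusteringSearchSpace | None = None,
    ari_mode: str = "mean",
) -> tuple[Partition, dict, pd.DataFrame]:
    """Run the same optimized clustering directly on standardized features.

    No embedding step: distances are Euclidean in the standardized feature
    space; determinism follows from the search-space seed alone.
    """
    return _optimize_points(table.values, list(table.lesion_ids), gt_labels,
                            space=space, ari_mode=ari_mode)
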