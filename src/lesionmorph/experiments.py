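"""The experiment grid: lesion-subset x feature-class x mask-variant runs.

One :class:`ExperimentSpec` fully determines one analysis cell:

    cohort -> extract features (full or eroded masks) -> subset lesions
    (all / metastatic / solid-organ) -> subset features (all / shape /
    intensity / texture) -> standardize + impute -> represent (t-SNE
    embedding or raw feature vectors) -> Bayesian-optimized agglomerative
    clustering -> paired bootstrap ARI concordance against both ground
    truths -> contingency tables.

:func:`run_grid` enumerates cells over chosen axes, reusing feature
extraction per mask variant, and emits a summary table with one row per
(analysis, ground truth).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort import CohortConfig, iter_cohort, records_to_table
from .embedding import Embedding, Partition, embed, standardize_impute
from .errors import ConfigError, ParameterError
from .features import ExtractionSpec, FeatureTable, extract_table
from .optimize import ClusteringSearchSpace, cluster_raw_features, optimize_clustering
from .stats import ConcordanceResult, ContingencyTable, bootstrap_concordance, contingency

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentSpec",
    "ExperimentReport",
    "Seeds",
    "subset_lesions",
    "subset_features",
    "extract_cohort_features",
    "run_experiment",
    "run_grid",
    "SUMMARY_COLUMNS",
]

LESION_SUBSETS = ("all", "metastatic", "solid_organ")
FEATURE_SUBSETS = ("all", "shape", "intensity", "texture")
MASK_VARIANTS = ("full", "eroded")
REPRESENTATIONS = ("embedding", "raw")

SUMMARY_COLUMNS = [
    "analysis", "cohort", "ground_truth", "mean_ARI", "CI_low", "CI_high",
    "original_ARI", "mean_diff", "diff_CI_low", "diff_CI_high", "p_value",
]


@dataclass(frozen=True)
class Seeds:
    """Independent named seeds for each stochastic stage."""

    cohort: int = 0
    embedding: int = 1
    optimizer: int = 2
    bootstrap: int = 3


@dataclass
class ExperimentSpec:
    """One fully specified analysis cell."""

    cohort: CohortConfig | str  # synthetic config, or a directory of NRRD + metadata CSV
    lesion_subset: str = "all"
    feature_subset: str = "all"
    mask_variant: str = "full"
    representation: str = "embedding"
    seeds: Seeds = field(default_factory=Seeds)
    search_space: ClusteringSearchSpace = field(default_factory=ClusteringSearchSpace)
    extraction: ExtractionSpec = field(default_factory=ExtractionSpec)
    embedding_params: dict = field(default_factory=dict)
    n_boot: int = 100
    ari_mode: str = "mean"
    environment_grouping: dict[str, str] | None = None
    # sensitivity option: re-cluster each bootstrap resample (on the fixed
    # representation, at the selected hyperparameters) instead of resampling
    # the fixed partition
    refit_per_replicate: bool = False

    def validate(self) -> None:
        if self.lesion_subset not in LESION_SUBSETS:
            raise ParameterError(f"lesion_subset must be one of {LESION_SUBSETS}")
        if self.feature_subset not in FEATURE_SUBSETS:
            raise ParameterError(f"feature_subset must be one of {FEATURE_SUBSETS}")
        if self.mask_variant not in MASK_VARIANTS:
            raise ParameterError(f"mask_variant must be one of {MASK_VARIANTS}")
        if self.representation not in REPRESENTATIONS:
            raise ParameterError(f"representation must be one of {REPRESENTATIONS}")

    def analysis_name(self) -> str:
        parts = [self.lesion_subset, self.feature_subset, self.mask_variant, self.representation]
        return "/".join(parts)


@dataclass
class ExperimentReport:
    """Everything one cell computed, recomputable from spec + seeds."""

    spec: ExperimentSpec
    n_lesions: int
    k: int
    silhouette: float
    best_params: dict
    concordance: ConcordanceResult
    contingency_tables: dict[str, ContingencyTable]
    partition: Partition
    embedding: Embedding | None
    dropped_lesions: list[str]
    provenance: dict

    def summary_rows(self) -> list[dict]:
        c = self.concordance
        rows = []
        for gt, mean, ci, full in (
            (c.label_a, c.mean_a, c.ci_a, c.ari_a_full),
            (c.label_b, c.mean_b, c.ci_b, c.ari_b_full),
        ):
            rows.append({
                "analysis": self.spec.analysis_name(),
                "cohort": f"synthetic (n={self.n_lesions})",
                "ground_truth": gt,
                "mean_ARI": mean,
                "CI_low": ci[0],
                "CI_high": ci[1],
                "original_ARI": full,
                "mean_diff": c.mean_diff,
                "diff_CI_low": c.ci_diff[0],
                "diff_CI_high": c.ci_diff[1],
                "p_value": c.p_value,
            })
        return rows

    def to_dict(self) -> dict:
        return {
            "analysis": self.spec.analysis_name(),
            "n_lesions": self.n_lesions,
            "k": self.k,
            "silhouette": self.silhouette,
            "best_params": self.best_params,
            "concordance": self.concordance.to_dict(include_vectors=False),
            "dropped_lesions": self.dropped_lesions,
            "provenance": self.provenance,
        }


def subset_lesions(
    table: pd.DataFrame, features: FeatureTable, subset: str
) -> tuple[pd.DataFrame, FeatureTable]:
    """Restrict to a lesion-class stratum, keeping table/feature alignment.

    ``metastatic`` drops primary tumors; ``solid_organ`` additionally drops
    lymph-node metastases.
    """
    if subset not in LESION_SUBSETS:
        raise ParameterError(f"unknown lesion subset {subset!r}")
    if list(table["lesion_id"]) != list(features.lesion_ids):
        raise ParameterError("lesion table and feature table are not aligned")
    if subset == "all":
        return table.reset_index(drop=True), features
    if subset == "metastatic":
        keep = (table["lesion_class"] != "primary").to_numpy()
    else:
        keep = (table["lesion_class"] == "solid_organ_met").to_numpy()
    if not keep.any():
        raise ParameterError(f"lesion subset {subset!r} is empty")
    return table.loc[keep].reset_index(drop=True), features.select_rows(keep)


def subset_features(features: FeatureTable, feature_class: str) -> FeatureTable:
    """Restrict the feature table to one class (shape/intensity/texture)."""
    if feature_class == "all":
        return features
    if feature_class not in ("shape", "intensity", "texture"):
        raise ParameterError(f"unknown feature class {feature_class!r}")
    keep = np.array([m.feature_class == feature_class for m in features.metas])
    if not keep.any():
        raise ParameterError(f"no features of class {feature_class!r} in table")
    return features.select_columns(keep)


def extract_cohort_features(
    cohort: CohortConfig | str,
    extraction: ExtractionSpec,
    mask_variant: str = "full",
) -> tuple[pd.DataFrame, FeatureTable, list[str]]:
    """Resolve a cohort source and extract its feature table.

    A :class:`CohortConfig` is generated lazily (volumes are never all held
    in memory); a string/path is read as a directory of per-lesion NRRD pairs
    plus a metadata CSV. Lesions degenerate under the requested mask variant
    are dropped; their ids are returned.
    """
    if isinstance(cohort, CohortConfig):
        records = []

        def _pairs():
            for rec, pair in iter_cohort(cohort):
                records.append(rec)
                yield pair

        # materialize ids lazily alongside the pairs
        from .cohort import sample_lesion_records

        ids = [r.lesion_id for r in sample_lesion_records(cohort)]
        features, dropped = extract_table(_pairs(), ids, extraction, mask_variant)
        table = records_to_table(records)
    else:
        from .io import read_cohort_dir

        table, pairs, ids = read_cohort_dir(cohort)
        features, dropped = extract_table(pairs, ids, extraction, mask_variant)
    if dropped:
        table = table[~table["lesion_id"].isin(dropped)].reset_index(drop=True)
    table = table[table["lesion_id"].isin(features.lesion_ids)].reset_index(drop=True)
    # align row order to the feature table
    table = table.set_index("lesion_id").loc[features.lesion_ids].reset_index()
    return table, features, dropped


def _config_hash(spec: ExperimentSpec) -> str:
    def _default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    payload = json.dumps(spec, default=_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(
    spec: ExperimentSpec,
    out_dir: str | Path | None = None,
    _features_cache: dict | None = None,
) -> ExperimentReport:
    """Execute one analysis cell end-to-end, optionally persisting artifacts.

    With ``out_dir`` set, the cell writes ``features.csv``, ``embedding.csv``
    (embedding representation only), ``partition.csv``, ``concordance.json``,
    ``contingency_<label>.csv`` and ``report.json``. All content is a pure
    function of the spec and its seeds.
    """
    spec.validate()
    cache_key = spec.mask_variant
    if _features_cache is not None and cache_key in _features_cache:
        table, features, dropped = _features_cache[cache_key]
    else:
        table, features, dropped = extract_cohort_features(
            spec.cohort, spec.extraction, spec.mask_variant
        )
        if _features_cache is not None:
            _features_cache[cache_key] = (table, features, dropped)

    if spec.environment_grouping:
        table = table.copy()
        table["environment"] = table["environment"].map(
            lambda e: spec.environment_grouping.get(e, e)
        )

    table, features = subset_lesions(table, features, spec.lesion_subset)
    features = subset_features(features, spec.feature_subset)
    std = standardize_impute(features)

    gt = {
        "tumor_type": table["tumor_type"].to_numpy(),
        "environment": table["environment"].to_numpy(),
    }
    space = replace(spec.search_space, seed=spec.seeds.optimizer)

    emb: Embedding | None = None
    if spec.representation == "embedding":
        emb = embed(std, params=spec.embedding_params, seed=spec.seeds.embedding)
        partition, best_params, trace = optimize_clustering(
            emb, gt, space=space, ari_mode=spec.ari_mode
        )
    else:
        partition, best_params, trace = cluster_raw_features(
            std, gt, space=space, ari_mode=spec.ari_mode
        )

    if spec.refit_per_replicate:
        from .embedding import agglomerative_cluster
        from .stats import bootstrap_concordance_refit

        points = emb.coords if emb is not None else std.values
        k, link, metric = best_params["k"], best_params["linkage"], best_params["metric"]
        conc = bootstrap_concordance_refit(
            points, gt["tumor_type"], gt["environment"],
            cluster_fn=lambda p: agglomerative_cluster(p, k, link, metric).labels,
            n_boot=spec.n_boot, seed=spec.seeds.bootstrap,
        )
    else:
        conc = bootstrap_concordance(
            partition.labels, gt["tumor_type"], gt["environment"],
            n_boot=spec.n_boot, seed=spec.seeds.bootstrap,
        )
    tables = {name: contingency(partition.labels, g) for name, g in gt.items()}

    provenance = {
        "config_hash": _config_hash(spec),
        "seeds": spec.seeds.__dict__,
        "version": _version,
    }
    report = ExperimentReport(
        spec=spec,
        n_lesions=len(table),
        k=partition.k,
        silhouette=float(best_params["silhouette"]),
        best_params=best_params,
        concordance=conc,
        contingency_tables=tables,
        partition=partition,
        embedding=emb,
        dropped_lesions=dropped,
        provenance=provenance,
    )
    if out_dir is not None:
        _persist(report, features, trace, Path(out_dir))
    return report


def _persist(report: ExperimentReport, features: FeatureTable, trace: pd.DataFrame,
             out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    features.write_csv(out_dir / "features.csv", out_dir / "feature_meta.csv")
    if report.embedding is not None:
        report.embedding.write_csv(out_dir / "embedding.csv")
    report.partition.write_csv(out_dir / "partition.csv")
    report.concordance.to_json(out_dir / "concordance.json")
    trace.to_csv(out_dir / "optimization_trace.csv", index=False, float_format="%.12g")
    for name, tab in report.contingency_tables.items():
        tab.counts.to_csv(out_dir / f"contingency_{name}.csv")
        tab.row_percent.to_csv(out_dir / f"contingency_{name}_percent.csv", float_format="%.6g")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def run_grid(
    base_spec: ExperimentSpec,
    axes: dict[str, list[str]] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[ExperimentReport | None], pd.DataFrame]:
    """Run every combination over the requested axes, plus a summary table.

    ``axes`` maps any of lesion_subset / feature_subset / mask_variant /
    representation to the values to enumerate; missing axes stay at the base
    spec's value. Feature extraction is shared across cells with the same
    mask variant. Failed cells are logged, marked ``None`` in the report
    list, and the grid continues.
    """
    axes = axes or {}
    allowed = {"lesion_subset", "feature_subset", "mask_variant", "representation"}
    if set(axes) - allowed:
        raise ParameterError(f"unknown grid axes: {set(axes) - allowed}")
    from itertools import product

    axis_names = list(axes.keys())
    combos = list(product(*axes.values())) if axes else [()]
    cache: dict = {}
    reports: list[ExperimentReport | None] = []
    rows: list[dict] = []
    for combo in combos:
        spec = replace(base_spec, **dict(zip(axis_names, combo)))
        cell_name = spec.analysis_name()
        cell_dir = None
        if out_dir is not None:
            cell_dir = Path(out_dir) / cell_name.replace("/", "_")
        try:
            rep = run_experiment(spec, out_dir=cell_dir, _features_cache=cache)
        except Exception as exc:  # keep the grid going, mark the failure
            log.error("grid cell %s failed: %s", cell_name, exc)
            reports.append(None)
            rows.append({c: (cell_name if c == "analysis" else "FAILED") for c in SUMMARY_COLUMNS})
            continue
        reports.append(rep)
        rows.extend(rep.summary_rows())
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(out_dir) / "summary_table3.csv", index=False, float_format="%.6g")
    return reports, summary
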