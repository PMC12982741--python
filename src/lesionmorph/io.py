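"""File formats and configuration: NRRD volumes, metadata CSV, YAML config.

Per-lesion volumes are stored as NRRD pairs ``<lesion_id>_image.nrrd`` /
``<lesion_id>_mask.nrrd`` next to a ``metadata.csv`` with header
``lesion_id,patient_id,tumor_type,environment,lesion_class``. The NRRD
``space directions`` field is the source of truth for voxel spacing; arrays
are exchanged in ``(slice, row, col)`` index order with spacing per array
axis, mirroring :mod:`lesionmorph.features`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .cohort import (
    CohortConfig,
    EnvironmentProfile,
    LESION_CLASSES,
    TumorTypeProfile,
    default_cohort_config,
    iter_cohort,
    records_to_table,
)
from .embedding import DEFAULT_EMBEDDING_PARAMS
from .errors import ConfigError, LesionIOError
from .experiments import ExperimentSpec, Seeds
from .features import DiscretizationSpec, ExtractionSpec, VolumeMaskPair
from .optimize import ClusteringSearchSpace

__all__ = [
    "read_nrrd",
    "write_nrrd",
    "read_volume_mask_pair",
    "write_volume_mask_pair",
    "read_lesion_table",
    "read_cohort_dir",
    "write_cohort",
    "load_run_config",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# NRRD
# ---------------------------------------------------------------------------

def _validate_nrrd_header(path: Path) -> None:
    """Light structural validation before handing the file to the reader.

    Checks the NRRD magic, 3-D dimensionality, and the presence of spacing
    metadata (``space directions`` or ``spacings``).
    """
    try:
        with open(path, "rb") as fh:
            header = fh.read(4096)
    except OSError as exc:
        raise LesionIOError(f"cannot read {path}: {exc}") from exc
    if not header.startswith(b"NRRD"):
        raise LesionIOError(f"{path}: not an NRRD file (bad magic)")
    text = header.split(b"\n\n", 1)[0].decode("ascii", errors="replace")
    fields = {}
    for line in text.splitlines()[1:]:
        if ":" in line and not line.startswith("#"):
            key = line.split(":", 1)[0].strip().lower()
            fields[key] = line.split(":", 1)[1].strip()
    dim = fields.get("dimension")
    if dim is not None and dim != "3":
        raise LesionIOError(f"{path}: expected a 3-D payload, header says dimension {dim}")
    if "space directions" not in fields and "spacings" not in fields:
        raise LesionIOError(
            f"{path}: missing voxel-spacing metadata ('space directions' or 'spacings' header field)"
        )


def read_nrrd(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D NRRD volume; returns (array, spacing per array axis)."""
    path = Path(path)
    if not path.exists():
        raise LesionIOError(f"no such file: {path}")
    _validate_nrrd_header(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise LesionIOError(f"failed to parse {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise LesionIOError(f"{path}: expected a 3-D payload, got {img.GetDimension()}-D")
    array = sitk.GetArrayFromImage(img)
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    return array, spacing


def write_nrrd(path, array: np.ndarray, spacing) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def write_volume_mask_pair(directory, lesion_id: str, pair: VolumeMaskPair) -> None:
    directory = Path(directory)
    write_nrrd(directory / f"{lesion_id}_image.nrrd", pair.image, pair.spacing)
    write_nrrd(directory / f"{lesion_id}_mask.nrrd", pair.mask.astype(np.uint8), pair.spacing)


def read_volume_mask_pair(directory, lesion_id: str) -> VolumeMaskPair:
    directory = Path(directory)
    image, sp_i = read_nrrd(directory / f"{lesion_id}_image.nrrd")
    mask, sp_m = read_nrrd(directory / f"{lesion_id}_mask.nrrd")
    if not np.allclose(sp_i, sp_m):
        raise LesionIOError(f"{lesion_id}: image and mask spacing disagree ({sp_i} vs {sp_m})")
    return VolumeMaskPair(image=image, mask=mask > 0, spacing=sp_i)


# ---------------------------------------------------------------------------
# Metadata CSV
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ["lesion_id", "patient_id", "tumor_type", "environment", "lesion_class"]


def read_lesion_table(path, data_dir=None) -> pd.DataFrame:
    """Read and validate the per-lesion metadata CSV.

    Rejects duplicate lesion ids and unknown lesion classes; when
    ``data_dir`` is given, checks that every lesion has its NRRD pair.
    """
    path = Path(path)
    if not path.exists():
        raise LesionIOError(f"no such file: {path}")
    table = pd.read_csv(path, dtype=str)
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise LesionIOError(f"{path}: missing required columns {sorted(missing)}")
    dup = table["lesion_id"][table["lesion_id"].duplicated()]
    if not dup.empty:
        raise LesionIOError(f"{path}: duplicate lesion_id values: {sorted(set(dup))[:5]}")
    bad = table.loc[~table["lesion_class"].isin(LESION_CLASSES)]
    if not bad.empty:
        row = bad.index[0]
        raise LesionIOError(
            f"{path} row {row + 2}: unknown lesion_class {bad['lesion_class'].iloc[0]!r} "
            f"(expected one of {LESION_CLASSES})"
        )
    if data_dir is not None:
        data_dir = Path(data_dir)
        for lesion_id in table["lesion_id"]:
            for suffix in ("image", "mask"):
                f = data_dir / f"{lesion_id}_{suffix}.nrrd"
                if not f.exists():
                    raise LesionIOError(f"{path}: dangling reference, {f} does not exist")
    return table[REQUIRED_COLUMNS]


def read_cohort_dir(directory):
    """Load a cohort directory: metadata table + lazy volume iterator.

    Rows are sorted by lesion_id so downstream results are independent of CSV
    row order (alignment is by id, not position).
    """
    directory = Path(directory)
    table = read_lesion_table(directory / "metadata.csv", data_dir=directory)
    table = table.sort_values("lesion_id").reset_index(drop=True)
    ids = list(table["lesion_id"])

    def _pairs():
        for lesion_id in ids:
            yield read_volume_mask_pair(directory, lesion_id)

    return table, _pairs(), ids


def write_cohort(config: CohortConfig, out_dir) -> pd.DataFrame:
    """Generate a synthetic cohort to disk (NRRD pairs + metadata.csv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for rec, pair in iter_cohort(config):
        write_volume_mask_pair(out_dir, rec.lesion_id, pair)
        records.append(rec)
    table = records_to_table(records)
    table.to_csv(out_dir / "metadata.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated top-level configuration for a pipeline run."""

    experiment: ExperimentSpec
    embedding_params: dict
    output_dir: str
    raw: dict

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_cohort(section: dict) -> CohortConfig | str:
    _check_keys(section, {"directory", "synthetic"}, "cohort")
    if "directory" in section:
        return str(section["directory"])
    syn = section.get("synthetic") or {}
    allowed = {
        "preset", "n_patients", "lesions_per_patient", "lesion_class_mix",
        "short_axis_range", "voxel_spacing", "grid_shape", "noise_sd",
        "environments", "tumor_types", "seed",
    }
    _check_keys(syn, allowed, "cohort.synthetic")
    base = default_cohort_config()
    if "environments" in syn:
        base.environments = [EnvironmentProfile(**e) for e in syn["environments"]]
    if "tumor_types" in syn:
        base.tumor_types = [TumorTypeProfile(**t) for t in syn["tumor_types"]]
    for key in ("n_patients", "noise_sd", "seed"):
        if key in syn:
            setattr(base, key, syn[key])
    if "lesions_per_patient" in syn:
        v = syn["lesions_per_patient"]
        base.lesions_per_patient = tuple(v) if isinstance(v, (list, tuple)) else int(v)
    for key in ("short_axis_range", "voxel_spacing", "grid_shape"):
        if key in syn:
            setattr(base, key, tuple(syn[key]))
    if "lesion_class_mix" in syn:
        base.lesion_class_mix = dict(syn["lesion_class_mix"])
    base.validate()
    return base


def load_run_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration (strict keys)."""
    path = Path(path)
    if not path.exists():
        raise LesionIOError(f"no such config file: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    _check_keys(raw, {"schema_version", "cohort", "extraction", "analysis", "seeds", "output_dir"},
                str(path))
    if raw.get("schema_version", 1) != 1:
        raise ConfigError(f"unsupported schema_version {raw.get('schema_version')}")

    cohort = _parse_cohort(raw.get("cohort") or {"synthetic": {}})

    ext_raw = raw.get("extraction") or {}
    _check_keys(ext_raw, {"target_spacing", "bin_width", "n_bins", "mode", "families"}, "extraction")
    disc_kwargs = {}
    if "mode" in ext_raw:
        disc_kwargs["mode"] = ext_raw["mode"]
    if "bin_width" in ext_raw:
        disc_kwargs["bin_width"] = float(ext_raw["bin_width"])
    if "n_bins" in ext_raw:
        disc_kwargs["n_bins"] = int(ext_raw["n_bins"])
    extraction = ExtractionSpec(
        target_spacing=tuple(ext_raw.get("target_spacing", (1.0, 1.0, 1.0))),
        discretization=DiscretizationSpec(**disc_kwargs),
        families=tuple(ext_raw.get("families", ExtractionSpec().families)),
    )

    ana = raw.get("analysis") or {}
    _check_keys(
        ana,
        {"search_space", "embedding", "n_boot", "ari_mode", "lesion_subset",
         "feature_subset", "mask_variant", "representation", "environment_grouping",
         "refit_per_replicate"},
        "analysis",
    )
    ss_raw = ana.get("search_space") or {}
    _check_keys(ss_raw, {"k_min", "k_max", "linkages", "metrics", "budget"}, "analysis.search_space")
    space = ClusteringSearchSpace(
        k_range=(int(ss_raw.get("k_min", 2)), int(ss_raw.get("k_max", 15))),
        linkage_options=tuple(ss_raw.get("linkages", ("ward", "complete", "average"))),
        metric_options=tuple(ss_raw.get("metrics", ("euclidean",))),
        budget=int(ss_raw.get("budget", 50)),
    )
    emb_raw = ana.get("embedding") or {}
    _check_keys(emb_raw, {"perplexity", "max_iter", "init"}, "analysis.embedding")
    embedding_params = dict(DEFAULT_EMBEDDING_PARAMS)
    embedding_params.update(emb_raw)

    seeds_raw = raw.get("seeds") or {}
    _check_keys(seeds_raw, {"cohort", "embedding", "optimizer", "bootstrap"}, "seeds")
    seeds = Seeds(**{k: int(v) for k, v in seeds_raw.items()})
    if isinstance(cohort, CohortConfig) and "cohort" in seeds_raw:
        cohort.seed = seeds.cohort

    spec = ExperimentSpec(
        cohort=cohort,
        lesion_subset=ana.get("lesion_subset", "all"),
        feature_subset=ana.get("feature_subset", "all"),
        mask_variant=ana.get("mask_variant", "full"),
        representation=ana.get("representation", "embedding"),
        seeds=seeds,
        search_space=space,
        extraction=extraction,
        embedding_params=embedding_params,
        n_boot=int(ana.get("n_boot", 100)),
        ari_mode=ana.get("ari_mode", "mean"),
        environment_grouping=ana.get("environment_grouping"),
        refit_per_replicate=bool(ana.get("refit_per_replicate", False)),
    )
    spec.validate()
    return RunConfig(
        experiment=spec,
        embedding_params=embedding_params,
        output_dir=str(raw.get("output_dir", "runs")),
        raw=raw,
    )
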