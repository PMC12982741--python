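"""Per-lesion radiomic feature extraction.

The extractor consumes a :class:`VolumeMaskPair` (intensity volume in HU, an
aligned binary mask, per-axis voxel spacing in mm) and produces a tagged
feature row. Pipeline: resample to isotropic spacing (cubic B-spline for the
image, nearest-neighbour + re-binarization for the mask), then

* shape features from the mask geometry alone (14 features),
* first-order intensity statistics from the in-mask voxel values,
* texture features from the discretized gray levels via the five matrix
  families in :mod:`lesionmorph.texture`.

Arrays are indexed ``(slice, row, col)``, i.e. axis 0 is the axial (z)
direction; ``spacing`` is given per array axis in mm. Physical coordinates of
a voxel are ``index * spacing`` — all operators are relative to the mask, so
features are invariant under whole-voxel translations of image+mask.

The feature set is a reduced, class-tagged analogue of a full IBSI bank
(~65 features across 7 families); breadth is configurable, correctness of the
class tags (shape / intensity / texture) is what the downstream concordance
analysis relies on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial import QhullError, ConvexHull
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from . import texture
from .errors import ConfigError, DegenerateLesionError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "VolumeMaskPair",
    "FeatureMeta",
    "FeatureTable",
    "DiscretizationSpec",
    "ExtractionSpec",
    "resample_isotropic",
    "discretize_intensities",
    "shape_features",
    "firstorder_features",
    "erode_mask",
    "extract_features",
    "extract_table",
    "principal_extents",
]

STRUCT_6 = ndimage.generate_binary_structure(3, 1)   # face neighbours
STRUCT_26 = ndimage.generate_binary_structure(3, 3)  # full 3x3x3 neighbourhood


@dataclass
class VolumeMaskPair:
    """A 3-D intensity volume with an aligned binary lesion mask."""

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.image.ndim != 3 or self.image.shape != self.mask.shape:
            raise ConfigError(
                f"image {self.image.shape} and mask {self.mask.shape} must be matching 3-D grids"
            )
        if not self.mask.any():
            raise DegenerateLesionError("mask has no foreground voxels")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be positive, got {self.spacing}")


@dataclass(frozen=True)
class FeatureMeta:
    """Name, class tag and family of one radiomic feature."""

    name: str
    feature_class: str  # shape | intensity | texture
    family: str  # shape3d | firstorder | glcm | glrlm | glszm | ngtdm | gldm

    _CLASS_OF_FAMILY = {
        "shape3d": "shape",
        "firstorder": "intensity",
        "glcm": "texture",
        "glrlm": "texture",
        "glszm": "texture",
        "ngtdm": "texture",
        "gldm": "texture",
    }

    def __post_init__(self):
        expected = self._CLASS_OF_FAMILY.get(self.family)
        if expected is None:
            raise ConfigError(f"unknown feature family {self.family!r}")
        if self.feature_class != expected:
            raise ConfigError(
                f"feature {self.name!r}: family {self.family!r} implies class "
                f"{expected!r}, got {self.feature_class!r}"
            )


@dataclass
class FeatureTable:
    """Lesions x features matrix with per-feature class tags.

    ``values`` may contain NaN for features that were undefined for a lesion;
    imputation happens downstream in the embedding stage.
    """

    lesion_ids: list[str]
    metas: list[FeatureMeta]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        names = [m.name for m in self.metas]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate feature names in FeatureTable")
        if self.values.shape != (len(self.lesion_ids), len(self.metas)):
            raise ConfigError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.lesion_ids)} lesions x {len(self.metas)} features"
            )

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metas]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.lesion_ids, name="lesion_id"),
                            columns=self.names)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.name, m.feature_class, m.family) for m in self.metas],
            columns=["name", "feature_class", "family"],
        )

    def select_columns(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        return FeatureTable(
            lesion_ids=list(self.lesion_ids),
            metas=[m for m, k in zip(self.metas, keep) if k],
            values=self.values[:, keep],
        )

    def select_rows(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        return FeatureTable(
            lesion_ids=[l for l, k in zip(self.lesion_ids, keep) if k],
            metas=list(self.metas),
            values=self.values[keep],
        )

    def write_csv(self, values_path, meta_path=None) -> None:
        self.to_frame().to_csv(values_path, float_format="%.12g")
        if meta_path is not None:
            self.meta_frame().to_csv(meta_path, index=False)

    @classmethod
    def read_csv(cls, values_path, meta_path) -> "FeatureTable":
        frame = pd.read_csv(values_path, index_col="lesion_id")
        meta = pd.read_csv(meta_path)
        metas = [
            FeatureMeta(r["name"], r["feature_class"], r["family"])
            for _, r in meta.iterrows()
        ]
        if [m.name for m in metas] != list(frame.columns):
            raise ConfigError("feature meta CSV does not match feature table columns")
        return cls(lesion_ids=[str(i) for i in frame.index], metas=metas,
                   values=frame.to_numpy())


@dataclass(frozen=True)
class DiscretizationSpec:
    """Gray-level discretization: fixed bin width (HU) or fixed bin count."""

    mode: str = "fixed_bin_width"
    bin_width: float = 25.0
    n_bins: int = 32

    def __post_init__(self):
        if self.mode not in ("fixed_bin_width", "fixed_bin_count"):
            raise ConfigError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.mode == "fixed_bin_count" and self.n_bins < 1:
            raise ConfigError("n_bins must be positive")


@dataclass(frozen=True)
class ExtractionSpec:
    """Extraction parameters: target spacing, discretization, families."""

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    families: tuple[str, ...] = ("shape3d", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
    gldm_alpha: int = 0


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _to_sitk(array: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))  # sitk is (x, y, z)
    return img


def resample_isotropic(
    pair: VolumeMaskPair, target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> VolumeMaskPair:
    """Resample image+mask onto an isotropic grid (default 1 mm^3).

    The image is interpolated with a cubic B-spline, the mask with
    nearest-neighbour followed by re-binarization at 0.5. A grid already at
    the target spacing is returned unchanged (identity fast path).
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ParameterError(f"target spacing must be positive, got {target}")
    if np.allclose(pair.spacing, target):
        return VolumeMaskPair(pair.image.copy(), pair.mask.copy(), target)

    new_size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(pair.image.shape, pair.spacing, target)
    ]
    img = _to_sitk(pair.image, pair.spacing)
    msk = _to_sitk(pair.mask.astype(np.uint8), pair.spacing)
    ref_size = [int(v) for v in new_size[::-1]]
    ref_spacing = tuple(target[::-1])

    def _resample(im, interp):
        return sitk.Resample(
            im, ref_size, sitk.Transform(), interp, im.GetOrigin(), ref_spacing,
            im.GetDirection(), 0.0, im.GetPixelID(),
        )

    image_r = sitk.GetArrayFromImage(_resample(img, sitk.sitkBSpline))
    mask_r = sitk.GetArrayFromImage(_resample(msk, sitk.sitkNearestNeighbor)) > 0.5
    if not mask_r.any():
        raise DegenerateLesionError("mask became empty after resampling")
    return VolumeMaskPair(image_r, mask_r, target)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_intensities(
    image: np.ndarray, mask: np.ndarray, spec: DiscretizationSpec
) -> np.ndarray:
    """Map in-mask intensities to integer gray levels 1..G (0 outside mask).

    Fixed bin width: ``level = floor((v - min) / width) + 1``. Fixed bin
    count: the in-mask range is split into ``n_bins`` equal bins; a constant
    image maps to the single level 1.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateLesionError("cannot discretize an empty mask")
    vals = np.asarray(image, dtype=float)[mask]
    levels = np.zeros(mask.shape, dtype=np.int64)
    vmin, vmax = vals.min(), vals.max()
    if spec.mode == "fixed_bin_width":
        lev = np.floor((vals - vmin) / spec.bin_width).astype(np.int64) + 1
    else:
        if vmax == vmin:
            lev = np.ones(vals.shape, dtype=np.int64)
        else:
            lev = np.floor((vals - vmin) / (vmax - vmin) * spec.n_bins).astype(np.int64) + 1
            lev = np.minimum(lev, spec.n_bins)
    levels[mask] = lev
    return levels


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def principal_extents(mask: np.ndarray, spacing) -> np.ndarray:
    """Sorted (desc) physical extents of the mask along its principal axes.

    Extents are peak-to-peak projections of voxel centers onto the PCA axes
    plus one mean voxel width, accounting for the finite voxel support.
    """
    coords = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    voxel = float(np.mean(spacing))
    if coords.shape[0] == 1:
        return np.array([voxel, voxel, voxel])
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    ext = proj.max(axis=0) - proj.min(axis=0) + voxel
    ext = np.sort(ext)[::-1]
    return np.pad(ext, (0, 3 - ext.size), constant_values=voxel)


def _max_pairwise_distance(coords: np.ndarray) -> float:
    """Largest pairwise distance; uses the convex hull to prune when possible."""
    if coords.shape[0] < 2:
        return 0.0
    pts = coords
    if pts.shape[0] > 200:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) point set: brute force
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=STRUCT_6, border_value=0)
    return mask & ~eroded


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """The 14 mask-geometry features, all in physical units (mm-based).

    Surface area counts exposed voxel faces (a deliberate, exactly-testable
    simplification of mesh-based area). Axis lengths follow the PCA
    eigenvalue convention ``4 * sqrt(lambda)``; a single-voxel mask has axis
    lengths 0 and elongation/flatness 1 by convention.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateLesionError("empty mask")
    sp = np.asarray(spacing, dtype=float)
    n_vox = int(mask.sum())
    voxel_volume = float(np.prod(sp))
    volume = n_vox * voxel_volume

    # exposed-face surface area: for each axis, faces where mask meets background
    area = 0.0
    face_areas = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
    for ax, fa in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=ax)
        area += np.abs(diff).sum() * fa
    surface_area = float(area)

    coords = np.argwhere(mask) * sp
    if n_vox > 1:
        cov = np.cov(coords.T, bias=False)
        eigvals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
        elongation = math.sqrt(eigvals[1] / eigvals[0]) if eigvals[0] > 0 else 1.0
        flatness = math.sqrt(eigvals[2] / eigvals[0]) if eigvals[0] > 0 else 1.0
    else:
        major = minor = least = 0.0
        elongation = flatness = 1.0

    surf_coords = np.argwhere(_surface_voxels(mask)) * sp
    max_diam = _max_pairwise_distance(surf_coords)

    sphericity = (math.pi ** (1.0 / 3.0)) * ((6.0 * volume) ** (2.0 / 3.0)) / surface_area
    compactness = 36.0 * math.pi * volume**2 / surface_area**3

    # 2-D analogues on the largest-area axial slice (axis 0 = axial direction)
    slice_counts = mask.sum(axis=(1, 2))
    k = int(np.argmax(slice_counts))
    sl = mask[k]
    pixel_area = float(sp[1] * sp[2])
    area_2d = float(sl.sum() * pixel_area)
    perim = 0.0
    edge_lengths = [sp[2], sp[1]]  # edges exposed along rows have length of the col spacing
    for ax, el in enumerate(edge_lengths):
        padded = np.pad(sl, [(1, 1) if a == ax else (0, 0) for a in range(2)])
        perim += np.abs(np.diff(padded.astype(np.int8), axis=ax)).sum() * el
    coords2d = np.argwhere(sl) * sp[1:]
    diam_2d = _max_pairwise_distance(coords2d)

    return {
        "shape_volume": volume,
        "shape_surface_area": surface_area,
        "shape_surface_volume_ratio": surface_area / volume,
        "shape_sphericity": sphericity,
        "shape_compactness": compactness,
        "shape_max_diameter_3d": max_diam,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_least_axis_length": least,
        "shape_elongation": elongation,
        "shape_flatness": flatness,
        "shape_slice_area_2d": area_2d,
        "shape_slice_perimeter_2d": perim,
        "shape_slice_diameter_2d": diam_2d,
    }


SHAPE_FEATURE_NAMES = (
    "shape_volume",
    "shape_surface_area",
    "shape_surface_volume_ratio",
    "shape_sphericity",
    "shape_compactness",
    "shape_max_diameter_3d",
    "shape_major_axis_length",
    "shape_minor_axis_length",
    "shape_least_axis_length",
    "shape_elongation",
    "shape_flatness",
    "shape_slice_area_2d",
    "shape_slice_perimeter_2d",
    "shape_slice_diameter_2d",
)


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------

def firstorder_features(
    image: np.ndarray, mask: np.ndarray, disc: DiscretizationSpec | None = None
) -> dict[str, float]:
    """First-order statistics of the in-mask intensities.

    Entropy is computed on the discretized gray levels (bits); skewness and
    kurtosis (Pearson, i.e. normal = 3) are 0 and 0 for constant input by the
    scipy convention propagated here as 0.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateLesionError("empty mask")
    v = np.asarray(image, dtype=float)[mask]
    disc = disc or DiscretizationSpec()
    levels = discretize_intensities(image, mask, disc)[mask]
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / p.sum()
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    inner = v[(v >= p10) & (v <= p90)]
    robust_mad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    sk = float(_skew(v)) if v.size > 1 and v.std() > 0 else 0.0
    ku = float(_kurtosis(v, fisher=False)) if v.size > 1 and v.std() > 0 else 0.0
    return {
        "firstorder_mean": float(v.mean()),
        "firstorder_median": float(np.median(v)),
        "firstorder_min": float(v.min()),
        "firstorder_max": float(v.max()),
        "firstorder_range": float(v.max() - v.min()),
        "firstorder_variance": float(v.var()),
        "firstorder_skewness": sk,
        "firstorder_kurtosis": ku,
        "firstorder_energy": float((v**2).sum()),
        "firstorder_entropy": float(-(p * np.log2(p)).sum()),
        "firstorder_p10": float(p10),
        "firstorder_p90": float(p90),
        "firstorder_iqr": float(p75 - p25),
        "firstorder_robust_mad": robust_mad,
    }


FIRSTORDER_FEATURE_NAMES = (
    "firstorder_mean",
    "firstorder_median",
    "firstorder_min",
    "firstorder_max",
    "firstorder_range",
    "firstorder_variance",
    "firstorder_skewness",
    "firstorder_kurtosis",
    "firstorder_energy",
    "firstorder_entropy",
    "firstorder_p10",
    "firstorder_p90",
    "firstorder_iqr",
    "firstorder_robust_mad",
)


# ---------------------------------------------------------------------------
# Erosion
# ---------------------------------------------------------------------------

def erode_mask(mask: np.ndarray) -> np.ndarray:
    """One-voxel binary erosion with the 3-D 6-connected (face) element.

    A voxel survives iff it and all six face-neighbours are foreground;
    out-of-grid counts as background. If erosion disconnects the mask, the
    largest 26-connected component is kept (preserving connectivity). The
    result may be empty (e.g. one-voxel-thick slabs) — callers treat an empty
    result as a degenerate lesion.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ParameterError("erode_mask expects a 3-D mask")
    if not mask.any():
        raise DegenerateLesionError("cannot erode an empty mask")
    eroded = ndimage.binary_erosion(mask, structure=STRUCT_6, border_value=0)
    if not eroded.any():
        return eroded
    labels, n_comp = ndimage.label(eroded, structure=STRUCT_26)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        eroded = labels == (int(np.argmax(sizes)) + 1)
    return eroded


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _crop_to_mask(pair: VolumeMaskPair, margin: int = 1) -> VolumeMaskPair:
    idx = np.argwhere(pair.mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, pair.mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return VolumeMaskPair(pair.image[sl], pair.mask[sl], pair.spacing)


def feature_metas(spec: ExtractionSpec | None = None) -> list[FeatureMeta]:
    """The stable feature ordering for a given extraction spec."""
    spec = spec or ExtractionSpec()
    metas: list[FeatureMeta] = []
    if "shape3d" in spec.families:
        metas += [FeatureMeta(n, "shape", "shape3d") for n in SHAPE_FEATURE_NAMES]
    if "firstorder" in spec.families:
        metas += [FeatureMeta(n, "intensity", "firstorder") for n in FIRSTORDER_FEATURE_NAMES]
    for fam in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
        if fam in spec.families:
            metas += [FeatureMeta(n, "texture", fam) for n in texture.TEXTURE_FEATURE_NAMES[fam]]
    return metas


def extract_features(
    pair: VolumeMaskPair, spec: ExtractionSpec | None = None
) -> tuple[np.ndarray, list[FeatureMeta]]:
    """Full extraction pipeline for one lesion: resample, then all families.

    Returns the feature row (aligned with :func:`feature_metas`) and the meta
    list. Undefined features come back as NaN for downstream imputation.
    """
    spec = spec or ExtractionSpec()
    metas = feature_metas(spec)
    resampled = resample_isotropic(pair, spec.target_spacing)
    cropped = _crop_to_mask(resampled)
    values: dict[str, float] = {}
    if "shape3d" in spec.families:
        values.update(shape_features(cropped.mask, cropped.spacing))
    needs_levels = any(
        f in spec.families for f in ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
    )
    if needs_levels:
        levels = discretize_intensities(cropped.image, cropped.mask, spec.discretization)
        if "firstorder" in spec.families:
            values.update(firstorder_features(cropped.image, cropped.mask, spec.discretization))
        if "glcm" in spec.families:
            values.update(texture.glcm_features(levels))
        if "glrlm" in spec.families:
            values.update(texture.glrlm_features(levels))
        if "glszm" in spec.families:
            values.update(texture.glszm_features(levels))
        if "ngtdm" in spec.families:
            values.update(texture.ngtdm_features(levels))
        if "gldm" in spec.families:
            values.update(texture.gldm_features(levels, alpha=spec.gldm_alpha))
    row = np.array([values.get(m.name, np.nan) for m in metas], dtype=float)
    return row, metas


def extract_table(
    pairs,
    lesion_ids,
    spec: ExtractionSpec | None = None,
    mask_variant: str = "full",
) -> tuple[FeatureTable, list[str]]:
    """Extract a :class:`FeatureTable` from an iterable of lesion volumes.

    ``mask_variant='eroded'`` applies the one-voxel 6-connected erosion before
    extraction; lesions whose eroded mask is empty are dropped and returned in
    the second element (list of dropped lesion ids).
    """
    spec = spec or ExtractionSpec()
    if mask_variant not in ("full", "eroded"):
        raise ParameterError(f"unknown mask variant {mask_variant!r}")
    rows, kept_ids, dropped = [], [], []
    metas = feature_metas(spec)
    for lesion_id, pair in zip(lesion_ids, pairs):
        if mask_variant == "eroded":
            em = erode_mask(pair.mask)
            if not em.any():
                log.warning("lesion %s: eroded mask empty, dropped from eroded analysis", lesion_id)
                dropped.append(lesion_id)
                continue
            pair = replace(pair, image=pair.image, mask=em)
        row, _ = extract_features(pair, spec)
        rows.append(row)
        kept_ids.append(lesion_id)
    if not rows:
        raise DegenerateLesionError("no lesions survived extraction")
    return FeatureTable(kept_ids, metas, np.vstack(rows)), dropped
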