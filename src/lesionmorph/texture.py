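"""Gray-level texture matrices and their derived features.

All operators work on an integer "levels" grid as produced by
:func:`lesionmorph.features.discretize_intensities`: voxels inside the mask
carry levels ``1..G``, voxels outside carry 0 and never contribute to any
matrix. Conventions follow the IBSI definitions:

* GLCM — 13 unique 3-D offsets, symmetric, features averaged over offsets.
* GLRLM — runs along the same 13 directions, features averaged.
* GLSZM — zones are 26-connected components of equal level.
* NGTDM — 26-neighbourhood mean differences.
* GLDM — dependence counts over the 26-neighbourhood at tolerance alpha.

Degenerate inputs (single level, single voxel) fall back to documented
conventions instead of raising: probability-weighted features evaluate on the
(possibly trivial) matrix and correlation-type features return 0.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

__all__ = [
    "UNIQUE_OFFSETS_3D",
    "glcm_matrix",
    "glcm_features",
    "run_length_matrix",
    "glrlm_features",
    "size_zone_matrix",
    "glszm_features",
    "ngtdm_features",
    "dependence_matrix",
    "gldm_features",
    "TEXTURE_FEATURE_NAMES",
]

# The 13 unique 3-D directions: one representative per +/- pair,
# lexicographically positive.
UNIQUE_OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
)

_ALL_NEIGHBOUR_OFFSETS = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


def _overlap_slices(shape, offset):
    """Index slices aligning each voxel with its neighbour at `offset`."""
    sl_a, sl_b = [], []
    for d, size in zip(offset, shape):
        if d >= 0:
            sl_a.append(slice(0, size - d))
            sl_b.append(slice(d, size))
        else:
            sl_a.append(slice(-d, size))
            sl_b.append(slice(0, size + d))
    return tuple(sl_a), tuple(sl_b)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, offset, n_levels: int | None = None,
                symmetric: bool = True) -> np.ndarray:
    """Co-occurrence count matrix for one offset (G x G, level index 0 = level 1)."""
    G = int(n_levels if n_levels is not None else levels.max())
    sl_a, sl_b = _overlap_slices(levels.shape, offset)
    la, lb = levels[sl_a], levels[sl_b]
    valid = (la > 0) & (lb > 0)
    la, lb = la[valid].astype(np.int64), lb[valid].astype(np.int64)
    counts = np.bincount((la - 1) * G + (lb - 1), minlength=G * G).reshape(G, G)
    counts = counts.astype(float)
    if symmetric:
        counts = counts + counts.T
    return counts


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    G = p.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    mu_i = float((i * pi).sum())
    sigma_i = float(np.sqrt(((i - mu_i) ** 2 * pi).sum()))
    # symmetric matrix: both marginals coincide
    diff = ii - jj
    out = {
        "contrast": float((p * diff**2).sum()),
        "dissimilarity": float((p * np.abs(diff)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "angular_second_moment": float((p**2).sum()),
        "joint_entropy": _entropy_bits(p.ravel()),
        "autocorrelation": float((p * ii * jj).sum()),
        "cluster_shade": float((p * (ii + jj - 2 * mu_i) ** 3).sum()),
    }
    if sigma_i > 1e-12:
        out["correlation"] = float(
            ((p * ii * jj).sum() - mu_i * mu_i) / (sigma_i * sigma_i)
        )
    else:
        out["correlation"] = 0.0
    return out


_GLCM_NAMES = (
    "contrast",
    "dissimilarity",
    "inverse_difference_moment",
    "angular_second_moment",
    "joint_entropy",
    "autocorrelation",
    "cluster_shade",
    "correlation",
)


def glcm_features(levels: np.ndarray, offsets=UNIQUE_OFFSETS_3D) -> dict[str, float]:
    """GLCM features averaged over the supplied offsets (symmetric, normalized)."""
    acc: dict[str, list[float]] = {name: [] for name in _GLCM_NAMES}
    for off in offsets:
        counts = glcm_matrix(levels, off)
        total = counts.sum()
        if total == 0:
            continue
        vals = _glcm_single(counts / total)
        for name in _GLCM_NAMES:
            acc[name].append(vals[name])
    return {
        f"glcm_{name}": float(np.mean(v)) if v else 0.0 for name, v in acc.items()
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def run_length_matrix(levels: np.ndarray, direction) -> np.ndarray:
    """Run-length count matrix (G x max_run) for one direction.

    A run is a maximal sequence of in-mask voxels of equal level along the
    direction; out-of-mask voxels and grid edges terminate runs. Each run is
    counted once (directions are treated as unsigned).
    """
    mask = levels > 0
    if not mask.any():
        return np.zeros((0, 0))
    c = np.argwhere(mask)
    lev = levels[mask]
    d = np.asarray(direction)
    anchor = int(np.nonzero(d)[0][0])
    t = c[:, anchor] * d[anchor]
    line_key = c - t[:, None] * d
    order = np.lexsort((t, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
    t_s, key_s, lev_s = t[order], line_key[order], lev[order]
    continues = np.zeros(t_s.size, dtype=bool)
    if t_s.size > 1:
        same_line = np.all(key_s[1:] == key_s[:-1], axis=1)
        continues[1:] = same_line & (t_s[1:] == t_s[:-1] + 1) & (lev_s[1:] == lev_s[:-1])
    starts = np.nonzero(~continues)[0]
    lengths = np.diff(np.append(starts, t_s.size))
    run_levels = lev_s[starts]
    G = int(levels.max())
    M = np.zeros((G, int(lengths.max())))
    np.add.at(M, (run_levels - 1, lengths - 1), 1.0)
    return M


def _glrlm_single(M: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = M.sum()
    G, L = M.shape
    i = np.arange(1, G + 1, dtype=float)[:, None]
    j = np.arange(1, L + 1, dtype=float)[None, :]
    return {
        "short_run_emphasis": float((M / j**2).sum() / nr),
        "long_run_emphasis": float((M * j**2).sum() / nr),
        "gray_level_nonuniformity": float((M.sum(axis=1) ** 2).sum() / nr),
        "run_length_nonuniformity": float((M.sum(axis=0) ** 2).sum() / nr),
        "run_percentage": float(nr / n_voxels),
        "low_gray_level_run_emphasis": float((M / i**2).sum() / nr),
        "high_gray_level_run_emphasis": float((M * i**2).sum() / nr),
        "run_entropy": _entropy_bits(M.ravel() / nr),
    }


_GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "run_entropy",
)


def glrlm_features(levels: np.ndarray, directions=UNIQUE_OFFSETS_3D) -> dict[str, float]:
    """Run-length features averaged over the supplied directions."""
    n_vox = int((levels > 0).sum())
    acc: dict[str, list[float]] = {name: [] for name in _GLRLM_NAMES}
    for d in directions:
        M = run_length_matrix(levels, d)
        if M.size == 0 or M.sum() == 0:
            continue
        vals = _glrlm_single(M, n_vox)
        for name in _GLRLM_NAMES:
            acc[name].append(vals[name])
    return {
        f"glrlm_{name}": float(np.mean(v)) if v else 0.0 for name, v in acc.items()
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def size_zone_matrix(levels: np.ndarray) -> np.ndarray:
    """Size-zone count matrix (G x max_zone_size), zones 26-connected."""
    G = int(levels.max())
    if G == 0:
        return np.zeros((0, 0))
    structure = np.ones((3,) * levels.ndim)
    zones: list[tuple[int, int]] = []
    for g in range(1, G + 1):
        lab, n_lab = ndimage.label(levels == g, structure=structure)
        if n_lab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    M = np.zeros((G, max_size))
    for g, s in zones:
        M[g - 1, s - 1] += 1.0
    return M


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    M = size_zone_matrix(levels)
    n_vox = int((levels > 0).sum())
    if M.size == 0 or M.sum() == 0:
        return {f"glszm_{n}": 0.0 for n in _GLSZM_NAMES}
    nz = M.sum()
    G, S = M.shape
    i = np.arange(1, G + 1, dtype=float)[:, None]
    s = np.arange(1, S + 1, dtype=float)[None, :]
    vals = {
        "small_area_emphasis": float((M / s**2).sum() / nz),
        "large_area_emphasis": float((M * s**2).sum() / nz),
        "gray_level_nonuniformity": float((M.sum(axis=1) ** 2).sum() / nz),
        "zone_size_nonuniformity": float((M.sum(axis=0) ** 2).sum() / nz),
        "zone_percentage": float(nz / n_vox),
        "low_gray_level_zone_emphasis": float((M / i**2).sum() / nz),
        "high_gray_level_zone_emphasis": float((M * i**2).sum() / nz),
        "zone_entropy": _entropy_bits(M.ravel() / nz),
    }
    return {f"glszm_{n}": vals[n] for n in _GLSZM_NAMES}


_GLSZM_NAMES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "zone_size_nonuniformity",
    "zone_percentage",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "zone_entropy",
)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _neighbour_mean(levels: np.ndarray):
    """Per-voxel mean level of in-mask 26-neighbours, plus a validity mask."""
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=float)
    offsets = [d for d in _ALL_NEIGHBOUR_OFFSETS if len(d) == levels.ndim] or [
        d for d in itertools.product((-1, 0, 1), repeat=levels.ndim) if any(d)
    ]
    for off in offsets:
        sl_a, sl_b = _overlap_slices(levels.shape, off)
        contrib = np.where(mask[sl_b], levels[sl_b], 0)
        nb_sum[sl_a] += contrib
        nb_cnt[sl_a] += mask[sl_b]
    valid = mask & (nb_cnt > 0)
    mean = np.zeros(levels.shape, dtype=float)
    mean[valid] = nb_sum[valid] / nb_cnt[valid]
    return mean, valid


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """Neighbouring-gray-tone-difference features (coarseness, contrast, ...)."""
    G = int(levels.max())
    names = ("coarseness", "contrast", "busyness", "complexity", "strength")
    if G == 0:
        return {f"ngtdm_{n}": 0.0 for n in names}
    mean, valid = _neighbour_mean(levels)
    lev_v = levels[valid]
    absdiff = np.abs(lev_v - mean[valid])
    n_i = np.bincount(lev_v, minlength=G + 1)[1:].astype(float)
    s_i = np.zeros(G)
    np.add.at(s_i, lev_v - 1, absdiff)
    n_v = n_i.sum()
    p_i = n_i / n_v
    present = p_i > 0
    n_gp = int(present.sum())
    i = np.arange(1, G + 1, dtype=float)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if n_gp > 1:
        pij = np.outer(p_i, p_i)
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = (pij * dij2).sum() / (n_gp * (n_gp - 1)) * (s_i.sum() / n_v)
    else:
        contrast = 0.0

    ip = i * p_i
    busy_den = float(np.abs(ip[present][:, None] - ip[present][None, :]).sum())
    busyness = float((p_i * s_i).sum() / busy_den) if busy_den > 0 else 0.0

    if n_gp > 1:
        pi_p, si_p, i_p = p_i[present], s_i[present], i[present]
        num = np.abs(i_p[:, None] - i_p[None, :]) * (
            (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
            / (pi_p[:, None] + pi_p[None, :])
        )
        complexity = float(num.sum() / n_v)
        strength_num = (
            (pi_p[:, None] + pi_p[None, :]) * (i_p[:, None] - i_p[None, :]) ** 2
        ).sum()
        strength = float(strength_num / s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        complexity = 0.0
        strength = 0.0

    vals = dict(
        coarseness=float(coarseness),
        contrast=float(contrast),
        busyness=busyness,
        complexity=complexity,
        strength=strength,
    )
    return {f"ngtdm_{n}": vals[n] for n in names}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def dependence_matrix(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix (G x max_dependence+1).

    The dependence of a voxel is the number of in-mask 26-neighbours whose
    level differs by at most ``alpha``; column ``j`` holds dependence ``j``
    (so column 0 means "no dependent neighbour").
    """
    mask = levels > 0
    G = int(levels.max())
    if G == 0:
        return np.zeros((0, 0))
    dep = np.zeros(levels.shape, dtype=np.int64)
    offsets = [
        d for d in itertools.product((-1, 0, 1), repeat=levels.ndim) if any(d)
    ]
    for off in offsets:
        sl_a, sl_b = _overlap_slices(levels.shape, off)
        ok = mask[sl_b] & (np.abs(levels[sl_a] - levels[sl_b]) <= alpha)
        dep[sl_a] += ok
    lev_v = levels[mask]
    dep_v = dep[mask]
    M = np.zeros((G, int(dep_v.max()) + 1))
    np.add.at(M, (lev_v - 1, dep_v), 1.0)
    return M


def gldm_features(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    names = (
        "small_dependence_emphasis",
        "large_dependence_emphasis",
        "gray_level_nonuniformity",
        "dependence_nonuniformity",
        "dependence_entropy",
        "low_gray_level_emphasis",
        "high_gray_level_emphasis",
        "dependence_variance",
    )
    M = dependence_matrix(levels, alpha=alpha)
    if M.size == 0 or M.sum() == 0:
        return {f"gldm_{n}": 0.0 for n in names}
    nd = M.sum()
    G, D = M.shape
    i = np.arange(1, G + 1, dtype=float)[:, None]
    j = np.arange(1, D + 1, dtype=float)[None, :]  # dependence+1, per convention
    p = M / nd
    mu_j = float((p * j).sum())
    vals = {
        "small_dependence_emphasis": float((M / j**2).sum() / nd),
        "large_dependence_emphasis": float((M * j**2).sum() / nd),
        "gray_level_nonuniformity": float((M.sum(axis=1) ** 2).sum() / nd),
        "dependence_nonuniformity": float((M.sum(axis=0) ** 2).sum() / nd),
        "dependence_entropy": _entropy_bits(p.ravel()),
        "low_gray_level_emphasis": float((M / i**2).sum() / nd),
        "high_gray_level_emphasis": float((M * i**2).sum() / nd),
        "dependence_variance": float((p * (j - mu_j) ** 2).sum()),
    }
    return {f"gldm_{n}": vals[n] for n in names}


TEXTURE_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "glcm": tuple(f"glcm_{n}" for n in _GLCM_NAMES),
    "glrlm": tuple(f"glrlm_{n}" for n in _GLRLM_NAMES),
    "glszm": tuple(f"glszm_{n}" for n in _GLSZM_NAMES),
    "ngtdm": tuple(f"ngtdm_{n}" for n in ("coarseness", "contrast", "busyness", "complexity", "strength")),
    "gldm": tuple(
        f"gldm_{n}"
        for n in (
            "small_dependence_emphasis",
            "large_dependence_emphasis",
            "gray_level_nonuniformity",
            "dependence_nonuniformity",
            "dependence_entropy",
            "low_gray_level_emphasis",
            "high_gray_level_emphasis",
            "dependence_variance",
        )
    ),
}
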