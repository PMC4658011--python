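"""3-D statistical texture features of parametric maps.

Thirteen features per map per compartment: four first-order statistics (mean,
standard deviation, skewness, kurtosis) of the valid voxel values, and nine
gray-level co-occurrence (GLCM) features computed at a 1-voxel offset and
averaged over the 26 directions of 3-D space after uniform re-quantization to
G = 8 gray levels (3-bit) within the compartment.

GLCM feature definitions, with p(i, j) the normalized pair counts of one
direction, marginals pₓ(i) = Σⱼ p(i,j), p_y(j) = Σᵢ p(i,j), and μₓ, μ_y, σₓ,
σ_y their means and standard deviations:

* energy        = Σ p²
* contrast      = Σ |i − j| · p          (dissimilarity form)
* correlation   = Σ (i − μₓ)(j − μ_y) p / (σₓ σ_y), defined 0 when σₓσ_y = 0
* variance      = Σ (i − μ)² p  with μ = (μₓ + μ_y) / 2
* homogeneity   = Σ p / (1 + |i − j|)
* sum mean      = ½ Σ (i + j) p
* entropy       = −Σ p ln p  (natural log)
* inertia       = Σ (i − j)² p           (classic contrast)
* cluster shade = Σ (i + j − μₓ − μ_y)³ p

Note on contrast vs inertia: in Haralick's original set these coincide; to
keep nine distinct features, inertia keeps the classic squared-difference form
and contrast uses the absolute-difference (dissimilarity) form.  Pair counts
are not symmetrized per direction — averaging over all 26 directions covers
both orientations of every axis.  Directions with no valid pair are dropped
from the average, not counted as zero.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
from scipy import stats

from .errors import EmptyRegionError
from .tables import ALL_STATS, FIRST_ORDER_STATS, GLCM_STATS, MAP_NAMES
from .volume import ParametricMaps

#: the 26 unit offsets of the 3-D neighborhood
DIRECTIONS_26 = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


def first_order_stats(values: np.ndarray) -> dict:
    """Sample mean, std (n−1), Fisher skewness g1, excess kurtosis g2.

    Moments that need more samples than provided (std: 2, skewness: 3,
    kurtosis: 4) — or that are undefined on a constant sample — are returned
    as NaN rather than zero.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        raise EmptyRegionError("first-order statistics need at least one sample")
    out = {"mean": float(x.mean()), "std": np.nan, "skewness": np.nan, "kurtosis": np.nan}
    if n >= 2:
        out["std"] = float(x.std(ddof=1))
    # numerically constant sample: std snaps to 0, 0/0 moments stay missing
    if not out["std"] > 1e-12 * max(1.0, abs(out["mean"])):
        if n >= 2:
            out["std"] = 0.0
        return out
    if n >= 3:
        out["skewness"] = float(stats.skew(x, bias=False))
    if n >= 4:
        out["kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=False))
    return out


def quantize(values: np.ndarray, mask: np.ndarray, levels: int = 8):
    """Uniformly re-quantize a map to ``levels`` gray levels within ``mask``.

    Equal-width bins span [min, max] of the in-mask values; the maximum maps
    to ``levels − 1``.  Returns ``(level_volume, (vmin, vmax))``; a constant
    region quantizes to all zeros with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("quantization mask is empty")
    x = np.asarray(values, dtype=np.float64)
    sample = x[mask]
    if not np.all(np.isfinite(sample)):
        raise EmptyRegionError("quantization input contains non-finite values")
    vmin, vmax = float(sample.min()), float(sample.max())
    q = np.zeros(x.shape, dtype=np.int64)
    if vmax == vmin:
        warnings.warn("constant region: all voxels quantized to level 0", stacklevel=2)
        return q, (vmin, vmax)
    scaled = (x - vmin) / (vmax - vmin) * levels
    q[mask] = np.clip(np.floor(scaled[mask]).astype(np.int64), 0, levels - 1)
    return q, (vmin, vmax)


def glcm_counts(levels_volume: np.ndarray, mask: np.ndarray,
                direction: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Pair-count matrix for one direction: counts of (v(x), v(x+d)) with both
    endpoints inside the mask."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, d in enumerate(direction):
        n = levels_volume.shape[axis]
        if abs(d) >= n:
            return np.zeros((n_levels, n_levels), dtype=np.int64)
        if d > 0:
            src[axis] = slice(0, n - d)
            dst[axis] = slice(d, n)
        elif d < 0:
            src[axis] = slice(-d, n)
            dst[axis] = slice(0, n + d)
    a = levels_volume[tuple(src)]
    b = levels_volume[tuple(dst)]
    both = mask[tuple(src)] & mask[tuple(dst)]
    pairs = a[both] * n_levels + b[both]
    return np.bincount(pairs, minlength=n_levels * n_levels).reshape(n_levels, n_levels)


def glcm_features_from_matrix(p: np.ndarray) -> dict:
    """The nine co-occurrence features of one normalized GLCM ``p``."""
    g = p.shape[0]
    i = np.arange(g, dtype=np.float64)[:, None]
    j = np.arange(g, dtype=np.float64)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(g) * px).sum())
    mu_y = float((np.arange(g) * py).sum())
    sd_x = float(np.sqrt(((np.arange(g) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(g) - mu_y) ** 2 * py).sum()))
    mu = 0.5 * (mu_x + mu_y)

    nz = p[p > 0]
    out = {
        "Energy": float((p**2).sum()),
        "Contrast": float((np.abs(i - j) * p).sum()),
        "Variance": float(((i - mu) ** 2 * p).sum()),
        "Homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "SumMean": float(0.5 * ((i + j) * p).sum()),
        "Entropy": float(-(nz * np.log(nz)).sum()),
        "Inertia": float(((i - j) ** 2 * p).sum()),
        "ClusterShade": float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
    }
    if sd_x * sd_y > 0:
        out["Correlation"] = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y))
    else:
        out["Correlation"] = 0.0
    return out


def glcm_3d(levels_volume: np.ndarray, mask: np.ndarray, n_levels: int = 8,
            directions=DIRECTIONS_26) -> dict:
    """Direction-averaged 3-D GLCM features at a 1-voxel offset.

    Computes the nine features per direction and averages them over the
    directions that contain at least one valid in-mask pair.  Raises when no
    direction has any valid pair.
    """
    mask = np.asarray(mask, dtype=bool)
    per_direction = {}
    for d in directions:
        counts = glcm_counts(levels_volume, mask, d, n_levels)
        total = counts.sum()
        if total == 0:
            continue
        per_direction[d] = glcm_features_from_matrix(counts / total)
    if not per_direction:
        raise EmptyRegionError("no valid co-occurring voxel pair in any direction")
    averaged = {
        name: float(np.mean([f[name] for f in per_direction.values()]))
        for name in GLCM_STATS
    }
    averaged["per_direction"] = per_direction
    return averaged


def extract_compartment_features(
    maps: ParametricMaps,
    mask: np.ndarray,
    compartment: str,
    n_levels: int = 8,
) -> dict:
    """The 39 texture features (13 per parametric map) of one compartment.

    Keys follow the study-export naming convention, e.g.
    ``"parenchyma SER skewness"`` or ``"tumor PE Variance"``.  Per map, only
    voxels valid for that map and inside ``mask`` contribute; quantization
    bounds are the min/max within that region.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError(f"{compartment}: empty mask")
    record = {}
    for map_name in MAP_NAMES:
        region = mask & maps.valid[map_name]
        if not region.any():
            raise EmptyRegionError(f"{compartment} {map_name}: no valid voxels")
        values = maps.maps[map_name]
        fo = first_order_stats(values[region])
        for stat in FIRST_ORDER_STATS:
            record[f"{compartment} {map_name} {stat}"] = fo[stat]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant regions are legitimate here
            q, _ = quantize(values, region, n_levels)
        glcm = glcm_3d(q, region, n_levels)
        for stat in GLCM_STATS:
            record[f"{compartment} {map_name} {stat}"] = glcm[stat]
    assert len(record) == len(MAP_NAMES) * len(ALL_STATS)
    return record
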