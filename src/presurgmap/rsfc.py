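"""Resting-state analysis: ReHo, seed guidance, and seed-based connectivity.

Regional homogeneity (ReHo) scores each voxel by Kendall's coefficient of
concordance W between its time series and its neighbourhood's, computed on
preprocessed but spatially *unsmoothed* data.  Guidance maps for seed
placement can be a task t-map, the ReHo map itself, or the ReHo map confined
to a dilated meta-analysis mask (RH+MA).  Connectivity maps are Pearson
correlations of each voxel against the mean seed time course, reported both
as r and as Fisher z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .glm import DesignMatrix, GLMResult, fit_glm
from .masks import dilate_mask
from .volumes import MaskVolume, StatMap, Volume4D

__all__ = [
    "SeedSpec",
    "FCMap",
    "GuidanceMap",
    "compute_reho",
    "build_rh_ma_guidance",
    "find_local_maxima",
    "seed_timecourse",
    "fc_map",
    "seed_glm",
    "SeedError",
    "FISHER_CLIP",
]

FISHER_CLIP = 1e-7


class SeedError(ValueError):
    """Raised when a seed sphere intersects no usable voxels."""


@dataclass
class SeedSpec:
    """A spherical seed: world-mm center and radius (0 = single voxel)."""

    center_mm: np.ndarray
    radius_mm: float = 0.0

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, float)
        if self.center_mm.shape != (3,):
            raise ValueError("center_mm must be a 3-vector")
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")


@dataclass
class FCMap:
    """Seed connectivity as correlation (r) and Fisher z maps."""

    r: StatMap
    z: StatMap
    seed: SeedSpec


@dataclass
class GuidanceMap:
    """A map used to steer seed placement (task t, ReHo, RH+MA, anatomy)."""

    source: str  # one of task_t, reho, rh_ma, anatomical
    map: StatMap
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("task_t", "reho", "rh_ma", "anatomical"):
            raise ValueError(f"unknown guidance source {self.source!r}")


_FOOTPRINTS = {}


def _footprint(neighborhood: int) -> np.ndarray:
    if neighborhood not in (7, 19, 27):
        raise ValueError("neighborhood must be 7, 19 or 27")
    if neighborhood not in _FOOTPRINTS:
        if neighborhood == 7:
            fp = ndimage.generate_binary_structure(3, 1)
        elif neighborhood == 19:
            fp = ndimage.generate_binary_structure(3, 2)
        else:
            fp = np.ones((3, 3, 3), bool)
        _FOOTPRINTS[neighborhood] = fp
    return _FOOTPRINTS[neighborhood]


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for an (m, n) set of series.

    Each of the m series is ranked across its n timepoints (ties get
    average ranks); W = 12 * sum_t (R_t - mean R)^2 / (m^2 (n^3 - n)) where
    R_t is the rank sum at timepoint t.  W = 1 iff all series are perfectly
    concordant, 0 for complete rank disagreement.
    """
    series = np.atleast_2d(np.asarray(series, float))
    m, n = series.shape
    if n < 3:
        raise ValueError("need at least 3 timepoints for Kendall's W")
    ranks = rankdata(series, axis=1)
    R = ranks.sum(axis=0)
    s = ((R - R.mean()) ** 2).sum()
    return float(12.0 * s / (m ** 2 * (n ** 3 - n)))


def compute_reho(vol: Volume4D, neighborhood: int = 27,
                 mask: MaskVolume | None = None) -> StatMap:
    """Voxel-wise Kendall's W with the 7/19/27-voxel neighbourhood.

    Intended for preprocessed data *before* spatial smoothing (smoothing
    artificially inflates neighbourhood concordance).  Edge voxels use the
    in-mask subset of their neighbourhood; out-of-mask voxels are 0.
    """
    n = vol.n_volumes
    if n < 3:
        raise ValueError("need at least 3 timepoints")
    fp = _footprint(neighborhood).astype(float)
    mask_arr = (mask.data > 0) if mask is not None \
        else np.ones(vol.shape[:3], bool)
    # rank each voxel series across time
    ranks = rankdata(vol.data, axis=3).astype(float)
    ranks[~mask_arr] = 0.0
    # neighbourhood rank sums per timepoint, and per-voxel neighbour counts
    m_count = ndimage.convolve(mask_arr.astype(float), fp, mode="constant")
    R = np.empty_like(ranks)
    for t in range(n):
        R[..., t] = ndimage.convolve(ranks[..., t], fp, mode="constant")
    Rbar = R.mean(axis=3, keepdims=True)
    s = ((R - Rbar) ** 2).sum(axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / (m_count ** 2 * (n ** 3 - n))
    w[~mask_arr] = 0.0
    w = np.clip(np.nan_to_num(w), 0.0, 1.0)
    return StatMap(w, vol.affine, "reho")


def build_rh_ma_guidance(reho: StatMap, meta_mask: MaskVolume,
                         dilate_mm: float = 4.0) -> GuidanceMap:
    """ReHo confined within the (4-mm dilated) meta-analysis mask.

    The dilation allows for functional anatomy displaced by the lesion.
    Voxels outside the dilated mask are zeroed.
    """
    if reho.data.shape != meta_mask.data.shape:
        raise ValueError("meta mask must be on the ReHo grid")
    dil = dilate_mask(meta_mask, dilate_mm)
    data = np.where(dil.data > 0, reho.data, 0.0)
    if not np.any(data > 0):
        warnings.warn("guidance map is empty: meta mask does not intersect "
                      "nonzero ReHo")
    return GuidanceMap("rh_ma", StatMap(data, reho.affine, "reho"),
                       provenance=f"meta mask dilated {dilate_mm} mm")


def find_local_maxima(guide: GuidanceMap, min_separation_mm: float = 0.0
                      ) -> list[tuple[np.ndarray, float]]:
    """26-connected local maxima, strongest first, with spatial suppression.

    A peak within ``min_separation_mm`` (world distance) of a stronger peak
    is dropped.  Constant maps yield no peaks.  Returns a list of
    (world-mm coordinate, value) pairs.
    """
    data = guide.map.data
    if np.ptp(data) == 0:
        return []
    local_max = (data == ndimage.maximum_filter(data, size=3,
                                                mode="constant", cval=-np.inf))
    local_max &= data > data.min()
    coords = np.argwhere(local_max)
    vals = data[local_max]
    order = np.argsort(-vals)
    coords, vals = coords[order], vals[order]
    affine = guide.map.affine
    world = (affine @ np.vstack([coords.T, np.ones(len(coords))]))[:3].T
    kept: list[tuple[np.ndarray, float]] = []
    for w, v in zip(world, vals):
        if all(np.linalg.norm(w - kw) > min_separation_mm
               for kw, _ in kept):
            kept.append((w, float(v)))
    return kept


def _sphere_voxels(vol_shape, affine: np.ndarray,
                   seed: SeedSpec) -> np.ndarray:
    """Indices (N, 3) of voxels whose centers lie within the seed sphere."""
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(seed.center_mm, 1.0))[:3]
    if seed.radius_mm == 0:
        nearest = np.rint(center_vox).astype(int)
        if np.any(nearest < 0) or np.any(nearest >= np.array(vol_shape)):
            raise SeedError("seed voxel outside the volume")
        return nearest[None, :]
    # bound the search box by the radius in voxel units
    from .volumes import voxel_sizes
    vox = voxel_sizes(affine)
    half = np.ceil(seed.radius_mm / vox).astype(int) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.floor(center_vox).astype(int) + half + 1,
                    np.array(vol_shape))
    if np.any(lo >= hi):
        raise SeedError("seed sphere outside the volume")
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    world = (affine @ np.vstack([idx.T, np.ones(len(idx))]))[:3].T
    dist = np.linalg.norm(world - seed.center_mm, axis=1)
    idx = idx[dist <= seed.radius_mm + 1e-9]
    if len(idx) == 0:
        raise SeedError("no voxel centers within the seed sphere")
    return idx


def seed_timecourse(vol: Volume4D, seed: SeedSpec,
                    mask: MaskVolume | None = None) -> np.ndarray:
    """Mean time series over the seed sphere (radius 0 = nearest voxel)."""
    idx = _sphere_voxels(vol.shape[:3], vol.affine, seed)
    if mask is not None:
        keep = mask.data[tuple(idx.T)] > 0
        idx = idx[keep]
        if len(idx) == 0:
            raise SeedError("seed sphere does not intersect the brain mask")
    return vol.data[tuple(idx.T)].mean(axis=0)


def fc_map(vol: Volume4D, seed: SeedSpec,
           mask: MaskVolume | None = None) -> FCMap:
    """Seed-based correlation map with Fisher z transform.

    Pearson r of every in-mask voxel against the mean seed series;
    z = atanh(r) with |r| clipped to 1 - 1e-7 so the map stays finite.
    Zero-variance voxels get r = 0.
    """
    if vol.n_volumes < 10:
        raise ValueError("need at least 10 timepoints for a stable FC map")
    s = seed_timecourse(vol, seed, mask)
    data = vol.data.reshape(-1, vol.n_volumes)
    mask_flat = (mask.data.reshape(-1) > 0) if mask is not None \
        else np.ones(data.shape[0], bool)
    sc = s - s.mean()
    s_norm = np.sqrt((sc ** 2).sum())
    yc = data - data.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((yc ** 2).sum(axis=1))
    r = np.zeros(data.shape[0])
    ok = mask_flat & (y_norm > 0) & (s_norm > 0)
    r[ok] = (yc[ok] @ sc) / (y_norm[ok] * s_norm)
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -(1 - FISHER_CLIP), 1 - FISHER_CLIP))
    z[~mask_flat] = 0.0
    shape = vol.shape[:3]
    return FCMap(
        r=StatMap(r.reshape(shape), vol.affine, "r"),
        z=StatMap(z.reshape(shape), vol.affine, "z"),
        seed=seed)


def seed_glm(vol: Volume4D, seed: SeedSpec,
             nuisance: np.ndarray | None = None,
             mask: MaskVolume | None = None) -> GLMResult:
    """GLM with the seed time course as the regressor of interest.

    An intercept is always included; nuisance columns (e.g. motion) are
    appended.  With no nuisance the t-map relates to the correlation map by
    t = r * sqrt(df / (1 - r^2)).
    """
    s = seed_timecourse(vol, seed, mask)
    if s.std() == 0:
        raise ValueError("seed time course is constant: degenerate regressor")
    n = vol.n_volumes
    cols = [s[:, None], np.ones((n, 1))]
    labels = ["seed", "intercept"]
    if nuisance is not None and np.size(nuisance):
        nuis = np.asarray(nuisance, float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        cols.append(nuis)
        labels += [f"nuis{i}" for i in range(nuis.shape[1])]
    X = DesignMatrix(np.concatenate(cols, axis=1), labels, interest_index=0)
    data = vol.data.reshape(-1, n)
    return fit_glm(data, X, noise_model="ols")
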