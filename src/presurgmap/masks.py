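"""Tissue segmentation and nuisance/whole-brain mask construction.

Segmentation here is an intensity-only 3-class Gaussian mixture over the
T1-weighted histogram (CSF < GM < WM by mean intensity), exposed alongside a
pass-through for externally supplied tissue probability maps.  Nuisance
masks follow the standard recipe: threshold the WM/CSF posterior at 99.9%,
erode one voxel along each axis, exclude lesion voxels, and resample to the
functional grid with nearest-neighbour interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import GeometryError, MaskVolume, Volume3D, voxel_sizes

__all__ = [
    "TissueProbMaps",
    "segment_tissues",
    "make_nuisance_mask",
    "make_wholebrain_mask",
    "dilate_mask",
    "SegmentationError",
]


class SegmentationError(RuntimeError):
    """Raised when the mixture fit cannot separate three tissue classes."""


@dataclass
class TissueProbMaps:
    """Posterior probability maps for CSF, GM and WM on a shared grid."""

    gm: Volume3D
    wm: Volume3D
    csf: Volume3D

    def __post_init__(self) -> None:
        for m in (self.gm, self.wm, self.csf):
            if m.data.min() < -1e-9 or m.data.max() > 1 + 1e-9:
                raise ValueError("probability maps must lie in [0, 1]")
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise GeometryError("tissue maps must share a grid")


def segment_tissues(t1: Volume3D, mask: MaskVolume | None = None,
                    max_iter: int = 200, tol: float = 1e-6,
                    random_state: int = 0) -> TissueProbMaps:
    """3-class Gaussian-mixture segmentation of a T1-weighted volume.

    Classes are ordered by mean intensity, which for T1w contrast maps to
    CSF (dark) < GM < WM (bright).  Voxels outside ``mask`` (or at exactly
    zero intensity when no mask is given) receive zero probability in all
    classes.  Fails with :class:`SegmentationError` when the intensity
    histogram does not support three distinct modes.
    """
    if mask is not None:
        sel = mask.data > 0
    else:
        sel = t1.data > 0
    x = t1.data[sel].astype(float)
    if x.size < 30 or np.ptp(x) == 0:
        raise SegmentationError(
            "too few distinguishable intensities for a 3-class fit; "
            "supply external tissue probability maps instead")
    # init means evenly spaced over the robust intensity range so each
    # tissue mode captures one component regardless of class proportions
    p1, p99 = np.percentile(x, [1, 99])
    mu = p1 + (p99 - p1) * np.array([0.25, 0.5, 0.75])
    if np.unique(mu).size < 3:
        raise SegmentationError(
            "intensity histogram lacks three modes; supply external maps")
    var = np.full(3, x.var() / 4.0)
    pi = np.full(3, 1.0 / 3.0)
    ll_old = -np.inf
    for _ in range(max_iter):
        log_p = (-0.5 * (x[:, None] - mu) ** 2 / var
                 - 0.5 * np.log(2 * np.pi * var) + np.log(pi))
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float((np.log(norm[:, 0]) + m[:, 0]).sum())
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-6):
            raise SegmentationError(
                "a mixture class collapsed; supply external maps")
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-12 * x.var() + 1e-12)
        pi = nk / x.size
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    order = np.argsort(mu)  # CSF, GM, WM by ascending T1w intensity
    maps = []
    for cls in order:
        vol = np.zeros(t1.shape)
        vol[sel] = resp[:, cls]
        maps.append(Volume3D(vol, t1.affine))
    csf, gm, wm = maps
    return TissueProbMaps(gm=gm, wm=wm, csf=csf)


def _erode_once_6conn(mask: np.ndarray) -> np.ndarray:
    """One erosion pass with the face-adjacent (6-connected) cross element."""
    struct = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(mask, structure=struct)


def _nearest_resample_mask(mask: MaskVolume, target_affine: np.ndarray,
                           target_shape) -> MaskVolume:
    idx = np.indices(tuple(target_shape)).reshape(3, -1)
    hom = np.vstack([idx, np.ones((1, idx.shape[1]))])
    src_vox = (np.linalg.inv(mask.affine) @ np.asarray(target_affine, float)
               @ hom)[:3]
    nearest = np.rint(src_vox).astype(int)
    inside = np.all((nearest >= 0)
                    & (nearest < np.array(mask.data.shape)[:, None]), axis=0)
    out = np.zeros(idx.shape[1], dtype=np.uint8)
    out[inside] = mask.data[tuple(nearest[:, inside])]
    return MaskVolume(out.reshape(tuple(target_shape)),
                      np.asarray(target_affine, float))


def make_nuisance_mask(prob: Volume3D, threshold: float = 0.999,
                       lesion: MaskVolume | None = None,
                       target_affine: np.ndarray | None = None,
                       target_shape=None) -> MaskVolume:
    """WM or CSF nuisance mask: threshold -> erode -> lesion-exclude -> resample.

    The probability map is thresholded at 99.9% by default, eroded by one
    voxel along each axis (6-connected element) against partial-volume
    contamination, cleared of lesion voxels when a lesion mask is supplied,
    and finally carried to the functional grid by nearest-neighbour
    resampling.  The order is fixed; see the package methods note.
    """
    if prob.data.min() < -1e-9 or prob.data.max() > 1 + 1e-9:
        raise ValueError("probability map must lie in [0, 1]")
    m = prob.data > threshold
    m = _erode_once_6conn(m)
    if lesion is not None:
        m = m & ~(lesion.data > 0)
    mask = MaskVolume(m.astype(np.uint8), prob.affine)
    if target_affine is not None:
        mask = _nearest_resample_mask(mask, target_affine, target_shape)
    if mask.n_voxels == 0:
        warnings.warn("nuisance mask is empty after erosion/exclusion")
    return mask


def make_wholebrain_mask(tissues: TissueProbMaps,
                         threshold: float = 0.30) -> MaskVolume:
    """Whole-brain mask: sum of GM+WM+CSF probabilities above 30%."""
    total = tissues.gm.data + tissues.wm.data + tissues.csf.data
    return MaskVolume((total > threshold).astype(np.uint8),
                      tissues.gm.affine)


def dilate_mask(mask: MaskVolume, radius_mm: float) -> MaskVolume:
    """Dilate with a spherical element of physical radius ``radius_mm``.

    The sphere is rasterized in voxel units using the voxel sizes from the
    affine, so anisotropic grids dilate by the same physical distance along
    every axis.  Radius 0 is the identity.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if radius_mm == 0:
        return MaskVolume(mask.data.copy(), mask.affine)
    vox = voxel_sizes(mask.affine)
    half = np.floor(radius_mm / vox).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * v
                          for h, v in zip(half, vox)], indexing="ij")
    ball = sum(g ** 2 for g in grids) <= radius_mm ** 2 + 1e-9
    return MaskVolume(
        ndimage.binary_dilation(mask.data > 0, structure=ball)
        .astype(np.uint8),
        mask.affine)
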