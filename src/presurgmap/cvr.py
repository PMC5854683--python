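"""Breath-hold cerebrovascular-reactivity mapping and NVU labeling.

CVR maps come from a delay-swept GLM: the expected respiratory response
(RRF- or HRF-convolved breath-hold paradigm) is shifted over a range of
hemodynamic delays (default -10..15 s), a GLM is fit at each delay, and
each voxel keeps the delay that maximizes its t-statistic.  This absorbs
the regionally varying latency of the vascular response.  Comparing the
thresholded CVR map with the task-fMRI map inside a region of interest
flags voxels where BOLD activation may be missing because the vasculature
cannot respond (neurovascular uncoupling, NVU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .glm import Paradigm, build_design, fit_glm
from .volumes import MaskVolume, StatMap, Volume3D, Volume4D

__all__ = [
    "DelaySweep",
    "CVRResult",
    "NVULabelMap",
    "DisplayComposite",
    "cvr_map",
    "nvu_label",
    "fuse_for_display",
]


@dataclass
class DelaySweep:
    """Ascending hemodynamic delays (s) at which the GLM is repeated."""

    delays: np.ndarray = field(
        default_factory=lambda: np.arange(-10.0, 15.0 + 1e-9, 1.0))

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, float)
        if self.delays.size == 0:
            raise ValueError("delay sweep must be nonempty")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly ascending")

    @classmethod
    def from_range(cls, lo: float = -10.0, hi: float = 15.0,
                   step: float = 1.0) -> "DelaySweep":
        if lo > hi:
            raise ValueError(f"invalid delay range: {lo} > {hi}")
        return cls(np.arange(lo, hi + 1e-9, step))


@dataclass
class CVRResult:
    """Per-voxel max-t, best delay (s) and amplitude at the best delay."""

    tmax: StatMap            # stat_type cvr_t
    best_delay: Volume3D     # seconds
    amplitude: Volume3D      # beta at the best delay, signal units
    df: int
    delays: np.ndarray = field(default_factory=lambda: np.array([0.0]))


def cvr_map(vol: Volume4D, paradigm: Paradigm, irf: str = "rrf",
            sweep: DelaySweep | None = None,
            nuisance: np.ndarray | None = None,
            noise_model: str = "ols") -> CVRResult:
    """Delay-swept GLM with voxel-wise max-t selection.

    For each delay d the paradigm regressor is rebuilt with the blocks
    shifted by d and a GLM is fit; per voxel the delay maximizing t wins
    (ties resolved toward the smallest absolute delay).  Returns the max-t
    map, the winning delay and the amplitude (beta) at that delay.
    """
    sweep = sweep or DelaySweep()
    if abs(paradigm.n_volumes * paradigm.tr - paradigm.total_duration) > 1e-6:
        raise ValueError("paradigm total must match the data duration")
    span = paradigm.onsets[0] + sweep.delays[0]
    last = (paradigm.onsets[-1] + paradigm.durations[-1] + sweep.delays[-1])
    if span < 0 or last > paradigm.total_duration:
        warnings.warn("delay sweep shifts blocks partially outside the "
                      "series; shifted blocks are trimmed to the run")
    shape = vol.shape[:3]
    y = vol.data.reshape(-1, vol.n_volumes)
    n_vox = y.shape[0]
    tmax = np.full(n_vox, -np.inf)
    best_delay = np.zeros(n_vox)
    amplitude = np.zeros(n_vox)
    df = 0
    # visit delays by ascending |d| so strict improvement implements the
    # smallest-|delay| tie-break
    order = np.argsort(np.abs(sweep.delays) + 1e-9 * np.sign(sweep.delays))
    for d in sweep.delays[order]:
        X = build_design(paradigm, irf=irf, nuisance=nuisance, delay_s=d)
        res = fit_glm(y, X, noise_model=noise_model)
        df = res.df
        better = res.tstat > tmax
        tmax[better] = res.tstat[better]
        best_delay[better] = d
        amplitude[better] = res.beta[better, X.interest_index]
    return CVRResult(
        tmax=StatMap(tmax.reshape(shape), vol.affine, "cvr_t"),
        best_delay=Volume3D(best_delay.reshape(shape), vol.affine),
        amplitude=Volume3D(amplitude.reshape(shape), vol.affine),
        df=df,
        delays=sweep.delays.copy())


#: NVU label codes
NVU_NONE, NVU_FMRI_ONLY, NVU_CVR_ONLY, NVU_BOTH = 0, 1, 2, 3


@dataclass
class NVULabelMap:
    """Exhaustive labels inside the ROI: 0 none, 1 fMRI, 2 CVR, 3 both."""

    labels: np.ndarray
    affine: np.ndarray
    fmri_thr: float
    cvr_thr: float
    roi: MaskVolume
    nvu_potential: MaskVolume | None = None
    counts: dict = field(default_factory=dict)


def nvu_label(fmri: StatMap, cvr: CVRResult, fmri_thr: float,
              cvr_thr: float, roi: MaskVolume,
              expected_region: MaskVolume | None = None) -> NVULabelMap:
    """Partition the ROI by which modality exceeds its threshold.

    Code 3 where both the task t-map and the CVR max-t exceed their
    thresholds, 1/2 where only one does, 0 where neither.  When an
    expected-function region is supplied, code-0 voxels inside it are
    reported separately as NVU-potential: a place where activation was
    expected but neither the neural nor the vascular response is seen.
    """
    if fmri.data.shape != cvr.tmax.data.shape \
            or fmri.data.shape != roi.data.shape:
        raise ValueError("fmri, cvr and roi must share a grid")
    in_roi = roi.data > 0
    f = fmri.data > fmri_thr
    c = cvr.tmax.data > cvr_thr
    labels = np.zeros(fmri.data.shape, dtype=np.uint8)
    labels[in_roi & f & ~c] = NVU_FMRI_ONLY
    labels[in_roi & ~f & c] = NVU_CVR_ONLY
    labels[in_roi & f & c] = NVU_BOTH
    counts = {code: int(((labels == code) & in_roi).sum())
              for code in (NVU_NONE, NVU_FMRI_ONLY, NVU_CVR_ONLY, NVU_BOTH)}
    nvu_pot = None
    if expected_region is not None:
        pot = in_roi & (expected_region.data > 0) & (labels == NVU_NONE)
        nvu_pot = MaskVolume(pot.astype(np.uint8), fmri.affine)
        counts["nvu_potential"] = int(pot.sum())
    return NVULabelMap(labels, fmri.affine, fmri_thr, cvr_thr, roi,
                       nvu_pot, counts)


@dataclass
class DisplayComposite:
    """RGB fusion of anatomy, task activation and CVR for visual review."""

    rgb: np.ndarray            # (x, y, z, 3) in [0, 1]
    fmri_mask: MaskVolume
    cvr_mask: MaskVolume
    cvr_contour: MaskVolume


def _hot_colors(values: np.ndarray) -> np.ndarray:
    """Red-to-yellow 'hot' scale for normalized magnitudes in [0, 1]."""
    v = np.clip(values, 0.0, 1.0)
    rgb = np.zeros(v.shape + (3,))
    rgb[..., 0] = 1.0
    rgb[..., 1] = v
    return rgb


def fuse_for_display(underlay: Volume3D, fmri: StatMap, cvr: CVRResult,
                     fmri_thr: float, cvr_thr: float,
                     cvr_alpha: float = 0.4) -> DisplayComposite:
    """Burn task activation (hot scale) and CVR (translucent blue + contour)
    into the anatomical underlay.

    The CVR region is shown as a translucent blue wash with a solid blue
    boundary contour; fMRI suprathreshold voxels are painted on top with a
    red-to-yellow scale.  Rendering is a pure function of its inputs.
    """
    if underlay.data.shape != fmri.data.shape \
            or underlay.data.shape != cvr.tmax.data.shape:
        raise ValueError("underlay, fmri and cvr must share a grid")
    u = underlay.data.astype(float)
    span = np.ptp(u)
    gray = (u - u.min()) / span if span > 0 else np.zeros_like(u)
    rgb = np.repeat(gray[..., None], 3, axis=3)

    c_mask = cvr.tmax.data > cvr_thr
    contour = c_mask & ~ndimage.binary_erosion(
        c_mask, structure=ndimage.generate_binary_structure(3, 1))
    # translucent blue wash over the CVR region
    blue = np.array([0.1, 0.3, 1.0])
    rgb[c_mask] = (1 - cvr_alpha) * rgb[c_mask] + cvr_alpha * blue
    rgb[contour] = blue

    f_mask = fmri.data > fmri_thr
    if f_mask.any():
        fvals = fmri.data[f_mask]
        lo, hi = fmri_thr, max(float(fvals.max()), fmri_thr + 1e-12)
        rgb[f_mask] = _hot_colors((fvals - lo) / (hi - lo))
    return DisplayComposite(
        rgb=np.clip(rgb, 0.0, 1.0),
        fmri_mask=MaskVolume(f_mask.astype(np.uint8), underlay.affine),
        cvr_mask=MaskVolume(c_mask.astype(np.uint8), underlay.affine),
        cvr_contour=MaskVolume(contour.astype(np.uint8), underlay.affine))
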