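"""Temporal and spatial preprocessing of 4D BOLD data.

The pipeline pieces here mirror the standard clinical-fMRI recipe: pick the
least-corrupted timepoint as the motion reference, slice-timing correct,
rigid-body motion correct, align the functional series to the T1-weighted
anatomy (coordinate-based or intensity-based), and compose all spatial maps
so the data are interpolated exactly once.  Temporal cleanup (despiking,
detrending, nuisance regression and band-pass filtering) operates on voxel
time series.

Conventions
-----------
* ``RigidTransform`` objects are *pull-back* maps: resampling a moving
  volume with transform ``T`` evaluates the moving image at world
  coordinate ``T @ x`` for each target-grid world coordinate ``x``.
* Trilinear interpolation is used inside optimization loops; the final
  resample uses a 5-lobe Hann-windowed sinc kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import norm

from .volumes import (
    GeometryError,
    MaskVolume,
    RigidTransform,
    Volume3D,
    Volume4D,
    voxel_sizes,
)

__all__ = [
    "OutlierProfile",
    "PreprocessConfig",
    "outlier_threshold_factor",
    "count_outliers",
    "select_reference_volume",
    "slice_timing_correct",
    "motion_correct",
    "align_cbr",
    "align_ibr",
    "resample_once",
    "resample_to_iso",
    "resample_volume",
    "despike",
    "project_nuisance",
    "smooth_gaussian",
    "legendre_basis",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Outlier rule and reference-volume selection

def outlier_threshold_factor(n_timepoints: int) -> float:
    """MAD multiplier of the outlier deviation limit for an n-point series.

    The limit corresponds to a two-sided Gaussian tail of 0.001/n converted
    from standard deviations to MAD units:

        kappa(n) = Phi^-1(1 - 0.001/n) * sqrt(pi/2)

    which evaluates to roughly 5.5 for series of 50-500 timepoints.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    return float(norm.ppf(1.0 - 0.001 / n_timepoints) * np.sqrt(np.pi / 2.0))


def _lad_linear_trend(y: np.ndarray, max_iter: int = 60,
                      tol: float = 1e-10) -> np.ndarray:
    """Least-absolute-deviations straight-line trend, vectorized over rows.

    y is (n_series, n_time); returns fitted trend of the same shape.
    Solved by iteratively reweighted least squares on the 2-column basis
    [1, t]; the per-series 2x2 normal equations are inverted in closed form.
    """
    y = np.atleast_2d(np.asarray(y, float))
    n = y.shape[1]
    t = np.linspace(-1.0, 1.0, n)
    X = np.stack([np.ones(n), t], axis=1)  # (n, 2)
    w = np.ones_like(y)
    eps = 1e-8 * max(1.0, float(np.abs(y).max()))
    beta_old = None
    for _ in range(max_iter):
        # weighted normal equations per series
        a00 = w.sum(axis=1)
        a01 = (w * t).sum(axis=1)
        a11 = (w * t * t).sum(axis=1)
        b0 = (w * y).sum(axis=1)
        b1 = (w * y * t).sum(axis=1)
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        c0 = (a11 * b0 - a01 * b1) / det
        c1 = (a00 * b1 - a01 * b0) / det
        beta = np.stack([c0, c1], axis=1)
        if beta_old is not None and np.max(np.abs(beta - beta_old)) < tol:
            break
        beta_old = beta
        resid = y - beta @ X.T
        w = 1.0 / np.maximum(np.abs(resid), eps)
    return beta @ X.T


def _outlier_mask(ts_matrix: np.ndarray, kappa: float) -> np.ndarray:
    """Boolean (n_series, n_time) outlier flags from the robust-trend rule."""
    y = np.atleast_2d(np.asarray(ts_matrix, float))
    trend = _lad_linear_trend(y)
    resid = y - trend
    mad = np.median(np.abs(resid), axis=1, keepdims=True)
    limit = kappa * mad
    # MAD == 0 (e.g. constant series) -> nothing can exceed the limit
    return (np.abs(resid) > limit) & (mad > 0)


def count_outliers(ts: np.ndarray, kappa: float) -> int:
    """Count samples deviating from a robust linear trend by > kappa * MAD."""
    ts = np.asarray(ts, float)
    if ts.ndim != 1 or ts.size < 3:
        raise ValueError("need a 1D series of length >= 3")
    return int(_outlier_mask(ts[None, :], kappa)[0].sum())


@dataclass
class OutlierProfile:
    """Per-timepoint outlier-voxel counts and the chosen reference index."""

    counts: np.ndarray
    kappa: float
    reference_index: int


def select_reference_volume(vol: Volume4D,
                            mask: MaskVolume | None = None) -> OutlierProfile:
    """Pick the timepoint with the fewest outlier voxels (ties -> smallest).

    Outliers are computed per voxel time series with the default
    ``outlier_threshold_factor`` rule; ``counts[t]`` is the number of voxels
    flagged at timepoint ``t``.
    """
    n_t = vol.n_volumes
    if n_t == 1:
        return OutlierProfile(np.zeros(1, int), np.inf, 0)
    kappa = outlier_threshold_factor(n_t)
    data = vol.data.reshape(-1, n_t)
    if mask is not None:
        data = data[mask.data.reshape(-1) > 0]
    counts = np.zeros(n_t, dtype=int)
    # chunk voxels to bound the IRLS working-set memory
    for start in range(0, data.shape[0], 4096):
        flags = _outlier_mask(data[start:start + 4096], kappa)
        counts += flags.sum(axis=0)
    ref = int(np.argmin(counts))
    return OutlierProfile(counts, kappa, ref)


# ---------------------------------------------------------------------------
# Slice-timing correction

def slice_timing_correct(vol: Volume4D) -> Volume4D:
    """Resample each slice's series to the start of its TR by Fourier shift.

    A slice acquired at offset ``s`` within the TR is shifted back by ``s``
    seconds using the shift theorem applied to the FFT of each voxel series,
    so all slices refer to a common acquisition time (t = 0 of each TR).
    """
    if vol.slice_times is None:
        raise ValueError("slice_times required for slice-timing correction")
    n_t = vol.n_volumes
    freqs = np.fft.rfftfreq(n_t, d=vol.tr)
    out = np.empty_like(vol.data)
    for z in range(vol.shape[2]):
        shift = float(vol.slice_times[z])
        if shift == 0.0:
            out[:, :, z, :] = vol.data[:, :, z, :]
            continue
        spec = np.fft.rfft(vol.data[:, :, z, :], axis=-1)
        phase = np.exp(-2j * np.pi * freqs * shift)
        if n_t % 2 == 0:
            phase[-1] = phase[-1].real  # keep the Nyquist bin real
        out[:, :, z, :] = np.fft.irfft(spec * phase, n=n_t, axis=-1)
    return Volume4D(out, vol.affine, vol.tr, np.zeros(vol.shape[2]))


# ---------------------------------------------------------------------------
# Interpolation kernels

def _trilinear(data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at fractional voxel coords (3, N)."""
    return ndimage.map_coordinates(data, coords, order=1, mode="constant",
                                   cval=0.0)


_WSINC_RADIUS = 5


def _wsinc_kernel(frac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """5-lobe Hann-windowed sinc taps for fractional offsets (N,).

    Returns (offsets (2R,), weights (N, 2R)) with weights normalized to
    unit sum so constants are reproduced exactly.
    """
    r = _WSINC_RADIUS
    offs = np.arange(-r + 1, r + 1)  # 2R taps around the sample
    x = offs[None, :] - frac[:, None]
    w = np.sinc(x) * (0.5 + 0.5 * np.cos(np.pi * np.clip(x / r, -1, 1)))
    w /= w.sum(axis=1, keepdims=True)
    return offs, w


def _wsinc_interp(data: np.ndarray, coords: np.ndarray,
                  chunk: int = 2048) -> np.ndarray:
    """Windowed-sinc interpolation of ``data`` at voxel coords (3, N).

    Out-of-volume taps use edge clamping; points whose nearest voxel lies
    outside the grid return 0.
    """
    shape = data.shape
    n = coords.shape[1]
    out = np.empty(n)
    inside = np.all((coords >= -0.5) &
                    (coords <= np.array(shape)[:, None] - 0.5), axis=0)
    flat = data.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    for start in range(0, n, chunk):
        c = coords[:, start:start + chunk]
        base = np.floor(c).astype(int)
        frac = c - base
        offs, wx = _wsinc_kernel(frac[0])
        _, wy = _wsinc_kernel(frac[1])
        _, wz = _wsinc_kernel(frac[2])
        ix = np.clip(base[0][:, None] + offs[None, :], 0, shape[0] - 1)
        iy = np.clip(base[1][:, None] + offs[None, :], 0, shape[1] - 1)
        iz = np.clip(base[2][:, None] + offs[None, :], 0, shape[2] - 1)
        # separable gather: contract z, then y, then x
        idx = (ix[:, :, None, None] * strides[0]
               + iy[:, None, :, None] * strides[1]
               + iz[:, None, None, :] * strides[2])
        vals = flat[idx.reshape(idx.shape[0], -1)].reshape(idx.shape)
        acc = np.einsum("nxyz,nz->nxy", vals, wz)
        acc = np.einsum("nxy,ny->nx", acc, wy)
        out[start:start + chunk] = np.einsum("nx,nx->n", acc, wx)
    out[~inside] = 0.0
    return out


def _grid_world_coords(shape, affine) -> np.ndarray:
    """(4, N) homogeneous world coordinates of every voxel center."""
    idx = np.indices(shape).reshape(3, -1)
    hom = np.vstack([idx, np.ones((1, idx.shape[1]))])
    return np.asarray(affine, float) @ hom


def resample_volume(moving: Volume3D, transform: RigidTransform,
                    grid_affine: np.ndarray, grid_shape,
                    method: str = "wsinc") -> Volume3D:
    """Resample ``moving`` onto a target grid through a pull-back transform.

    For each target voxel center x (world), the moving image is evaluated at
    ``transform.matrix @ x``.
    """
    world = _grid_world_coords(tuple(grid_shape), grid_affine)
    src_world = transform.matrix @ world
    try:
        inv_aff = np.linalg.inv(moving.affine)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise GeometryError("moving affine not invertible") from exc
    vox = (inv_aff @ src_world)[:3]
    interp = _wsinc_interp if method == "wsinc" else _trilinear
    data = interp(moving.data, vox).reshape(tuple(grid_shape))
    return Volume3D(data, grid_affine)


# ---------------------------------------------------------------------------
# Motion correction (rigid, 6-parameter)

#: lever arm (mm) equating a unit rotation step to a unit translation step
#: in the optimizer's parameter space; roughly the head radius
_ROT_SCALE_MM = 50.0


def _register_rigid(moving: Volume3D, reference: Volume3D,
                    x0: np.ndarray | None = None,
                    fast: bool = False) -> tuple[RigidTransform, bool]:
    """Least-squares rigid registration of ``moving`` to ``reference``.

    Two-stage Powell search over the 6 parameters: a capture stage on
    lightly smoothed images with trilinear interpolation, then a
    refinement stage on the original images with a cubic-spline
    interpolant (the moving image is spline-prefiltered once).  Rotations
    are rescaled so one optimizer step moves the object surface by about
    the same distance as a 1 mm translation.
    """
    ref_flat = reference.data.ravel()
    world = _grid_world_coords(reference.data.shape, reference.affine)
    inv_aff = np.linalg.inv(moving.affine)
    x0 = np.zeros(6) if x0 is None else np.asarray(x0, float)
    scale = np.array([_ROT_SCALE_MM] * 3 + [1.0] * 3)

    mov_smooth = ndimage.gaussian_filter(moving.data, 1.0)
    ref_smooth = ndimage.gaussian_filter(reference.data, 1.0).ravel()
    mov_spline = ndimage.spline_filter(moving.data, order=3)

    def vox_coords(p):
        return (inv_aff @ (RigidTransform(p).matrix @ world))[:3]

    def cost_capture(p_scaled):
        vals = _trilinear(mov_smooth, vox_coords(p_scaled / scale))
        return float(np.mean((vals - ref_smooth) ** 2))

    def cost_refine(p_scaled):
        vals = ndimage.map_coordinates(mov_spline, vox_coords(p_scaled / scale),
                                       order=3, prefilter=False,
                                       mode="constant")
        return float(np.mean((vals - ref_flat) ** 2))

    # ``fast`` trims the evaluation budget for warm starts (consecutive
    # frames of one run); cold starts keep the full search
    opts1 = {"xtol": 1e-2, "ftol": 1e-6, "maxiter": 3 if fast else 10}
    opts2 = {"xtol": 1e-4, "ftol": 1e-9, "maxiter": 8}
    if fast:
        opts1["maxfev"] = 120
        opts2["maxfev"] = 300
    stage1 = optimize.minimize(cost_capture, x0 * scale, method="Powell",
                               options=opts1)
    stage2 = optimize.minimize(cost_refine, stage1.x, method="Powell",
                               options=opts2)
    # usable iff finite and no worse than where it started (hitting the
    # iteration cap with an improved cost still counts as converged)
    ok = np.all(np.isfinite(stage2.x)) \
        and stage2.fun <= cost_refine(x0 * scale) + 1e-12
    return RigidTransform(stage2.x / scale), bool(ok)


def motion_correct(vol: Volume4D, reference_index: int
                   ) -> tuple[Volume4D, list[RigidTransform]]:
    """Register every timepoint to the reference volume (6-dof rigid).

    Returns the realigned series (trilinear resample; use
    :func:`resample_once` to compose with an anatomical alignment for the
    single-interpolation output) and the per-timepoint transforms.
    Non-converged fits fall back to the identity transform.
    """
    n_t = vol.n_volumes
    if not 0 <= reference_index < n_t:
        raise ValueError(f"reference_index {reference_index} out of range "
                         f"[0, {n_t})")
    reference = vol.frame(reference_index)
    transforms: list[RigidTransform] = []
    out = np.empty_like(vol.data)
    prev = np.zeros(6)
    for t in range(n_t):
        if t == reference_index:
            tf = RigidTransform.identity()
        else:
            # warm start: consecutive frames move little, so later frames
            # can use a trimmed evaluation budget
            warm = t != (0 if reference_index != 0 else 1)
            tf, ok = _register_rigid(vol.frame(t), reference, x0=prev,
                                     fast=warm)
            if not ok:
                warnings.warn(f"motion correction did not converge at "
                              f"timepoint {t}; using identity")
                tf = RigidTransform.identity()
            prev = tf.params.copy()  # warm start: motion is usually slow
        transforms.append(tf)
        out[..., t] = resample_volume(vol.frame(t), tf, vol.affine,
                                      vol.shape[:3], method="trilinear").data
    return Volume4D(out, vol.affine, vol.tr, vol.slice_times), transforms


# ---------------------------------------------------------------------------
# Alignment to T1w

def _iso_grid(vol: Volume3D, iso_mm: float) -> tuple[np.ndarray, tuple]:
    """Target affine/shape covering ``vol``'s field of view at iso_mm."""
    corners = np.array([[i, j, k, 1.0]
                        for i in (0, vol.shape[0] - 1)
                        for j in (0, vol.shape[1] - 1)
                        for k in (0, vol.shape[2] - 1)])
    world = (vol.affine @ corners.T)[:3]
    lo, hi = world.min(axis=1), world.max(axis=1)
    shape = tuple(int(np.floor((h - l) / iso_mm)) + 1
                  for l, h in zip(lo, hi))
    affine = np.diag([iso_mm, iso_mm, iso_mm, 1.0])
    affine[:3, 3] = lo
    return affine, shape


def resample_to_iso(vol: Volume3D, iso_mm: float,
                    method: str = "wsinc") -> Volume3D:
    """Resample a 3D volume onto an axis-aligned isotropic RAS grid."""
    affine, shape = _iso_grid(vol, iso_mm)
    return resample_volume(vol, RigidTransform.identity(), affine, shape,
                           method=method)


def align_cbr(vol: Volume4D, t1: Volume3D, target_iso_mm: float) -> Volume4D:
    """Coordinate-based alignment: resample onto the T1w isotropic grid.

    No transform is estimated; the scanner header affines alone carry the
    functional data onto the anatomical grid.  ``t1`` must already live on
    the isotropic target grid (see :func:`resample_to_iso`).
    """
    if target_iso_mm not in (2, 3):
        raise ValueError("target_iso_mm must be 2 or 3")
    vox = voxel_sizes(t1.affine)
    if not np.allclose(vox, target_iso_mm, atol=1e-6):
        raise GeometryError(
            f"t1 grid is {vox} mm, expected {target_iso_mm} mm isotropic; "
            "resample it first with resample_to_iso")
    out = np.empty(t1.shape + (vol.n_volumes,))
    ident = RigidTransform.identity()
    for t in range(vol.n_volumes):
        out[..., t] = resample_volume(vol.frame(t), ident, t1.affine,
                                      t1.shape).data
    return Volume4D(out, t1.affine, vol.tr, None)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = hist / hist.sum()
    hx = _entropy(pxy.sum(axis=1))
    hy = _entropy(pxy.sum(axis=0))
    hxy = _entropy(pxy.ravel())
    if hxy == 0:
        raise ValueError("degenerate (constant) image: NMI undefined")
    return (hx + hy) / hxy


def align_ibr(epi_ref: Volume3D, t1: Volume3D,
              bins: int = 32) -> RigidTransform:
    """Intensity-based rigid alignment by normalized-mutual-information.

    Maximizes NMI of the EPI reference against the T1w over a joint
    histogram (default 32x32 bins) with Powell search, multi-started at
    +/-5 mm translations along each axis to escape local optima.  The
    returned transform maps T1-grid world coordinates into EPI world
    coordinates (pull-back), ready to compose with motion transforms for a
    single final interpolation.
    """
    if np.ptp(epi_ref.data) == 0 or np.ptp(t1.data) == 0:
        raise ValueError("degenerate (constant) image: registration "
                         "cost undefined")
    world = _grid_world_coords(t1.shape, t1.affine)
    inv_epi = np.linalg.inv(epi_ref.affine)
    t1_flat = t1.data.ravel()

    def neg_nmi(p):
        vox = (inv_epi @ (RigidTransform(p).matrix @ world))[:3]
        vals = _trilinear(epi_ref.data, vox)
        return -_nmi(vals, t1_flat, bins=bins)

    starts = [np.zeros(6)]
    for axis in range(3):
        for sign in (-5.0, 5.0):
            s = np.zeros(6)
            s[3 + axis] = sign
            starts.append(s)
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_nmi, x0, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-8,
                                         "maxiter": 30})
        if best is None or res.fun < best.fun:
            best = res
    return RigidTransform(best.x)


def resample_once(vol: Volume4D, motion: list[RigidTransform],
                  align: RigidTransform, grid_affine: np.ndarray,
                  grid_shape) -> Volume4D:
    """Apply motion + anatomical alignment in one windowed-sinc interpolation.

    For timepoint t the composite pull-back is ``motion[t] o align``: a
    target-grid world coordinate is first carried into the EPI reference
    frame by ``align``, then into the original frame-t space by the motion
    transform.  Each original volume is therefore interpolated exactly once.
    """
    if len(motion) != vol.n_volumes:
        raise ValueError("one motion transform per timepoint required")
    out = np.empty(tuple(grid_shape) + (vol.n_volumes,))
    for t in range(vol.n_volumes):
        composite = motion[t].compose(align)
        out[..., t] = resample_volume(vol.frame(t), composite,
                                      grid_affine, grid_shape).data
    return Volume4D(out, np.asarray(grid_affine, float), vol.tr, None)


# ---------------------------------------------------------------------------
# Despiking

DESPIKE_C1 = 2.5
DESPIKE_C2 = 4.0


def despike(ts: np.ndarray, c1: float = DESPIKE_C1,
            c2: float = DESPIKE_C2) -> np.ndarray:
    """Compress spike residuals with a saturating tanh transform.

    A robust smooth trend (least-absolute-deviations quartic Legendre fit)
    is computed per series; residuals are scaled by a MAD-based sigma.
    Samples within ``c1`` sigma pass through untouched; beyond that the
    residual is compressed to ``c1 + (c2 - c1) * tanh((s - c1)/(c2 - c1))``
    sigma, so no despiked sample exceeds ``c2`` sigma from the trend.

    Accepts a single series or an (n_series, n_time) matrix (vectorized).
    """
    ts = np.asarray(ts, float)
    single = ts.ndim == 1
    y = np.atleast_2d(ts)
    n = y.shape[1]
    if n < 5:
        raise ValueError("need series of length >= 5")
    x = np.linspace(-1.0, 1.0, n)
    order = min(4, n - 2)
    cols = [np.polynomial.legendre.legvander(x, order)]
    # low-frequency harmonics let the trend follow smooth signal so only
    # genuine transients show up in the residual
    n_harm = min(max(3, n // 30), max(0, (n - order - 1) // 4))
    tt = np.arange(n)
    for kh in range(1, n_harm + 1):
        ang = 2.0 * np.pi * kh * tt / n
        cols.append(np.stack([np.sin(ang), np.cos(ang)], axis=1))
    B = np.concatenate(cols, axis=1)  # (n, p)
    p = B.shape[1]
    w = np.ones_like(y)
    eps = 1e-8 * np.maximum(1.0, np.abs(y).max(axis=1, keepdims=True))
    # fixed iteration count keeps batched and single-series calls identical
    for _ in range(30):
        # per-series weighted normal equations, batched
        wB = w[:, :, None] * B  # (v, t, p)
        A = np.matmul(wB.transpose(0, 2, 1), B[None])
        b = (w * y) @ B
        A += 1e-12 * np.eye(p)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        resid = y - beta @ B.T
        w = 1.0 / np.maximum(np.abs(resid), eps)
    trend = beta @ B.T
    resid = y - trend
    sigma = np.median(np.abs(resid), axis=1, keepdims=True) / 0.6745
    out = y.copy()
    # a sigma far below the series range means the residuals are at the
    # level of fit error, not physiology: treat such rows as spike-free
    ok = sigma[:, 0] > 1e-4 * np.ptp(y, axis=1)
    if np.any(ok):
        s = np.zeros_like(resid)
        s[ok] = resid[ok] / sigma[ok]
        hot = np.abs(s) > c1
        s_hot = np.abs(s[hot])
        s_new = c1 + (c2 - c1) * np.tanh((s_hot - c1) / (c2 - c1))
        out[hot] = (trend[hot]
                    + np.sign(s[hot]) * s_new * np.broadcast_to(sigma, s.shape)[hot])
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Joint detrend + nuisance + band-pass projection

def legendre_basis(n: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns, orders 0..order, on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(x, order)


def _bandstop_basis(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Cos/sin columns for every DFT frequency bin outside the pass band."""
    f_low, f_high = band
    nyq = 0.5 / tr
    if not 0 <= f_low < f_high < nyq:
        raise ValueError(f"band {band} must satisfy 0 <= f_low < f_high < "
                         f"Nyquist ({nyq:.4g} Hz)")
    freqs = np.fft.rfftfreq(n, d=tr)
    t = np.arange(n)
    cols = []
    for i, f in enumerate(freqs):
        if i == 0 or (f_low <= f <= f_high):
            continue  # DC handled by the polynomial block; pass band kept
        ang = 2.0 * np.pi * i * t / n
        cols.append(np.cos(ang))
        if i != n // 2 or n % 2 == 1:
            cols.append(np.sin(ang))
    if not cols:
        return np.empty((n, 0))
    return np.stack(cols, axis=1)


def project_nuisance(ts_matrix: np.ndarray,
                     regressors: np.ndarray | None,
                     band: tuple[float, float] | None,
                     detrend_order: int = 2,
                     tr: float = 1.0) -> np.ndarray:
    """Remove drift, nuisance regressors and out-of-band frequencies jointly.

    All removal bases - Legendre drift terms up to ``detrend_order``, the
    nuisance regressor columns, and cos/sin pairs for every frequency bin
    outside ``band`` - are assembled into one matrix, and the voxel time
    series are residualized against it with a single orthogonal projection.
    Doing everything in one step prevents the nuisance regression from
    reintroducing frequencies the band-pass removed, and makes the operation
    idempotent.

    Parameters
    ----------
    ts_matrix : (n_voxels, n_time) array
    regressors : (n_time, k) array or None
    band : (f_low, f_high) in Hz, or None for no temporal filter
    detrend_order : Legendre polynomial order (0 = mean removal only)
    tr : sampling interval in seconds (needed when band is given)
    """
    y = np.atleast_2d(np.asarray(ts_matrix, float))
    n = y.shape[1]
    blocks = [legendre_basis(n, detrend_order)]
    if regressors is not None and np.size(regressors):
        reg = np.asarray(regressors, float)
        if reg.ndim == 1:
            reg = reg[:, None]
        if reg.shape[0] != n:
            raise ValueError("regressor rows must equal n_time")
        blocks.append(reg)
    if band is not None:
        blocks.append(_bandstop_basis(n, tr, band))
    basis = np.concatenate(blocks, axis=1)
    # orthonormalize via SVD; duplicated columns collapse to one direction
    u, s, _ = np.linalg.svd(basis, full_matrices=False)
    rank = int((s > 1e-10 * s.max()).sum())
    if rank < basis.shape[1]:
        warnings.warn(f"removal basis rank-deficient: {basis.shape[1] - rank}"
                      " duplicated column(s) collapsed")
    q = u[:, :rank]
    return y - (y @ q) @ q.T


# ---------------------------------------------------------------------------
# Spatial smoothing

def smooth_gaussian(vol, fwhm_mm: float):
    """Isotropic Gaussian smoothing with a kernel width given in mm FWHM.

    Applies sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel
    units through the affine.  4D inputs are smoothed frame by frame.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return vol
    sigmas = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes(vol.affine)
    if isinstance(vol, Volume4D):
        out = np.empty_like(vol.data)
        for t in range(vol.n_volumes):
            out[..., t] = ndimage.gaussian_filter(vol.data[..., t], sigmas)
        return Volume4D(out, vol.affine, vol.tr, vol.slice_times)
    return Volume3D(ndimage.gaussian_filter(vol.data, sigmas), vol.affine)


@dataclass
class PreprocessConfig:
    """Preprocessing options shared by the three pipeline modes."""

    target_iso_mm: int = 2
    fwhm_mm: float = 4.0
    band: tuple[float, float] | None = (0.01, 0.08)
    detrend_order: int = 2
    steps: tuple[str, ...] = ("slice_timing", "moco", "cbr", "despike",
                              "detrend", "nuisance", "bandpass", "smooth")

    def __post_init__(self) -> None:
        if self.target_iso_mm not in (2, 3):
            raise ValueError("target_iso_mm must be 2 or 3")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
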