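"""Design-matrix construction and voxel-wise GLM fitting.

Task activation maps come from fitting each voxel's time series to an
expected response built by convolving an impulse response (the canonical
double-gamma HRF for neural tasks, the respiration response function for
breath-hold challenges) with the block paradigm.  Serial correlation in the
residuals is handled by generalized least squares with an ARMA(1,1) noise
model estimated per voxel on a discrete (a, b) grid, in the spirit of the
standard prewhitening tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .volumes import MaskVolume, StatMap

__all__ = [
    "Paradigm",
    "DesignMatrix",
    "GLMResult",
    "build_block_paradigm",
    "hrf_canonical",
    "rrf",
    "build_design",
    "fit_glm",
    "t_threshold_map",
    "t_to_p",
]


@dataclass
class Paradigm:
    """A block paradigm: onsets/durations in seconds on a TR grid."""

    onsets: np.ndarray
    durations: np.ndarray
    total_duration: float
    tr: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, float)
        self.durations = np.asarray(self.durations, float)
        if self.onsets.size != self.durations.size:
            raise ValueError("onsets and durations must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.onsets + self.durations > self.total_duration + 1e-9):
            raise ValueError("a block extends past total_duration")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.tr))


def build_block_paradigm(initial_rest: float, task_s: float, rest_s: float,
                         cycles: int, tr: float,
                         drop_final_rest: bool = False) -> Paradigm:
    """Standard clinical block design: initial rest, then task/rest cycles.

    Onsets fall at ``initial_rest + i * (task_s + rest_s)``; with
    ``drop_final_rest`` the trailing rest interval is omitted from the total
    (sentence-completion style).  The total duration must be an integer
    number of TRs.
    """
    if min(initial_rest, task_s, rest_s, tr) <= 0 or cycles < 1:
        raise ValueError("durations must be positive and cycles >= 1")
    onsets = initial_rest + np.arange(cycles) * (task_s + rest_s)
    total = initial_rest + cycles * (task_s + rest_s)
    if drop_final_rest:
        total -= rest_s
    remainder = total % tr
    if min(remainder, tr - remainder) > 1e-9:
        raise ValueError(f"total duration {total} s is not a multiple of "
                         f"TR {tr} s (remainder {remainder:.6g} s)")
    return Paradigm(onsets, np.full(cycles, task_s), total, tr)


def hrf_canonical(t_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak.

    Difference of two gamma densities with peak delay 6 s, undershoot delay
    16 s, unit dispersions, and a 6:1 peak-to-undershoot ratio; the positive
    lobe peaks near 5 s and a shallow undershoot follows out to ~25 s.
    """
    t = np.asarray(t_grid, float)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    from scipy.stats import gamma as gamma_dist
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    dense = np.linspace(0, 32, 3201)  # peak found on a dense grid
    peak = (gamma_dist.pdf(dense, 6.0)
            - gamma_dist.pdf(dense, 16.0) / 6.0).max()
    return h / peak


def rrf(t_grid: np.ndarray) -> np.ndarray:
    """Respiration response function (breath-to-breath BOLD impulse response).

        r(t) = 0.6 t^2.1 e^(-t/1.6) - 0.0023 t^3.54 e^(-t/4.25)

    Early positive peak near 3 s, prolonged negative undershoot out past
    15 s; used as the impulse response for breath-hold CVR modelling.
    """
    t = np.asarray(t_grid, float)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    return (0.6 * t ** 2.1 * np.exp(-t / 1.6)
            - 0.0023 * t ** 3.54 * np.exp(-t / 4.25))


_IRFS = {"hrf": hrf_canonical, "rrf": rrf}


@dataclass
class DesignMatrix:
    """Time-by-regressor design with the tested column marked."""

    columns: np.ndarray
    labels: list[str]
    interest_index: int = 0

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, float)
        if self.columns.ndim != 2:
            raise ValueError("design must be 2D (time x k)")
        if len(self.labels) != self.columns.shape[1]:
            raise ValueError("one label per column required")
        if not 0 <= self.interest_index < self.columns.shape[1]:
            raise ValueError("interest_index out of range")

    @property
    def n(self) -> int:
        return self.columns.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.columns))


def _legendre(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.polynomial.legendre.legvander(x, order)


def build_design(paradigm: Paradigm, irf: str = "hrf",
                 nuisance: np.ndarray | None = None,
                 delay_s: float = 0.0, drift_order: int = 2,
                 dt: float = 0.1) -> DesignMatrix:
    """Convolve the (optionally delayed) block boxcar with an IRF.

    The boxcar is built on a fine ``dt`` grid, shifted by ``delay_s``
    (positive = response lags the task), convolved with the chosen impulse
    response and sampled at the volume acquisition times ``k * TR``.  Drift
    columns (Legendre, ``drift_order``) and nuisance columns (e.g. the six
    motion parameters) are appended; the task column is the column of
    interest.
    """
    if irf not in _IRFS:
        raise ValueError(f"irf must be one of {sorted(_IRFS)}")
    n_vol = paradigm.n_volumes
    n_fine = int(round(paradigm.total_duration / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    boxcar = np.zeros(n_fine)
    for onset, dur in zip(paradigm.onsets, paradigm.durations):
        boxcar[(t_fine >= onset + delay_s)
               & (t_fine < onset + dur + delay_s)] = 1.0
    kernel = _IRFS[irf](np.arange(0.0, 32.0 + dt, dt))
    conv = np.convolve(boxcar, kernel)[:n_fine] * dt
    sample_idx = np.rint(np.arange(n_vol) * paradigm.tr / dt).astype(int)
    sample_idx = np.clip(sample_idx, 0, n_fine - 1)
    task = conv[sample_idx]
    cols = [task[:, None], _legendre(n_vol, drift_order)]
    labels = ["task"] + [f"drift{i}" for i in range(drift_order + 1)]
    if nuisance is not None and np.size(nuisance):
        nuis = np.asarray(nuisance, float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != n_vol:
            raise ValueError(f"nuisance rows ({nuis.shape[0]}) must equal "
                             f"n_volumes ({n_vol})")
        # demean (the constant lives in the drift block) and drop columns
        # with no variation, e.g. motion parameters of motion-free data
        nuis = nuis - nuis.mean(axis=0)
        scale = np.abs(nuis).max(axis=0)
        keep = scale > 1e-8 * max(1.0, scale.max())
        if not keep.all():
            import warnings
            warnings.warn(f"dropped {int((~keep).sum())} degenerate "
                          "nuisance column(s)")
        nuis = nuis[:, keep]
        if nuis.shape[1]:
            cols.append(nuis)
            labels += [f"nuis{i}" for i in range(nuis.shape[1])]
    X = np.concatenate(cols, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient after assembly")
    return DesignMatrix(X, labels, interest_index=0)


@dataclass
class GLMResult:
    """Voxel-wise GLM estimates: betas, t for the column of interest, noise."""

    beta: np.ndarray           # (n_voxels, k)
    tstat: np.ndarray          # (n_voxels,)
    df: int
    noise: np.ndarray | None = None   # (n_voxels, 2) ARMA (a, b) or None
    zero_variance: np.ndarray | None = None  # flag mask


def _ols_fit(y: np.ndarray, X: np.ndarray, interest: int,
             df: int) -> tuple[np.ndarray, np.ndarray]:
    pinv = np.linalg.pinv(X)
    beta = (pinv @ y.T).T
    resid = y - beta @ X.T
    rss = (resid ** 2).sum(axis=1)
    xtx_inv_ii = float((pinv @ pinv.T)[interest, interest])
    sigma2 = rss / max(df, 1)
    denom = np.sqrt(np.maximum(sigma2 * xtx_inv_ii, 0.0))
    t = np.zeros(y.shape[0])
    ok = denom > 0
    t[ok] = beta[ok, interest] / denom[ok]
    return beta, t


def _arma_whiten(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Apply the inverse ARMA(1,1) filter along axis 0 (unit-diagonal)."""
    return lfilter([1.0, -a], [1.0, b], x, axis=0)


ARMA_GRID = np.round(np.arange(-0.8, 0.8 + 1e-9, 0.05), 2)

#: weak Gaussian prior (sd 0.5) on the ARMA coefficients.  ARMA(1,1) has a
#: pole-zero cancellation ridge at a = -b along which every point is exactly
#: white noise; the likelihood is flat there and finite-sample noise would
#: otherwise select arbitrary extremes.  The prior resolves the ridge toward
#: the parsimonious (0, 0) point without influencing genuinely correlated
#: voxels, whose likelihood gain grows with n.
ARMA_PRIOR_WEIGHT = 2.0


def fit_glm(y: np.ndarray, X: DesignMatrix,
            noise_model: str = "ols") -> GLMResult:
    """Fit every voxel's series; OLS or ARMA(1,1) generalized least squares.

    For ``arma11``, the AR and MA coefficients are selected per voxel by a
    grid search over a, b in [-0.8, 0.8] (step 0.05) maximizing the
    restricted likelihood of the whitened model; betas and the t-statistic
    of the column of interest then come from GLS at the selected (a, b).
    The whitening filter is causal with unit leading coefficient, so the
    covariance log-determinant term vanishes from the criterion.
    """
    y = np.atleast_2d(np.asarray(y, float))
    Xc = X.columns
    n, k = Xc.shape
    if y.shape[1] != n:
        raise ValueError(f"time dimension {y.shape[1]} != design rows {n}")
    df = n - X.rank
    zero_var = y.std(axis=1) == 0
    if noise_model == "ols":
        beta, t = _ols_fit(y, Xc, X.interest_index, df)
        t[zero_var] = 0.0
        return GLMResult(beta, t, df, None, zero_var)
    if noise_model != "arma11":
        raise ValueError("noise_model must be 'ols' or 'arma11'")

    n_vox = y.shape[0]
    yT = y.T  # (n, n_vox)
    best_score = np.full(n_vox, -np.inf)
    best_ab = np.zeros((n_vox, 2))
    interest = X.interest_index
    for a in ARMA_GRID:
        for b in ARMA_GRID:
            Xw = _arma_whiten(Xc, a, b)
            yw = _arma_whiten(yT, a, b)
            q, r = np.linalg.qr(Xw)
            resid = yw - q @ (q.T @ yw)
            rss = (resid ** 2).sum(axis=0)
            sign, logdet = np.linalg.slogdet(r.T @ r)
            if sign <= 0:
                continue
            score = -0.5 * ((n - k) * np.log(np.maximum(rss, 1e-300))
                            + logdet) \
                - ARMA_PRIOR_WEIGHT * (a * a + b * b)
            better = score > best_score
            best_score[better] = score[better]
            best_ab[better] = (a, b)

    beta = np.zeros((n_vox, k))
    t = np.zeros(n_vox)
    # refit voxels grouped by their selected (a, b): whiten once per group
    pairs, inverse = np.unique(best_ab, axis=0, return_inverse=True)
    for gi, (a, b) in enumerate(pairs):
        idx = np.where(inverse == gi)[0]
        Xw = _arma_whiten(Xc, a, b)
        yw = _arma_whiten(yT[:, idx], a, b)
        bg, tg = _ols_fit(yw.T, Xw, interest, df)
        beta[idx] = bg
        t[idx] = tg
    t[zero_var] = 0.0
    return GLMResult(beta, t, df, best_ab, zero_var)


def t_threshold_map(stat: StatMap, thr: float) -> MaskVolume:
    """Binary mask of voxels with statistic > thr (one-sided, display rule)."""
    if stat.stat_type not in ("t", "cvr_t", "z", "r", "reho"):
        raise ValueError("unsupported statistic type")
    return MaskVolume((stat.data > thr).astype(np.uint8), stat.affine)


def t_to_p(t: np.ndarray, df: int, two_sided: bool = True) -> np.ndarray:
    """p-values for t statistics at the given degrees of freedom."""
    from scipy.stats import t as t_dist
    p = t_dist.sf(np.abs(np.asarray(t, float)), df)
    return 2 * p if two_sided else p
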