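"""Synthetic test sessions with recorded ground truth.

Generates everything the analysis modules consume — task, resting-state and
breath-hold BOLD series, a T1-weighted anatomy with tissue probability
maps, lesion and meta-analysis masks — on a small grid with fully known
ground truth, so the whole workflow can be exercised and validated without
any acquired data.

The anatomy is three concentric ellipsoids (CSF shell, GM ribbon, WM core)
with T1w-like mean intensities; BOLD noise is AR(1) plus a slow polynomial
drift and sparse spikes, which together exercise despiking, detrending and
the ARMA prewhitening with known truth.  Protocol fixtures reproduce the
acquisition arithmetic of the clinical recipes the package targets
(130/120-volume task runs at TR 2 s, a 180-volume rest run, and a 70-volume
breath-hold run at TR 3 s over a 210-s paradigm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .glm import Paradigm, build_block_paradigm, build_design
from .masks import TissueProbMaps
from .preprocess import resample_volume
from .volumes import MaskVolume, RigidTransform, Volume3D, Volume4D

__all__ = [
    "Region",
    "Network",
    "PhantomConfig",
    "GroundTruth",
    "SynthSession",
    "generate_session",
    "protocol_fixture",
    "PROTOCOL_NAMES",
]

BASELINE = 1000.0  # arbitrary BOLD signal units inside the brain


@dataclass
class Region:
    """A spherical signal region: world-mm center, radius, amplitude.

    ``amplitude`` is the task/CVR response height as a fraction of baseline
    (0.02 = a 2% signal change); ``delay_s`` shifts the response in time
    (used for the CVR latency field).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float = 0.02
    delay_s: float = 0.0


@dataclass
class Network:
    """A resting-state network: member regions sharing a common signal."""

    regions: list[Region]
    shared_fraction: float = 0.5  # variance fraction of the shared signal


@dataclass
class PhantomConfig:
    """Everything needed to synthesize one session deterministically."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 2.0
    n_task: int = 130
    n_rest: int = 180
    n_bh: int = 70
    bh_tr: float = 3.0
    task_paradigm: tuple = (20.0, 20.0, 20.0, 6, False)  # rest, task, rest, cycles, drop
    bh_paradigm: tuple = (30.0, 15.0, 45.0, 3, False)
    activation_regions: list[Region] = field(default_factory=list)
    networks: list[Network] = field(default_factory=list)
    cvr_regions: list[Region] = field(default_factory=list)
    ar1: float = 0.3
    noise_sigma: float = 10.0       # BOLD noise sd, signal units (1% baseline)
    spike_rate: float = 0.0         # per-voxel per-timepoint probability
    spike_amplitude: float = 80.0   # 8 sigma
    drift_amplitude: float = 10.0   # peak-to-peak linear+quadratic drift
    motion_params: np.ndarray | None = None  # (n_task, 6) injected motion
    lesion: Region | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        for r in (self.activation_regions + self.cvr_regions
                  + [reg for nw in self.networks for reg in nw.regions]):
            if r.amplitude < 0:
                raise ValueError("region amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """What was injected, for recovery tests."""

    activation_mask: MaskVolume
    network_masks: list[MaskVolume]
    cvr_delay: Volume3D
    cvr_amplitude: Volume3D
    motion_params: np.ndarray | None
    spike_index: list[tuple]       # (x, y, z, t) of injected spikes
    brain_mask: MaskVolume
    task_paradigm: Paradigm
    bh_paradigm: Paradigm


@dataclass
class SynthSession:
    """A complete synthetic session."""

    task: Volume4D
    rest: Volume4D
    bh: Volume4D
    t1: Volume3D
    tissues: TissueProbMaps
    lesion_mask: MaskVolume
    meta_mask: MaskVolume
    truth: GroundTruth


def _default_affine(cfg: PhantomConfig) -> np.ndarray:
    aff = np.diag([*cfg.voxel_mm, 1.0])
    # center the FOV on the world origin
    aff[:3, 3] = -(np.array(cfg.shape) - 1) / 2.0 * np.array(cfg.voxel_mm)
    return aff


def _ellipsoid(shape, center_frac, semiaxes_frac) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    c = np.array(center_frac) * (np.array(shape) - 1)
    a = np.array(semiaxes_frac) * np.array(shape) / 2.0
    d = sum(((idx[i] - c[i]) / a[i]) ** 2 for i in range(3))
    return d <= 1.0


def _anatomy(cfg: PhantomConfig, rng: np.random.Generator
             ) -> tuple[Volume3D, TissueProbMaps, MaskVolume]:
    """Concentric-ellipsoid head: CSF shell, GM ribbon, WM core."""
    shape = cfg.shape
    outer = _ellipsoid(shape, (0.5, 0.5, 0.5), (0.92, 0.92, 0.92))
    gm_out = _ellipsoid(shape, (0.5, 0.5, 0.5), (0.80, 0.80, 0.80))
    wm = _ellipsoid(shape, (0.5, 0.5, 0.5), (0.55, 0.55, 0.55))
    csf = outer & ~gm_out
    gm = gm_out & ~wm
    means = {"csf": 30.0, "gm": 80.0, "wm": 120.0}
    t1 = np.zeros(shape)
    t1[csf] = means["csf"]
    t1[gm] = means["gm"]
    t1[wm] = means["wm"]
    t1[outer] += rng.normal(0.0, 5.0, size=int(outer.sum()))
    aff = _default_affine(cfg)
    probs = {}
    for name, m in (("csf", csf), ("gm", gm), ("wm", wm)):
        p = np.zeros(shape)
        p[m] = 1.0
        probs[name] = Volume3D(p, aff)
    tissues = TissueProbMaps(gm=probs["gm"], wm=probs["wm"],
                             csf=probs["csf"])
    return Volume3D(t1, aff), tissues, MaskVolume(outer, aff)


def _region_mask(region: Region, shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1)
    world = (affine @ np.vstack([idx, np.ones(idx.shape[1])]))[:3]
    d = np.linalg.norm(world - np.array(region.center_mm)[:, None], axis=0)
    return (d <= region.radius_mm).reshape(shape)


def _ar1_noise(rng, shape, n_t, ar1, sigma) -> np.ndarray:
    e = rng.normal(0.0, sigma, size=shape + (n_t,))
    if ar1 == 0:
        return e
    out = np.empty_like(e)
    out[..., 0] = e[..., 0] / np.sqrt(1 - ar1 ** 2)
    for t in range(1, n_t):
        out[..., t] = ar1 * out[..., t - 1] + e[..., t]
    return out


def _drift(rng, shape, n_t, amplitude) -> np.ndarray:
    x = np.linspace(-1, 1, n_t)
    c1 = rng.uniform(-amplitude / 2, amplitude / 2, size=shape)
    c2 = rng.uniform(-amplitude / 2, amplitude / 2, size=shape)
    return c1[..., None] * x + c2[..., None] * (x ** 2)


def _task_regressor(paradigm: Paradigm, irf: str, delay_s: float) -> np.ndarray:
    X = build_design(paradigm, irf=irf, delay_s=delay_s, drift_order=0)
    reg = X.columns[:, X.interest_index]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def _bandlimited_signal(rng, n_t, tr, band=(0.01, 0.08)) -> np.ndarray:
    """Unit-variance signal with power confined to the given band."""
    freqs = np.fft.rfftfreq(n_t, d=tr)
    spec = np.zeros(freqs.size, complex)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    spec[sel] = rng.normal(size=int(sel.sum())) \
        + 1j * rng.normal(size=int(sel.sum()))
    sig = np.fft.irfft(spec, n=n_t)
    return sig / sig.std()


def generate_session(cfg: PhantomConfig) -> SynthSession:
    """Synthesize one session (task, rest, BH, anatomy, masks, truth).

    Deterministic for a given config: the same seed yields bit-identical
    outputs.  Raises if any region's sphere lies outside the grid.
    """
    rng = np.random.default_rng(cfg.seed)
    t1, tissues, brain = _anatomy(cfg, rng)
    aff = t1.affine
    shape = cfg.shape
    fov_half = (np.array(shape)) / 2.0 * np.array(cfg.voxel_mm)
    for r in (cfg.activation_regions + cfg.cvr_regions
              + [reg for nw in cfg.networks for reg in nw.regions]):
        if np.any(np.abs(np.array(r.center_mm)) > fov_half):
            raise ValueError(f"region at {r.center_mm} lies outside the grid")

    task_par = build_block_paradigm(*cfg.task_paradigm[:4], cfg.tr,
                                    cfg.task_paradigm[4])
    bh_par = build_block_paradigm(*cfg.bh_paradigm[:4], cfg.bh_tr,
                                  cfg.bh_paradigm[4])

    base = np.where(brain.data > 0, BASELINE, 0.0)

    # ---- task run ----------------------------------------------------
    n_task = cfg.n_task
    if n_task != task_par.n_volumes:
        raise ValueError("n_task inconsistent with the task paradigm")
    task = base[..., None] + _ar1_noise(rng, shape, n_task, cfg.ar1,
                                        cfg.noise_sigma)
    task += _drift(rng, shape, n_task, cfg.drift_amplitude) \
        * (brain.data[..., None] > 0)
    act_mask = np.zeros(shape, bool)
    reg = _task_regressor(task_par, "hrf", 0.0)
    for region in cfg.activation_regions:
        m = _region_mask(region, shape, aff)
        act_mask |= m
        task[m] += region.amplitude * BASELINE * reg

    spikes: list[tuple] = []
    if cfg.spike_rate > 0:
        brain_idx = np.argwhere(brain.data > 0)
        n_spikes = rng.binomial(len(brain_idx) * n_task, cfg.spike_rate)
        for _ in range(n_spikes):
            v = brain_idx[rng.integers(len(brain_idx))]
            t = int(rng.integers(n_task))
            task[v[0], v[1], v[2], t] += cfg.spike_amplitude
            spikes.append((int(v[0]), int(v[1]), int(v[2]), t))

    if cfg.motion_params is not None:
        mp = np.asarray(cfg.motion_params, float)
        if mp.shape != (n_task, 6):
            raise ValueError("motion_params must be (n_task, 6)")
        for t in range(n_task):
            if np.any(mp[t] != 0):
                tf = RigidTransform(mp[t])
                task[..., t] = resample_volume(
                    Volume3D(task[..., t], aff), tf, aff, shape,
                    method="trilinear").data

    # ---- rest run ----------------------------------------------------
    n_rest = cfg.n_rest
    rest = base[..., None] + _ar1_noise(rng, shape, n_rest, cfg.ar1,
                                        cfg.noise_sigma)
    rest += _drift(rng, shape, n_rest, cfg.drift_amplitude) \
        * (brain.data[..., None] > 0)
    network_masks = []
    for nw in cfg.networks:
        shared = _bandlimited_signal(rng, n_rest, cfg.tr)
        nw_mask = np.zeros(shape, bool)
        for region in nw.regions:
            m = _region_mask(region, shape, aff)
            nw_mask |= m
            amp = cfg.noise_sigma * np.sqrt(
                nw.shared_fraction / (1 - nw.shared_fraction))
            rest[m] += amp * shared
        network_masks.append(MaskVolume(nw_mask, aff))

    # ---- breath-hold run ---------------------------------------------
    n_bh = cfg.n_bh
    if n_bh != bh_par.n_volumes:
        raise ValueError("n_bh inconsistent with the BH paradigm")
    bh = base[..., None] + _ar1_noise(rng, shape, n_bh, cfg.ar1,
                                      cfg.noise_sigma)
    cvr_delay = np.zeros(shape)
    cvr_amp = np.zeros(shape)
    for region in cfg.cvr_regions:
        m = _region_mask(region, shape, aff)
        resp = _task_regressor(bh_par, "rrf", region.delay_s)
        bh[m] += region.amplitude * BASELINE * resp
        cvr_delay[m] = region.delay_s
        cvr_amp[m] = region.amplitude * BASELINE

    # ---- lesion and meta-analysis masks ------------------------------
    if cfg.lesion is not None:
        lesion_mask = MaskVolume(
            _region_mask(cfg.lesion, shape, aff), aff)
    else:
        lesion_mask = MaskVolume(np.zeros(shape, np.uint8), aff)
    # meta mask: union of network (or activation) regions, mimicking a
    # meta-analysis map brought into subject space
    meta = np.zeros(shape, bool)
    source = (cfg.networks[0].regions if cfg.networks
              else cfg.activation_regions)
    for region in source:
        meta |= _region_mask(region, shape, aff)
    meta_mask = MaskVolume(meta, aff)

    truth = GroundTruth(
        activation_mask=MaskVolume(act_mask, aff),
        network_masks=network_masks,
        cvr_delay=Volume3D(cvr_delay, aff),
        cvr_amplitude=Volume3D(cvr_amp, aff),
        motion_params=(None if cfg.motion_params is None
                       else np.asarray(cfg.motion_params, float)),
        spike_index=spikes,
        brain_mask=brain,
        task_paradigm=task_par,
        bh_paradigm=bh_par)
    # ascending slice acquisition offsets so slice-timing correction has
    # something to do on the rest run
    slice_times = np.arange(shape[2]) * cfg.tr / shape[2]
    return SynthSession(
        task=Volume4D(task, aff, cfg.tr),
        rest=Volume4D(rest, aff, cfg.tr, slice_times),
        bh=Volume4D(bh, aff, cfg.bh_tr),
        t1=t1, tissues=tissues, lesion_mask=lesion_mask,
        meta_mask=meta_mask, truth=truth)


def _default_regions() -> dict:
    """Signal geometry shared by the protocol fixtures (world mm)."""
    return {
        "activation": [Region((-20.0, 20.0, 6.0), 9.0, amplitude=0.02)],
        "networks": [
            Network([Region((-20.0, 20.0, 6.0), 8.0),
                     Region((20.0, -20.0, 6.0), 8.0)], shared_fraction=0.5),
            Network([Region((-20.0, -20.0, -6.0), 8.0),
                     Region((20.0, 20.0, -6.0), 8.0)], shared_fraction=0.5),
        ],
        "cvr": [Region((-20.0, 20.0, 6.0), 9.0, amplitude=0.02,
                       delay_s=6.0),
                Region((20.0, -20.0, 6.0), 9.0, amplitude=0.02,
                       delay_s=0.0)],
        "lesion": Region((24.0, 24.0, 0.0), 8.0),
    }


PROTOCOL_NAMES = ("patient1_task", "patient1_task_sentence",
                  "patient1_rest", "patient1_bh", "patient2_rest")


def protocol_fixture(name: str) -> PhantomConfig:
    """Phantom config matching one of the printed clinical protocols.

    * ``patient1_task``: letter/category fluency — 130 volumes at TR 2 s
      (20-s rest, then six 20-s task / 20-s rest cycles).
    * ``patient1_task_sentence``: sentence completion — 120 volumes (the
      final 20-s rest interval is dropped).
    * ``patient1_rest`` / ``patient2_rest``: 180 volumes at TR 2 s (6 min).
    * ``patient1_bh``: breath-hold — 70 volumes at TR 3 s over a 210-s
      paradigm (30-s natural breathing, then three 15-s BH / 45-s
      breathing cycles).
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from "
                         f"{PROTOCOL_NAMES}")
    geo = _default_regions()
    cfg = PhantomConfig(
        activation_regions=geo["activation"],
        networks=geo["networks"],
        cvr_regions=geo["cvr"],
        lesion=geo["lesion"])
    if name == "patient1_task_sentence":
        cfg = replace(cfg, task_paradigm=(20.0, 20.0, 20.0, 6, True),
                      n_task=120)
    return cfg
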