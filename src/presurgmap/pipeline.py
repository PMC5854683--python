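"""End-to-end task / rest / CVR workflows with reports.

Each ``run_*_pipeline`` function takes a config (dict, or path to a YAML
file), validates it up front (fail-fast: nothing is written on a config
error), executes the configured steps in order, writes NIfTI outputs plus a
JSON report, and returns the :class:`PipelineReport`.

Inputs may be NIfTI paths or a named synthetic protocol fixture
(``inputs: {fixture: patient1_rest, seed: 42}``), which makes every
workflow runnable without acquired data.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cvr import DelaySweep, cvr_map
from .glm import DesignMatrix, build_block_paradigm, fit_glm, build_design
from .masks import make_nuisance_mask, make_wholebrain_mask, segment_tissues
from .phantom import PROTOCOL_NAMES, generate_session, protocol_fixture
from .preprocess import (despike, motion_correct, project_nuisance,
                         resample_once, resample_to_iso,
                         select_reference_volume, slice_timing_correct,
                         smooth_gaussian)
from .rsfc import (GuidanceMap, SeedSpec, build_rh_ma_guidance, compute_reho,
                   fc_map, find_local_maxima, seed_timecourse)
from .volumes import (MaskVolume, RigidTransform, StatMap, Volume4D,
                      load_volume3d, load_volume4d, save_volume)

__all__ = ["PipelineReport", "ConfigError", "DataError",
           "run_task_pipeline", "run_rest_pipeline", "run_cvr_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2 in the CLI)."""


class DataError(RuntimeError):
    """Input data unusable (exit code 3 in the CLI)."""


@dataclass
class PipelineReport:
    """A replayable account of one pipeline run."""

    mode: str
    steps: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    versions: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def log_step(self, name: str, duration_s: float, **params) -> None:
        self.steps.append({"name": name, "duration_s": round(duration_s, 3),
                           "params": params})

    @property
    def step_names(self) -> list[str]:
        return [s["name"] for s in self.steps]

    def to_json(self, path) -> None:
        payload = {"mode": self.mode, "steps": self.steps,
                   "outputs": self.outputs, "warnings": self.warnings,
                   "seed": self.seed, "versions": self.versions,
                   "extras": self.extras}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _versions() -> dict:
    import scipy
    return {"presurgmap": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    return config


class _Timer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0


def _resolve_inputs(cfg: dict, need: tuple[str, ...]) -> dict:
    """Load NIfTI inputs or synthesize the named protocol fixture."""
    inputs = cfg.get("inputs")
    if not inputs:
        raise ConfigError("config requires an 'inputs' section")
    out: dict = {}
    if "fixture" in inputs:
        name = inputs["fixture"]
        if name not in PROTOCOL_NAMES:
            raise ConfigError(f"unknown fixture {name!r}")
        pcfg = protocol_fixture(name)
        from dataclasses import replace
        if "seed" in inputs:
            pcfg = replace(pcfg, seed=int(inputs["seed"]))
        if "shape" in inputs:
            pcfg = replace(pcfg, shape=tuple(inputs["shape"]))
        if "voxel_mm" in inputs:
            v = inputs["voxel_mm"]
            v = (v, v, v) if np.isscalar(v) else tuple(v)
            pcfg = replace(pcfg, voxel_mm=v)
        if "n_rest" in inputs:  # shorter rest runs for quick plumbing checks
            pcfg = replace(pcfg, n_rest=int(inputs["n_rest"]))
        session = generate_session(pcfg)
        out["session"] = session
        out["t1"] = session.t1
        out["func"] = {"task": session.task, "rest": session.rest,
                       "cvr": session.bh}[cfg["mode"]]
        out["seed_value"] = pcfg.seed
        return out
    for key in need:
        if key not in inputs:
            raise ConfigError(f"missing input '{key}'")
        path = Path(inputs[key])
        if not path.exists():
            raise ConfigError(f"input file not found: {path}")
    out["t1"] = load_volume3d(inputs["t1"])
    tr = inputs.get("tr")
    out["func"] = load_volume4d(inputs["func"], tr=tr)
    out["session"] = None
    out["seed_value"] = inputs.get("seed")
    return out


def _paradigm_from_config(cfg: dict, default_tr: float):
    p = cfg.get("paradigm")
    if not p:
        raise ConfigError("config requires a 'paradigm' section")
    try:
        return build_block_paradigm(
            float(p["initial_rest"]), float(p["task_s"]), float(p["rest_s"]),
            int(p["cycles"]), float(p.get("tr", default_tr)),
            bool(p.get("drop_final_rest", False)))
    except KeyError as exc:
        raise ConfigError(f"paradigm missing field {exc}") from exc
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _spatial_stage(report: PipelineReport, func: Volume4D, t1,
                   iso_mm: int) -> tuple[Volume4D, np.ndarray]:
    """moco + CBR with single-shot interpolation; returns data on the T1
    iso grid and the 6-column motion table."""
    with _Timer() as tm:
        profile = select_reference_volume(func)
    report.log_step("reference", tm.elapsed,
                    reference_index=profile.reference_index,
                    kappa=round(float(profile.kappa), 3))
    with _Timer() as tm:
        _, transforms = motion_correct(func, profile.reference_index)
    motion_table = np.array([tf.params for tf in transforms])
    report.log_step("moco", tm.elapsed,
                    reference_index=profile.reference_index,
                    max_abs_translation_mm=float(
                        np.abs(motion_table[:, 3:]).max()))
    with _Timer() as tm:
        t1_iso = resample_to_iso(t1, iso_mm)
        aligned = resample_once(func, transforms, RigidTransform.identity(),
                                t1_iso.affine, t1_iso.shape)
    report.log_step("cbr", tm.elapsed, target_iso_mm=iso_mm,
                    interpolation="wsinc5")
    report.extras["t1_iso"] = t1_iso
    return aligned, motion_table


def _despike_stage(report: PipelineReport, vol: Volume4D,
                   mask: MaskVolume) -> Volume4D:
    with _Timer() as tm:
        data = vol.data.copy()
        flat = data.reshape(-1, vol.n_volumes)
        sel = mask.data.reshape(-1) > 0
        flat[sel] = despike(flat[sel])
    report.log_step("despike", tm.elapsed, c1=2.5, c2=4.0)
    return Volume4D(data, vol.affine, vol.tr, vol.slice_times)


def _brain_mask_on(grid_affine, grid_shape, tissues) -> MaskVolume:
    wb = make_wholebrain_mask(tissues)
    from .masks import _nearest_resample_mask
    return _nearest_resample_mask(wb, grid_affine, grid_shape)


def _finish(report: PipelineReport, out_dir, volumes: dict) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.extras.pop("t1_iso", None)
    for name, vol in volumes.items():
        path = out_dir / f"{name}.nii.gz"
        save_volume(vol, path)
        report.outputs[name] = str(path)
    report.versions = _versions()
    rpath = out_dir / "report.json"
    report.to_json(rpath)
    report.outputs["report"] = str(rpath)


# ---------------------------------------------------------------------------

def run_task_pipeline(config) -> PipelineReport:
    """Task workflow: moco -> CBR -> despike -> smooth -> GLM t-map."""
    cfg = _load_config(config)
    cfg.setdefault("mode", "task")
    out_dir = cfg.get("out")
    if not out_dir:
        raise ConfigError("config requires 'out' directory")
    pre = cfg.get("preprocess", {})
    iso = int(pre.get("iso", 2))
    fwhm = float(pre.get("fwhm", 4.0))
    noise_model = cfg.get("glm", {}).get("noise", "arma11")
    if noise_model not in ("ols", "arma11"):
        raise ConfigError(f"unknown noise model {noise_model!r}")
    inputs = _resolve_inputs(cfg, ("func", "t1"))
    paradigm = _paradigm_from_config(cfg, inputs["func"].tr)
    if paradigm.n_volumes != inputs["func"].n_volumes:
        raise ConfigError(
            f"paradigm implies {paradigm.n_volumes} volumes, data has "
            f"{inputs['func'].n_volumes}")

    report = PipelineReport(mode="task", seed=inputs["seed_value"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        aligned, motion = _spatial_stage(report, inputs["func"],
                                         inputs["t1"], iso)
        tissues = segment_tissues(inputs["t1"])
        brain = _brain_mask_on(aligned.affine, aligned.shape[:3], tissues)
        aligned = _despike_stage(report, aligned, brain)
        with _Timer() as tm:
            smoothed = smooth_gaussian(aligned, fwhm)
        report.log_step("smooth", tm.elapsed, fwhm_mm=fwhm)
        with _Timer() as tm:
            X = build_design(paradigm, irf="hrf", nuisance=motion)
            flat = smoothed.data.reshape(-1, smoothed.n_volumes)
            sel = brain.data.reshape(-1) > 0
            res = fit_glm(flat[sel], X, noise_model=noise_model)
            tmap = np.zeros(flat.shape[0])
            tmap[sel] = res.tstat
            stat = StatMap(tmap.reshape(smoothed.shape[:3]),
                           smoothed.affine, "t", df=res.df)
        report.log_step("glm", tm.elapsed, noise_model=noise_model,
                        df=res.df, n_regressors=X.columns.shape[1])
    report.warnings = [str(w.message) for w in caught]
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    motion_path = Path(out_dir) / "motion.tsv"
    np.savetxt(motion_path, motion, delimiter="\t",
               header="rx\try\trz\ttx\tty\ttz", comments="")
    report.outputs["motion"] = str(motion_path)
    _finish(report, out_dir, {"tstat": stat, "brain_mask": brain})
    return report


def run_rest_pipeline(config) -> PipelineReport:
    """Rest workflow: slice timing, moco, CBR, despike, joint
    detrend/nuisance/band-pass, ReHo (pre-smoothing), smooth, seed FC."""
    cfg = _load_config(config)
    cfg.setdefault("mode", "rest")
    out_dir = cfg.get("out")
    if not out_dir:
        raise ConfigError("config requires 'out' directory")
    pre = cfg.get("preprocess", {})
    iso = int(pre.get("iso", 2))
    fwhm = float(pre.get("fwhm", 4.0))
    band = tuple(pre.get("band", (0.01, 0.08)))
    detrend_order = int(pre.get("detrend_order", 2))
    rest_cfg = cfg.get("rest", {})
    guidance_src = rest_cfg.get("guidance", "reho")
    if guidance_src not in ("task_t", "reho", "rh_ma", "anatomical"):
        raise ConfigError(f"unknown guidance source {guidance_src!r}")
    radius = float(rest_cfg.get("radius", 5.0))
    inputs = _resolve_inputs(cfg, ("func", "t1"))
    session = inputs["session"]
    if guidance_src == "rh_ma" and session is None \
            and "meta_mask" not in cfg.get("inputs", {}):
        raise ConfigError("rh_ma guidance requires a meta_mask input")

    report = PipelineReport(mode="rest", seed=inputs["seed_value"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        func = inputs["func"]
        if func.slice_times is not None:
            with _Timer() as tm:
                func = slice_timing_correct(func)
            report.log_step("slice_timing", tm.elapsed)
        aligned, motion = _spatial_stage(report, func, inputs["t1"], iso)
        tissues = (session.tissues if session is not None
                   else segment_tissues(inputs["t1"]))
        brain = _brain_mask_on(aligned.affine, aligned.shape[:3], tissues)
        aligned = _despike_stage(report, aligned, brain)

        with _Timer() as tm:
            wm_mask = make_nuisance_mask(tissues.wm, 0.999, None,
                                         aligned.affine, aligned.shape[:3])
            csf_mask = make_nuisance_mask(tissues.csf, 0.999, None,
                                          aligned.affine, aligned.shape[:3])
            flat = aligned.data.reshape(-1, aligned.n_volumes)
            regs = [motion]
            for m in (wm_mask, csf_mask):
                if m.n_voxels:
                    regs.append(flat[m.data.reshape(-1) > 0].mean(0)[:, None])
            # optional global-signal regression (off by default): mean over
            # the 30%-threshold whole-brain mask
            if pre.get("global_signal", False):
                regs.append(flat[brain.data.reshape(-1) > 0]
                            .mean(0)[:, None])
            regressors = np.concatenate(regs, axis=1)
            sel = brain.data.reshape(-1) > 0
            cleaned = flat.copy()
            cleaned[sel] = project_nuisance(flat[sel], regressors, band,
                                            detrend_order, tr=aligned.tr)
            clean_vol = Volume4D(cleaned.reshape(aligned.shape),
                                 aligned.affine, aligned.tr)
        report.log_step("detrend_nuisance_bandpass", tm.elapsed,
                        band=list(band), detrend_order=detrend_order,
                        n_nuisance=regressors.shape[1],
                        global_signal=bool(pre.get("global_signal", False)))

        guidance = None
        reho = None
        if guidance_src in ("reho", "rh_ma"):
            with _Timer() as tm:
                reho = compute_reho(clean_vol, mask=brain)
            report.log_step("reho", tm.elapsed, neighborhood=27,
                            pre_smoothing=True)
            if guidance_src == "rh_ma":
                if session is not None:
                    meta = session.meta_mask
                    from .masks import _nearest_resample_mask
                    meta = _nearest_resample_mask(meta, clean_vol.affine,
                                                  clean_vol.shape[:3])
                else:
                    from .volumes import load_volume3d as _l3
                    mv = _l3(cfg["inputs"]["meta_mask"])
                    meta = MaskVolume(mv.data, mv.affine)
                guidance = build_rh_ma_guidance(reho, meta)
            else:
                guidance = GuidanceMap("reho", reho)
        elif guidance_src == "task_t":
            guide_path = rest_cfg.get("guide_map")
            if guide_path:
                g = load_volume3d(guide_path)
                guidance = GuidanceMap(
                    "task_t", StatMap(g.data, g.affine, "t", df=1))

        with _Timer() as tm:
            smoothed = smooth_gaussian(clean_vol, fwhm)
        report.log_step("smooth", tm.elapsed, fwhm_mm=fwhm)

        with _Timer() as tm:
            if "seed_mm" in rest_cfg:
                center = np.asarray(rest_cfg["seed_mm"], float)
                seed_source = "config"
            elif guidance is not None:
                peaks = find_local_maxima(guidance,
                                          min_separation_mm=2 * radius)
                if not peaks:
                    raise DataError("guidance map has no local maxima")
                center = peaks[0][0]
                seed_source = guidance.source
            else:
                raise ConfigError("no seed: give rest.seed_mm or a guidance "
                                  "source that yields peaks")
            seed = SeedSpec(center, radius)
            fc = fc_map(smoothed, seed, brain)
        report.log_step("fc", tm.elapsed, seed_mm=list(np.round(center, 2)),
                        radius_mm=radius, seed_source=seed_source)
        report.extras["seed_mm"] = [float(v) for v in center]
        report.extras["seed_source"] = seed_source

    report.warnings = [str(w.message) for w in caught]
    volumes = {"fc_z": fc.z, "fc_r": fc.r, "brain_mask": brain}
    if reho is not None:
        volumes["reho"] = reho
    if guidance is not None and guidance_src == "rh_ma":
        volumes["guidance"] = guidance.map
    _finish(report, out_dir, volumes)
    return report


def run_cvr_pipeline(config) -> PipelineReport:
    """CVR workflow: moco, CBR, despike, smooth, delay-swept GLM."""
    cfg = _load_config(config)
    cfg.setdefault("mode", "cvr")
    out_dir = cfg.get("out")
    if not out_dir:
        raise ConfigError("config requires 'out' directory")
    pre = cfg.get("preprocess", {})
    iso = int(pre.get("iso", 2))
    fwhm = float(pre.get("fwhm", 4.0))
    cvr_cfg = cfg.get("cvr", {})
    lo = float(cvr_cfg.get("delay_min", -10.0))
    hi = float(cvr_cfg.get("delay_max", 15.0))
    step = float(cvr_cfg.get("step", 1.0))
    if lo > hi:
        raise ConfigError(f"invalid delay range: {lo} > {hi}")
    irf = cvr_cfg.get("irf", "rrf")
    if irf not in ("hrf", "rrf"):
        raise ConfigError(f"unknown irf {irf!r}")
    inputs = _resolve_inputs(cfg, ("func", "t1"))
    paradigm = _paradigm_from_config(cfg, inputs["func"].tr)
    if paradigm.n_volumes != inputs["func"].n_volumes:
        raise ConfigError(
            f"paradigm implies {paradigm.n_volumes} volumes, data has "
            f"{inputs['func'].n_volumes}")

    report = PipelineReport(mode="cvr", seed=inputs["seed_value"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        aligned, motion = _spatial_stage(report, inputs["func"],
                                         inputs["t1"], iso)
        session = inputs["session"]
        tissues = (session.tissues if session is not None
                   else segment_tissues(inputs["t1"]))
        brain = _brain_mask_on(aligned.affine, aligned.shape[:3], tissues)
        aligned = _despike_stage(report, aligned, brain)
        with _Timer() as tm:
            smoothed = smooth_gaussian(aligned, fwhm)
        report.log_step("smooth", tm.elapsed, fwhm_mm=fwhm)
        with _Timer() as tm:
            sweep = DelaySweep.from_range(lo, hi, step)
            result = cvr_map(smoothed, paradigm, irf=irf, sweep=sweep,
                             nuisance=motion)
        report.log_step("cvr_glm", tm.elapsed, irf=irf,
                        delay_range_s=[lo, hi], step_s=step,
                        n_delays=int(sweep.delays.size), df=result.df)
    report.warnings = [str(w.message) for w in caught]
    _finish(report, out_dir, {
        "cvr_tmax": result.tmax,
        "cvr_best_delay": result.best_delay,
        "cvr_amplitude": result.amplitude,
        "brain_mask": brain})
    return report
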