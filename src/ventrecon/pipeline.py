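"""Pipeline orchestration: simulate -> bin -> recon -> analyze -> metrics.

A validated configuration (YAML-loadable, unknown keys rejected) drives
the five stages; each stage reads its upstream artifacts from the working
directory and writes its own, so stages are idempotent and rerunnable.
Every JSON artifact records the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import binning, fileio, metrics, phantom, preful, recon, trajectory
from .registration import RegistrationParams

log = logging.getLogger("ventrecon")

STAGES = ("simulate", "bin", "recon", "analyze", "metrics")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrajectorySection(_Section):
    fov_mm: float = 320.0
    res_mm: float | None = None          # None -> fov_mm / grid_size
    n_hubs: int = 3
    samples_per_readout: int = 64
    n_excitations: int = 20000
    nyquist_pct: float = 1.0
    hub_half_angle_deg: float = 45.0
    interleave_order: str = "golden"


class DefectSection(_Section):
    center_voxel: tuple[int, int, int]
    radius_mm: float
    amplitude_scale: float = 0.0
    phase_lag: float = 0.0


class PhantomSection(_Section):
    grid_size: int = 48
    breathing_period_s: float = 4.0
    tidal_amplitude: float = 0.3
    lung_density_ee: float = 0.25
    defects: list[DefectSection] = Field(default_factory=list)
    defect_fraction: float | None = None   # auto-placed amplitude defects
    defect_amplitude_scale: float = 0.15
    lag_defect: bool = False
    lag_fraction: float = 0.2              # cycle lag of the lag defect
    n_coils: int = 4
    noise_sd: float = 0.3
    tr_s: float = 0.0038
    amp_jitter: float = 0.05
    period_jitter: float = 0.05
    bellows_noise_sd: float = 0.01
    drift: float = 0.0
    outlier_rate: float = 0.0
    with_trachea: bool = False
    with_vessels: bool = False


class BinningSection(_Section):
    n_bins: int = 8
    smoothing_window: int | None = None
    exclusion_k: float = 2.0
    total_budget: int | None = None        # None -> scaled to usable count
    max_share_fraction: float = 0.5


class ReconSection(_Section):
    lambda_l: float = 0.01
    inner_iters: int = 5
    outer_iters: int = 3
    superior_iters: int = 3
    step_rho: float = 1.0
    recon_res_mm: float | None = None
    nufft_width: int = 3
    cg_init_iters: int = 8
    weighted_residual: bool = True


class RegistrationSection(_Section):
    mode: str = "affine_then_nonrigid"
    similarity: str = "cross_correlation"
    levels: tuple[int, ...] = (6, 4, 2, 1)
    smoothing: tuple[float, ...] = (3.0, 2.0, 1.0, 0.5)
    iterations: tuple[int, ...] = (150, 150, 100, 80)


class PrefulSection(_Section):
    n_phases: int = 16
    gauss_sigma: float = 0.3
    lowpass_hz: float = 0.7
    fvl_cm_threshold: float = 0.9
    rvent_pct: float = 90.0
    rvent_frac: float = 0.4
    ref_quantiles: tuple[float, float] = (0.75, 0.95)
    cm_max_lag: int = 0
    bias_correction: bool = True
    edge_preserving: bool = True


class PipelineConfig(_Section):
    seed: int = 0
    trajectory: TrajectorySection = Field(default_factory=TrajectorySection)
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    binning: BinningSection = Field(default_factory=BinningSection)
    recon: ReconSection = Field(default_factory=ReconSection)
    registration: RegistrationSection = Field(
        default_factory=RegistrationSection)
    preful: PrefulSection = Field(default_factory=PrefulSection)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _phantom_spec(cfg: PipelineConfig) -> phantom.PhantomSpec:
    p = cfg.phantom
    defects = tuple(
        phantom.DefectSpec(center_voxel=tuple(d.center_voxel),
                           radius_mm=d.radius_mm,
                           amplitude_scale=d.amplitude_scale,
                           phase_lag=d.phase_lag)
        for d in p.defects)
    spec = phantom.PhantomSpec(
        grid_size=p.grid_size, fov_mm=cfg.trajectory.fov_mm,
        breathing_period_s=p.breathing_period_s,
        tidal_amplitude=p.tidal_amplitude,
        lung_density_ee=p.lung_density_ee, defects=defects,
        n_coils=p.n_coils, noise_sd=p.noise_sd, seed=cfg.seed,
        with_trachea=p.with_trachea, with_vessels=p.with_vessels)
    if p.defect_fraction or p.lag_defect:
        base = phantom.build_phantom(
            phantom.PhantomSpec(grid_size=p.grid_size,
                                fov_mm=cfg.trajectory.fov_mm,
                                tidal_amplitude=p.tidal_amplitude,
                                lung_density_ee=p.lung_density_ee,
                                seed=cfg.seed))
        out = list(defects)
        if p.defect_fraction:
            out += list(phantom.amplitude_defect_layout(
                base, p.defect_fraction,
                amplitude_scale=p.defect_amplitude_scale,
                seed=cfg.seed + 11))
        if p.lag_defect:
            avoid = phantom.defect_region_mask(base, tuple(out))
            out += list(phantom.amplitude_defect_layout(
                base, 0.05, amplitude_scale=1.0, seed=cfg.seed + 23,
                phase_lag=p.lag_fraction, avoid=avoid))
        spec = phantom.PhantomSpec(
            grid_size=p.grid_size, fov_mm=cfg.trajectory.fov_mm,
            breathing_period_s=p.breathing_period_s,
            tidal_amplitude=p.tidal_amplitude,
            lung_density_ee=p.lung_density_ee, defects=tuple(out),
            n_coils=p.n_coils, noise_sd=p.noise_sd, seed=cfg.seed,
            with_trachea=p.with_trachea, with_vessels=p.with_vessels)
    return spec


def run_pipeline(config: PipelineConfig, workdir,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns artifact paths.

    Raises if a stage is requested without its upstream artifact present.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict[str, object] = {}
    stamps = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        log.info("stage %s (config %s, seed %d)", stage, chash, config.seed)
        _STAGE_FN[stage](config, workdir, artifacts)
        stamps[stage] = round(time.time() - t0, 2)
    meta = {"config_hash": chash, "seed": config.seed, "timing_s": stamps,
            "config": config.model_dump()}
    with open(workdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return artifacts


def _require(workdir: Path, name: str, stage: str) -> Path:
    p = workdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires missing artifact {name!r}; run the "
            "upstream stage first")
    return p


def _stage_simulate(cfg: PipelineConfig, wd: Path, art: dict) -> None:
    spec = _phantom_spec(cfg)
    model = phantom.build_phantom(spec)
    t = cfg.trajectory
    res = t.res_mm or t.fov_mm / spec.grid_size
    tconf = trajectory.TrajectoryConfig(
        fov_mm=t.fov_mm, res_mm=res, n_hubs=t.n_hubs,
        samples_per_readout=t.samples_per_readout,
        n_excitations=t.n_excitations, nyquist_pct=t.nyquist_pct,
        hub_half_angle_deg=t.hub_half_angle_deg,
        interleave_order=t.interleave_order)
    traj = trajectory.generate_floret(tconf)
    p = cfg.phantom
    bell = phantom.simulate_bellows(
        spec, t.n_excitations, tr_s=p.tr_s, drift=p.drift,
        outlier_rate=p.outlier_rate, amp_jitter=p.amp_jitter,
        period_jitter=p.period_jitter, noise_sd=p.bellows_noise_sd)
    sens = phantom.make_coil_maps(p.n_coils, spec.grid_size)
    kdata = phantom.simulate_acquisition(model, traj, bell, sens,
                                         noise_sd=p.noise_sd)
    fileio.write_raw(wd / "raw.h5", kdata, seed=cfg.seed,
                     extra_attrs={"config_hash": cfg.config_hash()})
    truth = model.ground_truth(1.0)
    vox = t.fov_mm / spec.grid_size
    for key in ("fv_amplitude", "phase_lag", "vttp_pct"):
        fileio.write_nifti(wd / f"truth_{key}.nii.gz", truth[key], vox)
    for key in ("defect_mask", "lag_mask", "lung_mask", "parenchyma_mask"):
        fileio.write_nifti(wd / f"truth_{key}.nii.gz",
                           truth[key].astype(np.float32), vox)
    art["raw"] = wd / "raw.h5"
    art["truth"] = truth
    art["phantom"] = model


def _stage_bin(cfg: PipelineConfig, wd: Path, art: dict) -> None:
    kdata = fileio.read_raw(_require(wd, "raw.h5", "bin"))
    bcfg = binning.BinningConfig(
        n_bins=cfg.binning.n_bins,
        smoothing_window=cfg.binning.smoothing_window,
        exclusion_k=cfg.binning.exclusion_k,
        total_budget=cfg.binning.total_budget,
        max_share_fraction=cfg.binning.max_share_fraction)
    bins, _ = binning.bin_bellows(kdata.bellows, bcfg,
                                  cfg.phantom.breathing_period_s)
    bins.to_json(wd / "bins.json")
    art["bins"] = bins


def _load_bins(wd: Path, kdata) -> binning.RespiratoryBinSet:
    with open(_require(wd, "bins.json", "recon")) as fh:
        payload = json.load(fh)
    idx = [np.asarray(b, dtype=np.int64) for b in payload["bins"]]
    targets = np.asarray(payload["target_phases"])
    smoothed = binning.preprocess_bellows(
        kdata.bellows, max(1, len(kdata.bellows) // 400))
    amp = np.array([smoothed.values[i].mean() for i in idx])
    B = len(idx)
    return binning.RespiratoryBinSet(
        bin_indices=idx, target_phases=targets,
        phase_edges=[(float(t), float(t)) for t in targets],
        excluded=np.asarray(payload["excluded"], dtype=np.int64),
        share_matrix=np.zeros((B, B), dtype=np.int64),
        mean_amplitude=amp)


def _stage_recon(cfg: PipelineConfig, wd: Path, art: dict) -> None:
    kdata = fileio.read_raw(_require(wd, "raw.h5", "recon"))
    bins = art.get("bins") or _load_bins(wd, kdata)
    kb = binning.bin_kspace(kdata, bins)
    n = cfg.phantom.grid_size
    sens = recon.estimate_sensitivities(kb, (n, n, n))
    pre = recon.compute_preconditioner(kb.coords, kb.fov_mm, (n, n, n))
    rcfg = recon.ReconConfig(
        lambda_l=cfg.recon.lambda_l, inner_iters=cfg.recon.inner_iters,
        outer_iters=cfg.recon.outer_iters,
        superior_iters=cfg.recon.superior_iters,
        step_rho=cfg.recon.step_rho, recon_res_mm=cfg.recon.recon_res_mm,
        nufft_width=cfg.recon.nufft_width,
        cg_init_iters=cfg.recon.cg_init_iters,
        weighted_residual=cfg.recon.weighted_residual)
    series, motion = recon.mocolor(kb, sens, pre, rcfg)
    fileio.write_series_nifti(wd / "series.nii.gz", series.volumes,
                              series.voxel_mm,
                              descrip=f"cfg {cfg.config_hash()}")
    meta = {"bin_phases": series.bin_phases.tolist(),
            "bin_amplitudes": (None if series.bin_amplitudes is None
                               else series.bin_amplitudes.tolist()),
            "voxel_mm": series.voxel_mm,
            "objective_history": getattr(series, "objective_history", []),
            "config_hash": cfg.config_hash()}
    with open(wd / "series_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    art["series"] = series


def _load_series(wd: Path) -> recon.ImageSeries:
    vols, vox = fileio.read_series_nifti(_require(wd, "series.nii.gz",
                                                  "analyze"))
    with open(_require(wd, "series_meta.json", "analyze")) as fh:
        meta = json.load(fh)
    amp = meta.get("bin_amplitudes")
    return recon.ImageSeries(
        volumes=vols, bin_phases=np.asarray(meta["bin_phases"]),
        voxel_mm=float(meta["voxel_mm"]),
        bin_amplitudes=None if amp is None else np.asarray(amp))


def _stage_analyze(cfg: PipelineConfig, wd: Path, art: dict) -> None:
    series = art.get("series") or _load_series(wd)
    pc = cfg.preful
    pconf = preful.PrefulConfig(
        n_phases=pc.n_phases, gauss_sigma=pc.gauss_sigma,
        lowpass_hz=pc.lowpass_hz,
        breathing_period_s=cfg.phantom.breathing_period_s,
        fvl_cm_threshold=pc.fvl_cm_threshold, rvent_pct=pc.rvent_pct,
        rvent_frac=pc.rvent_frac,
        ref_quantiles=tuple(pc.ref_quantiles), cm_max_lag=pc.cm_max_lag)
    r = cfg.registration
    rparams = RegistrationParams(
        mode=r.mode, similarity=r.similarity, levels=tuple(r.levels),
        smoothing=tuple(r.smoothing), iterations=tuple(r.iterations))
    maps = preful.run_preful(series, pconf, rparams,
                             bias_correction=pc.bias_correction,
                             edge_preserving=pc.edge_preserving)
    vox = series.voxel_mm
    fileio.write_nifti(wd / "rvent_ei.nii.gz", maps.rvent_ei, vox)
    fileio.write_nifti(wd / "fvl_cm.nii.gz", maps.fvl_cm, vox)
    fileio.write_nifti(wd / "vttp.nii.gz",
                       np.nan_to_num(maps.vttp, nan=-1.0), vox)
    for name, arr in (("defect_rvent", maps.defect_rvent),
                      ("defect_fvlcm", maps.defect_fvlcm),
                      ("parenchyma", maps.parenchyma_mask)):
        fileio.write_nifti(wd / f"{name}.nii.gz", arr.astype(np.float32),
                           vox)
    summary = {"vdp_rvent_pct": maps.vdp_rvent,
               "vdp_fvlcm_pct": maps.vdp_fvlcm,
               "mean_vttp_pct": maps.mean_vttp,
               "mean_rvent": float(np.nanmean(
                   maps.rvent_ei[maps.parenchyma_mask])),
               "config_hash": cfg.config_hash(), "seed": cfg.seed}
    with open(wd / "preful_metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    art["maps"] = maps


def _stage_metrics(cfg: PipelineConfig, wd: Path, art: dict) -> None:
    series = art.get("series") or _load_series(wd)
    maps = art.get("maps")
    if maps is not None:
        rvent_ei = np.nan_to_num(maps.rvent_ei)
        parenchyma = maps.parenchyma_mask
        lung = maps.lung_mask
    else:
        rvent_ei, _ = fileio.read_nifti(
            _require(wd, "rvent_ei.nii.gz", "metrics"))
        parenchyma = fileio.read_nifti(
            _require(wd, "parenchyma.nii.gz", "metrics"))[0] > 0.5
        lung = parenchyma
        rvent_ei = np.nan_to_num(rvent_ei)
    mags = np.abs(series.volumes)
    ee, ei = preful.identify_ee_ei(mags, lung)
    lung_roi, bg_roi = metrics.default_snr_rois(mags[ei], lung)
    snr = metrics.roi_snr(mags[ei], lung_roi, bg_roi)
    sharp = metrics.sobel_sharpness(rvent_ei * parenchyma, parenchyma)
    vdp_s, _ = metrics.static_vdp(rvent_ei, parenchyma)
    report = metrics.MetricReport(snr=snr, sharpness=sharp,
                                  vdp_static=vdp_s)
    report.to_json(wd / "metrics.json")
    art["report"] = report


_STAGE_FN = {
    "simulate": _stage_simulate,
    "bin": _stage_bin,
    "recon": _stage_recon,
    "analyze": _stage_analyze,
    "metrics": _stage_metrics,
}
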