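"""Phase-resolved functional lung (PREFUL) ventilation analysis.

Turns a registered respiratory-resolved image series into static and
dynamic ventilation maps:

* RVent -- regional ventilation, the fractional parenchymal-density change
  of each voxel relative to end-expiration, (S_EE - S(t)) / S(t) in mL/mL;
  the end-inspiration map is the static ventilation surrogate.
* FVL-CM -- each voxel's flow-volume loop (dRVent/dt against RVent over
  the cycle) correlated with a high-ventilation reference loop; low values
  flag abnormal filling dynamics even when amplitude is normal.
* VTTP -- ventilation time-to-peak as a percentage of the cycle; healthy
  filling peaks near 50%.
* VDP -- ventilation defect percentages from fixed thresholds: CM < 0.9
  for FVL-CM, and RVent below 40% of its 90th percentile.

The processing chain mirrors clinical practice: resort the phases into one
canonical end-expiration -> end-inspiration -> end-expiration cycle, N4
bias-field correction, stepwise registration to end-inspiration,
Gaussian-kernel interpolation to 16 equidistant phases, temporal low-pass
filtering at 0.7 Hz plus 3D edge-preserving spatial smoothing, simple
threshold lung segmentation with vessel removal, then the parameter maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import frangi, threshold_otsu

from .recon import ImageSeries
from .registration import RegistrationParams, stepwise_register_series


@dataclass(frozen=True)
class PrefulConfig:
    n_phases: int = 16
    gauss_sigma: float = 0.3          # in units of source phase spacing
    lowpass_hz: float = 0.7
    breathing_period_s: float = 4.0
    fvl_cm_threshold: float = 0.9
    rvent_pct: float = 90.0           # percentile defining the RVent scale
    rvent_frac: float = 0.4           # threshold = frac * P{rvent_pct}
    ref_quantiles: tuple[float, float] = (0.75, 0.95)
    cm_max_lag: int = 0               # >0: max-over-circular-lag CM variant

    def __post_init__(self):
        if self.n_phases < 4:
            raise ValueError("n_phases must be >= 4")
        if not (0 < self.fvl_cm_threshold <= 1 and 0 < self.rvent_frac <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if not self.ref_quantiles[0] < self.ref_quantiles[1]:
            raise ValueError("ref_quantiles must be increasing")


@dataclass
class VentilationMaps:
    rvent_ei: np.ndarray              # mL/mL at end-inspiration
    rvent_cycle: np.ndarray           # (n_phases, ...) maps
    fvl_cm: np.ndarray                # in [-1, 1]
    vttp: np.ndarray                  # % of cycle (NaN where undefined)
    defect_rvent: np.ndarray
    defect_fvlcm: np.ndarray
    vdp_rvent: float                  # %
    vdp_fvlcm: float                  # %
    mean_vttp: float                  # %
    parenchyma_mask: np.ndarray = None
    lung_mask: np.ndarray = None
    vessel_mask: np.ndarray = None


# ---------------------------------------------------------------------------
# cycle sorting and signal conditioning
# ---------------------------------------------------------------------------

def identify_ee_ei(volumes: np.ndarray, mask: np.ndarray) -> tuple[int, int]:
    """(EE, EI) phase indices from the mask-mean lung signal.

    Parenchymal density -- hence proton signal -- is maximal at
    end-expiration and minimal at end-inspiration.
    """
    means = np.array([np.abs(v)[mask].mean() for v in volumes])
    return int(np.argmax(means)), int(np.argmin(means))


def sort_ventilation_cycle(series: ImageSeries) -> tuple[ImageSeries,
                                                         np.ndarray]:
    """Reorder phases into one canonical EE -> EI -> EE cycle.

    The end-expiration bin is found from the per-bin mean bellows amplitude
    when available (minimum amplitude = trough), else from the phase label
    nearest the trough phase pi.  Phases then run in increasing
    instantaneous-phase order, which traverses inspiration then expiration.
    Returns the reordered series and the applied index mapping.
    """
    if series.bin_phases is None:
        raise ValueError("series lacks respiratory phase labels")
    phases = np.asarray(series.bin_phases, dtype=np.float64)
    if series.bin_amplitudes is not None:
        ee = int(np.argmin(series.bin_amplitudes))
    else:
        ee = int(np.argmin(np.abs(
            ((phases - np.pi) + np.pi) % (2 * np.pi) - np.pi)))
    order = np.argsort((phases - phases[ee]) % (2 * np.pi), kind="stable")
    out = ImageSeries(
        volumes=series.volumes[order],
        bin_phases=phases[order],
        voxel_mm=series.voxel_mm,
        bin_amplitudes=(None if series.bin_amplitudes is None
                        else np.asarray(series.bin_amplitudes)[order]),
    )
    return out, order


def bias_field_correct(volume: np.ndarray, mask: np.ndarray | None = None,
                       shrink: int = 2, fitting_levels: int = 2) -> np.ndarray:
    """Divide out a multiplicative low-frequency field (N4 algorithm).

    The spline fitting is restricted to very low spatial frequencies
    (``fitting_levels``) so genuine regional ventilation contrast --
    smooth intensity structure on the ~10-voxel scale -- is not absorbed
    into the estimated field.  The output is rescaled so its mean inside
    the mask (or everywhere) matches the input, making the correction
    scale-preserving.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if np.any(vol < 0):
        warnings.warn("negative voxels clamped before bias correction",
                      stacklevel=2)
        vol = np.clip(vol, 0.0, None)
    # work on a unit-mean copy so the correction commutes with global
    # intensity scaling
    gscale = vol.mean() + 1e-300
    vol = vol / gscale
    img = sitk.GetImageFromArray(np.transpose(vol, (2, 1, 0)))
    if mask is not None:
        m_img = sitk.GetImageFromArray(
            np.transpose(mask.astype(np.uint8), (2, 1, 0)))
    else:
        m_img = sitk.GetImageFromArray(
            np.transpose(np.ones_like(vol, dtype=np.uint8), (2, 1, 0)))
    if shrink > 1:
        small = sitk.Shrink(img, [shrink] * 3)
        small_m = sitk.Shrink(m_img, [shrink] * 3)
    else:
        small, small_m = img, m_img
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([30, 25][:fitting_levels]
                                    + [20] * max(fitting_levels - 2, 0))
    n4.Execute(small + 1e-6, small_m)
    logfield = sitk.Resample(n4.GetLogBiasFieldAsImage(small), img)
    field = np.exp(np.transpose(sitk.GetArrayFromImage(logfield), (2, 1, 0)))
    out = vol / field
    sel = mask if mask is not None else np.ones_like(vol, dtype=bool)
    if out[sel].mean() > 0:
        out *= vol[sel].mean() / out[sel].mean()
    return out * gscale


def interpolate_to_phases(series: ImageSeries, config: PrefulConfig
                          ) -> ImageSeries:
    """Gaussian-kernel interpolation onto n_phases equidistant phases.

    Distances are circular on the ventilation cycle, measured in units of
    the source phase spacing; weights are normalized to one.  With
    n_phases = B and sigma -> 0 this is the identity.
    """
    if config.gauss_sigma <= 0:
        raise ValueError("gauss_sigma must be positive")
    B = series.n_phases
    if B < 2:
        raise ValueError("need at least two phases to interpolate")
    src = np.arange(B)                       # source positions, cycle = B
    out_pos = np.arange(config.n_phases) * B / config.n_phases
    d = np.abs(out_pos[:, None] - src[None, :])
    d = np.minimum(d, B - d)                 # circular distance
    w = np.exp(-0.5 * (d / config.gauss_sigma) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    vols = np.tensordot(w, series.volumes, axes=(1, 0))
    return ImageSeries(
        volumes=vols,
        bin_phases=2 * np.pi * out_pos / B - np.pi,
        voxel_mm=series.voxel_mm,
    )


def temporal_filter(series: ImageSeries, config: PrefulConfig,
                    edge_preserving: bool = True) -> ImageSeries:
    """Low-pass the per-voxel phase signal, then smooth spatially.

    The 0.7 Hz cutoff lives in real time; on the phase-resolved cycle it
    maps to the harmonic floor(0.7 * breathing period).  A cutoff below the
    fundamental keeps the fundamental (with a warning).  The spatial step
    is an edge-preserving bilateral filter whose range scale is tied to the
    image's own background noise, keeping the whole chain invariant to
    global intensity scaling.
    """
    if series.n_phases < 4:
        raise ValueError("need >= 4 phases for temporal filtering")
    cutoff = config.lowpass_hz * config.breathing_period_s
    if cutoff < 1.0:
        warnings.warn("low-pass cutoff below the breathing fundamental; "
                      "keeping the fundamental", stacklevel=2)
        cutoff = 1.0
    vols = np.asarray(series.volumes, dtype=np.float64)
    spec = np.fft.rfft(vols, axis=0)
    harm = np.arange(spec.shape[0])
    spec[harm > cutoff] = 0.0
    vols = np.fft.irfft(spec, n=vols.shape[0], axis=0)
    if edge_preserving:
        from skimage.restoration import estimate_sigma
        noise_sd = float(np.mean([estimate_sigma(v) for v in vols[:4]]))
        noise_sd = max(noise_sd, 1e-12)
        out = np.empty_like(vols)
        for t in range(vols.shape[0]):
            img = sitk.GetImageFromArray(np.transpose(vols[t], (2, 1, 0)))
            sm = sitk.Bilateral(img, domainSigma=1.0,
                                rangeSigma=2.0 * noise_sd)
            out[t] = np.transpose(sitk.GetArrayFromImage(sm), (2, 1, 0))
        vols = out
    return ImageSeries(volumes=vols, bin_phases=series.bin_phases,
                       voxel_mm=series.voxel_mm)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_lung_simple(volume: np.ndarray) -> np.ndarray:
    """Threshold-based lung cavity segmentation.

    Low-intensity connected components inside the body are extracted, the
    two largest kept (left and right lung; a trachea, being a separate
    smaller component, is dropped), and holes filled.  A deliberately
    simple stand-in for learned segmentation models.
    """
    v = np.abs(np.asarray(volume, dtype=np.float64))
    if np.ptp(v) == 0:
        raise ValueError("cannot segment a constant volume")
    thr = threshold_otsu(v)
    body = v > 0.3 * thr
    body = ndimage.binary_fill_holes(
        _largest_components(body, 1))
    interior = ndimage.binary_erosion(body, iterations=1)
    low = (v < 0.6 * np.median(v[body])) & interior
    low = ndimage.binary_opening(low)
    labels, n = ndimage.label(low)
    if n == 0:
        raise ValueError("no lung candidate component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    # guard against a single merged component: keep any second component
    # at least 20% of the largest
    if len(keep) == 2 and sizes[keep[1] - 1] < 0.2 * sizes[keep[0] - 1]:
        keep = keep[:1]
    mask = np.isin(labels, keep)
    return ndimage.binary_fill_holes(mask)


def _largest_components(mask: np.ndarray, n_keep: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:n_keep] + 1
    return np.isin(labels, keep)


def vessel_mask(volume: np.ndarray, lung_mask: np.ndarray) -> np.ndarray:
    """Bright tubular structures inside the lung (intensity + tubularness).

    The parenchyma mask for ventilation statistics is ``lung_mask`` minus
    this mask; an empty vessel mask is legitimate.
    """
    if not np.any(lung_mask):
        raise ValueError("empty lung mask")
    v = np.abs(np.asarray(volume, dtype=np.float64))
    med = np.median(v[lung_mask])
    bright = lung_mask & (v > 2.0 * med)
    if not np.any(bright):
        return np.zeros_like(lung_mask)
    tube = frangi(v, sigmas=(1.0, 2.0), black_ridges=False)
    tubular = tube > 0.05 * tube[bright].max()
    vess = bright & (tubular | ndimage.binary_dilation(bright & tubular))
    # fall back to pure intensity where tubularness finds nothing
    if vess.sum() < 0.2 * bright.sum():
        vess = bright
    return vess


# ---------------------------------------------------------------------------
# ventilation parameters
# ---------------------------------------------------------------------------

def compute_rvent(series16: ImageSeries, parenchyma_mask: np.ndarray,
                  ee_index: int = 0) -> np.ndarray:
    """Regional ventilation per phase: (S_EE - S(t)) / S(t), mL/mL.

    ``series16`` must be the registered, filtered cycle starting at
    end-expiration.  Voxels with non-positive signal are flagged NaN.
    """
    S = np.abs(np.asarray(series16.volumes, dtype=np.float64))
    see = S[ee_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = (see[None] - S) / S
    bad = (S <= 0) & parenchyma_mask[None]
    if np.any(bad):
        rv[bad] = np.nan
    return rv


def end_inspiration_index(rvent_cycle: np.ndarray,
                          parenchyma_mask: np.ndarray) -> int:
    """Phase at which the mask-mean ventilation peaks."""
    means = np.array([np.nanmean(r[parenchyma_mask]) for r in rvent_cycle])
    return int(np.argmax(means))


def flow_volume_cm(rvent_cycle: np.ndarray, parenchyma_mask: np.ndarray,
                   config: PrefulConfig) -> np.ndarray:
    """Flow-volume-loop cross-correlation metric per voxel.

    Flow is the circular first difference of RVent over the cycle.  The
    reference loop is the mean (volume, flow) trajectory of voxels whose
    end-inspiration RVent falls between the configured quantiles (a
    well-ventilated region).  CM is the Pearson correlation between the
    voxel's and the reference's concatenated standardized volume-and-flow
    series; with ``cm_max_lag > 0`` the maximum over circular lags up to
    that bound is taken instead (OFF by default so delayed filling is
    penalized).
    """
    if not np.any(parenchyma_mask):
        raise ValueError("empty parenchyma mask")
    T = rvent_cycle.shape[0]
    # guard against invalid voxels (S -> 0 divisions) outside the mask
    vol = np.clip(np.nan_to_num(rvent_cycle, nan=0.0, posinf=0.0,
                                neginf=0.0), -5.0, 5.0)
    flow = 0.5 * (np.roll(vol, -1, axis=0) - np.roll(vol, 1, axis=0))
    ei = end_inspiration_index(rvent_cycle, parenchyma_mask)
    rv_ei = rvent_cycle[ei]
    vals = rv_ei[parenchyma_mask]
    lo, hi = np.nanquantile(vals, config.ref_quantiles)
    ref_sel = parenchyma_mask & (rv_ei >= lo) & (rv_ei <= hi)
    if not np.any(ref_sel):
        raise ValueError("empty high-ventilation reference band")
    ref_v = vol[:, ref_sel].mean(axis=1)
    ref_f = flow[:, ref_sel].mean(axis=1)

    def standardize(x, axis=0):
        mu = x.mean(axis=axis, keepdims=True)
        sd = x.std(axis=axis, keepdims=True)
        return (x - mu) / np.where(sd > 0, sd, 1.0)

    ref = np.concatenate([standardize(ref_v), standardize(ref_f)])
    ref = standardize(ref)
    vox = np.concatenate([standardize(vol), standardize(flow)], axis=0)
    vox = standardize(vox, axis=0)

    def corr_with(shifted_ref):
        return np.tensordot(shifted_ref, vox, axes=(0, 0)) / (2 * T)

    cm = corr_with(ref)
    for lag in range(1, config.cm_max_lag + 1):
        for s in (lag, -lag):
            ref_l = np.concatenate([np.roll(ref[:T], s), np.roll(ref[T:], s)])
            cm = np.maximum(cm, corr_with(ref_l))
    cm = np.clip(cm, -1.0, 1.0)
    cm[~parenchyma_mask] = 0.0
    return cm


def compute_vttp(rvent_cycle: np.ndarray, parenchyma_mask: np.ndarray
                 ) -> tuple[np.ndarray, float]:
    """Ventilation time-to-peak, % of cycle; ties break to earliest phase.

    Voxels whose cycle is identically zero (or all-NaN) are undefined and
    returned as NaN; the mean is over defined parenchyma voxels.
    """
    T = rvent_cycle.shape[0]
    filled = np.nan_to_num(rvent_cycle)
    vttp = 100.0 * np.argmax(filled, axis=0) / T
    undefined = np.ptp(filled, axis=0) == 0
    vttp = vttp.astype(np.float64)
    vttp[undefined] = np.nan
    vttp[~parenchyma_mask] = np.nan
    valid = parenchyma_mask & ~undefined
    mean_vttp = float(np.nanmean(vttp[valid])) if np.any(valid) else np.nan
    return vttp, mean_vttp


def defect_maps(rvent_ei: np.ndarray, fvl_cm: np.ndarray,
                parenchyma_mask: np.ndarray, config: PrefulConfig,
                rvent_cycle: np.ndarray | None = None,
                **extra) -> VentilationMaps:
    """Threshold the parameter maps into defect masks and VDP scalars.

    RVent defects lie below ``rvent_frac`` times the ``rvent_pct``-th
    percentile of RVent inside the mask; FVL-CM defects lie below the fixed
    CM threshold.
    """
    if not np.any(parenchyma_mask):
        raise ValueError("empty parenchyma mask")
    vals = rvent_ei[parenchyma_mask]
    thr_rv = config.rvent_frac * np.nanpercentile(vals, config.rvent_pct)
    defect_rv = parenchyma_mask & (np.nan_to_num(rvent_ei,
                                                 nan=-np.inf) < thr_rv)
    defect_cm = parenchyma_mask & (fvl_cm < config.fvl_cm_threshold)
    n = parenchyma_mask.sum()
    vdp_rv = 100.0 * defect_rv.sum() / n
    vdp_cm = 100.0 * defect_cm.sum() / n
    if rvent_cycle is None:
        rvent_cycle = rvent_ei[None]
    vttp, mean_vttp = compute_vttp(rvent_cycle, parenchyma_mask)
    extra.setdefault("parenchyma_mask", parenchyma_mask)
    return VentilationMaps(
        rvent_ei=rvent_ei, rvent_cycle=rvent_cycle, fvl_cm=fvl_cm,
        vttp=vttp, defect_rvent=defect_rv, defect_fvlcm=defect_cm,
        vdp_rvent=float(vdp_rv), vdp_fvlcm=float(vdp_cm),
        mean_vttp=mean_vttp,
        **{k: v for k, v in extra.items()
           if k in ("parenchyma_mask", "lung_mask", "vessel_mask")})


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_preful(series: ImageSeries, config: PrefulConfig | None = None,
               reg_params: RegistrationParams | None = None,
               bias_correction: bool = True,
               edge_preserving: bool = True) -> VentilationMaps:
    """Full PREFUL chain on a reconstructed respiratory-resolved series.

    sort -> bias-field correction -> stepwise registration to
    end-inspiration -> 16-phase interpolation -> temporal/spatial filtering
    -> segmentation -> RVent / FVL-CM / VTTP / VDP maps.
    """
    config = config or PrefulConfig()
    if reg_params is None:
        # final-analysis registration: full multiresolution schedule with
        # locally-normalized (cross-correlation-style) forces, which keep
        # the parenchymal density signal out of the motion estimate
        reg_params = RegistrationParams(
            similarity="cross_correlation", levels=(6, 4, 2, 1),
            smoothing=(3.0, 2.0, 1.0, 0.5),
            iterations=(150, 150, 100, 80))
    sorted_series, _ = sort_ventilation_cycle(series)
    mags = np.abs(sorted_series.volumes).astype(np.float64)
    # normalize once so every later step (registration forces, bilateral
    # range scale, thresholds) sees the same numbers regardless of any
    # global intensity scaling of the input series
    mags = mags / (np.mean(mags) + 1e-300)

    rough = segment_lung_simple(mags.mean(axis=0))
    if bias_correction:
        mags = np.stack([bias_field_correct(v, mask=None) for v in mags])
    ee, ei = identify_ee_ei(mags, rough)

    # rectangular lung-covering mask for the registration metric
    idx = np.nonzero(rough)
    box = np.zeros_like(rough)
    box[idx[0].min():idx[0].max() + 1, idx[1].min():idx[1].max() + 1,
        idx[2].min():idx[2].max() + 1] = True
    warped, _ = stepwise_register_series(
        mags, ei, reg_params, (series.voxel_mm,) * 3, mask=box)

    reg_series = ImageSeries(volumes=warped,
                             bin_phases=sorted_series.bin_phases,
                             voxel_mm=series.voxel_mm)
    series16 = interpolate_to_phases(reg_series, config)
    series16 = temporal_filter(series16, config,
                               edge_preserving=edge_preserving)

    ei_vol = series16.volumes[
        identify_ee_ei(series16.volumes, rough)[1]]
    lung = segment_lung_simple(ei_vol)
    vessels = vessel_mask(ei_vol, lung)
    # drop the pleural rim (two voxels at this coarse resolution):
    # partial-volume voxels mix moving boundary tissue into the
    # parenchymal signal
    core = ndimage.binary_erosion(lung, iterations=2)
    parenchyma = core & ~vessels

    # the filtered cycle may start anywhere; roll so EE (max signal) leads
    ee16 = identify_ee_ei(series16.volumes, parenchyma)[0]
    cycle = np.roll(series16.volumes, -ee16, axis=0)
    series16 = ImageSeries(volumes=cycle, bin_phases=series16.bin_phases,
                           voxel_mm=series16.voxel_mm)

    rvent_cycle = compute_rvent(series16, parenchyma, ee_index=0)
    ei16 = end_inspiration_index(rvent_cycle, parenchyma)
    rvent_ei = rvent_cycle[ei16]
    cm = flow_volume_cm(rvent_cycle, parenchyma, config)
    return defect_maps(rvent_ei, cm, parenchyma, config,
                       rvent_cycle=rvent_cycle, lung_mask=lung,
                       vessel_mask=vessels)
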