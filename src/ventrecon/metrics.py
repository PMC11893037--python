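"""Image-quality and cohort-comparison metrics.

ROI-based SNR, Sobel gradient sharpness, the static gas-MRI-style
ventilation defect percentage (signal below 60% of the whole-lung mean,
after bias correction), and Bland-Altman / Pearson comparison of VDP
lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, stats


@dataclass
class MetricReport:
    snr: float | None = None
    sharpness: float | None = None
    vdp_static: float | None = None
    bias: float | None = None
    pearson_r: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: v for k, v in asdict(self).items()
                       if v is not None}, fh, indent=2)


def roi_snr(volume: np.ndarray, lung_roi: np.ndarray,
            background_roi: np.ndarray) -> float:
    """mean(signal ROI) / SD(background ROI).

    The ROIs must be disjoint and fixed across any settings being
    compared.  No Rayleigh-background correction is applied by default.
    """
    if not np.any(lung_roi) or not np.any(background_roi):
        raise ValueError("ROIs must be non-empty")
    if np.any(lung_roi & background_roi):
        raise ValueError("ROIs must be disjoint")
    v = np.abs(np.asarray(volume, dtype=np.float64))
    sd = v[background_roi].std()
    if sd == 0:
        raise ValueError("zero background standard deviation")
    return float(v[lung_roi].mean() / sd)


def default_snr_rois(volume: np.ndarray, lung_mask: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Signal/background ROIs on the central coronal slice.

    The signal ROI is the lung parenchyma on the coronal slice through the
    lung's center of mass (carina level for a thorax); the background ROI
    is the air outside the body on the same slice.
    """
    from skimage.filters import threshold_otsu
    com = ndimage.center_of_mass(lung_mask)
    y0 = int(round(com[1]))
    sl = np.zeros_like(lung_mask)
    sl[:, y0, :] = True
    lung_roi = lung_mask & sl
    v = np.abs(volume)
    body = ndimage.binary_fill_holes(v > 0.3 * threshold_otsu(v))
    bg = sl & ~ndimage.binary_dilation(body | lung_mask, iterations=3)
    bg[[0, -1], :, :] = False
    bg[:, :, [0, -1]] = False
    if not np.any(bg):   # fall back to the volume corners
        bg = np.zeros_like(lung_mask)
        bg[:3, :3, :3] = True
        bg &= ~lung_roi
    return lung_roi, bg


_SOBEL_AXES = (0, 1, 2)


def sobel_sharpness(volume: np.ndarray, mask: np.ndarray) -> float:
    """Mean 3D Sobel gradient magnitude inside the mask."""
    if not np.any(mask):
        raise ValueError("empty mask")
    v = np.abs(np.asarray(volume, dtype=np.float64))
    grads = [ndimage.sobel(v, axis=ax) for ax in _SOBEL_AXES]
    mag = np.sqrt(np.sum([g**2 for g in grads], axis=0))
    return float(mag[mask].mean())


def static_vdp(ventilation_volume: np.ndarray, lung_mask: np.ndarray,
               threshold_frac: float = 0.6,
               bias_correct: bool = True) -> tuple[float, np.ndarray]:
    """Static VDP: % of lung voxels below 60% of the whole-lung mean.

    Bias-field correction is applied first (as for gas-density ventilation
    images); the metric is invariant to global positive scaling.
    """
    if not np.any(lung_mask):
        raise ValueError("empty lung mask")
    v = np.abs(np.asarray(ventilation_volume, dtype=np.float64))
    if bias_correct and np.ptp(v[lung_mask]) > 0:
        from .preful import bias_field_correct
        v = bias_field_correct(v, mask=lung_mask)
    thr = threshold_frac * v[lung_mask].mean()
    defect = lung_mask & (v < thr)
    return float(100.0 * defect.sum() / lung_mask.sum()), defect


def compare_vdp(vdp_a, vdp_b) -> tuple[float, tuple[float, float], float]:
    """Bland-Altman bias and limits of agreement, plus Pearson r.

    bias = mean(a - b); limits = bias +/- 1.96 * SD(a - b).
    """
    a = np.asarray(vdp_a, dtype=np.float64)
    b = np.asarray(vdp_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D lists")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    d = a - b
    bias = float(d.mean())
    loa = 1.96 * d.std(ddof=1)
    r = float(stats.pearsonr(a, b).statistic)
    return bias, (bias - loa, bias + loa), r
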