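import numpy as np
import pytest

from ventrecon.phantom import PhantomSpec, build_phantom, breathing_wave
from ventrecon.recon import ImageSeries
from ventrecon.preful import (PrefulConfig, bias_field_correct,
                              compute_rvent, compute_vttp, defect_maps,
                              flow_volume_cm, interpolate_to_phases,
                              run_preful, segment_lung_simple,
                              sort_ventilation_cycle, temporal_filter,
                              vessel_mask)


def _series(volumes, phases=None, amplitudes=None, voxel_mm=1.0):
    B = volumes.shape[0]
    if phases is None:
        phases = -np.pi + 2 * np.pi * (np.arange(B) + 0.5) / B
    return ImageSeries(volumes=volumes, bin_phases=np.asarray(phases),
                       voxel_mm=voxel_mm,
                       bin_amplitudes=None if amplitudes is None
                       else np.asarray(amplitudes))


# --- cycle sorting ---------------------------------------------------------

def test_sort_already_canonical_is_identity(rng):
    vols = rng.random((6, 4, 4, 4))
    amps = np.array([0.0, 0.3, 0.8, 1.0, 0.7, 0.2])   # EE first
    s = _series(vols, amplitudes=amps)
    out, order = sort_ventilation_cycle(s)
    assert np.array_equal(order, np.arange(6))
    assert np.array_equal(out.volumes, vols)


def test_sort_reversed_input_reverses(rng):
    vols = rng.random((6, 4, 4, 4))
    phases = -np.pi + 2 * np.pi * (np.arange(6) + 0.5) / 6
    amps = np.array([0.0, 0.3, 0.8, 1.0, 0.7, 0.2])
    rev = slice(None, None, -1)
    s = _series(vols[rev], phases[rev], amps[rev])
    out, order = sort_ventilation_cycle(s)
    assert np.array_equal(out.volumes, vols)


def test_sort_matches_amplitude_ordering():
    """Hilbert-phase ordering agrees with the bellows amplitude cycle."""
    B = 8
    phases = -np.pi + 2 * np.pi * (np.arange(B) + 0.5) / B
    phis = ((phases + np.pi) / (2 * np.pi)) % 1.0
    amps = breathing_wave(phis)
    perm = np.random.default_rng(0).permutation(B)
    vols = np.arange(B, dtype=float)[:, None, None, None] * np.ones((4, 4, 4))
    s = _series(vols[perm], phases[perm], amps[perm])
    out, _ = sort_ventilation_cycle(s)
    sorted_amps = np.asarray(out.bin_amplitudes)
    assert sorted_amps[0] == sorted_amps.min()       # starts at EE
    peak = int(np.argmax(sorted_amps))
    # symmetric sampling can tie adjacent bins; require monotone ramps
    assert np.all(np.diff(sorted_amps[:peak + 1]) >= 0)
    assert np.all(np.diff(sorted_amps[peak:]) <= 0)


def test_sort_missing_labels_errors(rng):
    s = ImageSeries(volumes=rng.random((4, 4, 4, 4)), bin_phases=None,
                    voxel_mm=1.0)
    with pytest.raises(ValueError):
        sort_ventilation_cycle(s)


# --- bias-field correction -------------------------------------------------

def test_bias_free_volume_unchanged():
    # structured volume with edges: the spline field cannot absorb it
    vol = np.ones((32, 32, 32))
    vol[8:24, 8:24, 8:24] = 2.0
    vol[12:20, 12:20, 12:20] = 0.5
    out = bias_field_correct(vol)
    nrmse = np.linalg.norm(out - vol) / np.linalg.norm(vol)
    assert nrmse < 0.02


def test_synthetic_bias_recovered():
    n = 32
    base = np.ones((n, n, n))
    base[8:24, 8:24, 8:24] = 2.0
    x = np.linspace(-1, 1, n)
    bias = np.exp(0.4 * (x[:, None, None] + x[None, :, None]))
    corrected = bias_field_correct(base * bias)
    flat = np.zeros_like(base, dtype=bool)
    flat[10:22, 10:22, 10:22] = True
    inhom_before = (base * bias)[flat].std() / (base * bias)[flat].mean()
    inhom_after = corrected[flat].std() / corrected[flat].mean()
    assert inhom_after < 0.5 * inhom_before


def test_bias_correction_idempotent(smooth_volume):
    once = bias_field_correct(smooth_volume)
    twice = bias_field_correct(once)
    assert np.linalg.norm(twice - once) / np.linalg.norm(once) < 0.01


def test_negative_voxels_clamped_with_warning(smooth_volume):
    vol = smooth_volume - 0.2
    with pytest.warns(UserWarning, match="clamped"):
        bias_field_correct(vol)


# --- phase interpolation ---------------------------------------------------

def test_interpolation_identity_when_sigma_tiny(rng):
    vols = rng.random((8, 4, 4, 4))
    s = _series(vols)
    out = interpolate_to_phases(s, PrefulConfig(n_phases=8,
                                                gauss_sigma=1e-4))
    assert np.allclose(out.volumes, vols)


def test_interpolation_preserves_constant(rng):
    vols = np.ones((6, 4, 4, 4)) * 2.5
    out = interpolate_to_phases(_series(vols), PrefulConfig(n_phases=16))
    assert np.allclose(out.volumes, 2.5)


def test_interpolation_attenuation_matches_kernel_transfer():
    """Sinusoid amplitude after resampling matches the Gaussian kernel's
    own transfer (computed independently from the stated weights)."""
    B, n_out, sigma = 24, 16, 0.3
    t = np.arange(B)
    signal = np.sin(2 * np.pi * t / B)
    vols = signal[:, None, None, None] * np.ones((2, 2, 2))
    out = interpolate_to_phases(_series(vols),
                                PrefulConfig(n_phases=n_out,
                                             gauss_sigma=sigma))
    y = out.volumes[:, 0, 0, 0]
    # fit amplitude of the resampled sinusoid
    tp = np.arange(n_out) * B / n_out
    design = np.stack([np.sin(2 * np.pi * tp / B),
                       np.cos(2 * np.pi * tp / B)], axis=1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    measured = np.hypot(*coef)
    # independent oracle: attenuation of a unit complex exponential under
    # normalized circular Gaussian weights
    attens = []
    for p in tp:
        d = np.abs(t - p)
        d = np.minimum(d, B - d)
        w = np.exp(-0.5 * (d / sigma) ** 2)
        w /= w.sum()
        attens.append(np.abs(np.sum(w * np.exp(2j * np.pi * (t - p) / B))))
    assert measured == pytest.approx(np.mean(attens), rel=0.02)


def test_interpolation_rejects_bad_sigma(rng):
    s = _series(rng.random((6, 2, 2, 2)))
    with pytest.raises(ValueError):
        interpolate_to_phases(s, PrefulConfig(gauss_sigma=-1.0))


# --- temporal filtering ----------------------------------------------------

def test_fundamental_preserved():
    T = 16
    sig = np.sin(2 * np.pi * np.arange(T) / T)
    vols = sig[:, None, None, None] * np.ones((4, 4, 4)) + 2.0
    cfg = PrefulConfig(breathing_period_s=4.0)    # cutoff harmonic 2.8
    out = temporal_filter(_series(vols), cfg, edge_preserving=False)
    assert np.allclose(out.volumes, vols, atol=0.01)


def test_high_harmonic_removed():
    T = 16
    t = np.arange(T)
    fundamental = np.sin(2 * np.pi * t / T)
    h5 = 0.5 * np.sin(2 * np.pi * 5 * t / T)
    vols = (fundamental + h5)[:, None, None, None] * np.ones((4, 4, 4)) + 2
    cfg = PrefulConfig(breathing_period_s=4.0)
    out = temporal_filter(_series(vols), cfg, edge_preserving=False)
    resid = out.volumes[:, 0, 0, 0] - (fundamental + 2)
    # remaining harmonic-5 content < 5% of its injected amplitude
    amp5 = np.abs(np.fft.rfft(resid)[5]) * 2 / T
    assert amp5 < 0.05 * 0.5


def test_cutoff_below_fundamental_warns():
    vols = np.random.default_rng(0).random((8, 4, 4, 4))
    cfg = PrefulConfig(breathing_period_s=1.0)    # 0.7 * 1 < 1
    with pytest.warns(UserWarning, match="fundamental"):
        temporal_filter(_series(vols), cfg, edge_preserving=False)


def test_edge_preserving_filter_denoises_without_blurring_edge():
    rng = np.random.default_rng(4)
    n = 32
    step = np.zeros((n, n, n))
    step[n // 2:, :, :] = 1.0
    noisy = step + 0.05 * rng.standard_normal(step.shape)
    vols = np.stack([noisy] * 8)      # constant in time
    cfg = PrefulConfig(breathing_period_s=4.0)
    out = temporal_filter(_series(vols), cfg, edge_preserving=True)
    sm = out.volumes[0]
    flat = sm[4:12, 4:-4, 4:-4]
    assert flat.std() < 0.5 * 0.05
    # 10-90% edge width along x grows by less than one voxel
    prof = sm[:, n // 2, n // 2]
    lo = np.argmax(prof > 0.1)
    hi = np.argmax(prof > 0.9)
    assert hi - lo <= 2               # ideal step: width 1


# --- segmentation ----------------------------------------------------------

def test_phantom_lung_segmentation_dice(phantom32):
    vol = phantom32.volume_at(1.0)
    mask = segment_lung_simple(vol)
    truth = phantom32.lung_mask(1.0)
    dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
    assert dice > 0.9


def test_uniform_volume_segmentation_errors():
    with pytest.raises(ValueError):
        segment_lung_simple(np.ones((16, 16, 16)))


def test_trachea_excluded_from_lung_mask():
    m = build_phantom(PhantomSpec(grid_size=48, seed=2, with_trachea=True))
    mask = segment_lung_simple(m.volume_at(0.5))
    overlap = (mask & m.trachea).sum() / max(m.trachea.sum(), 1)
    assert overlap < 0.2


def test_vessels_flagged_inside_lung():
    m = build_phantom(PhantomSpec(grid_size=48, seed=2, with_vessels=True))
    vol = m.volume_at(0.0)
    lung = m.lung          # material-frame truth at EE
    vess = vessel_mask(vol, lung | m.vessels)
    recall = (vess & m.vessels).sum() / m.vessels.sum()
    assert recall >= 0.8


def test_vessel_free_lung_nearly_empty_mask(phantom32):
    vol = phantom32.volume_at(0.0)
    vess = vessel_mask(vol, phantom32.lung)
    assert vess.sum() < 0.01 * phantom32.lung.sum()
    assert not np.any(vess & ~phantom32.lung)


# --- ventilation parameters ------------------------------------------------

def _uniform_mask(shape=(6, 6, 6)):
    m = np.zeros(shape, dtype=bool)
    m[1:-1, 1:-1, 1:-1] = True
    return m


def test_rvent_zero_for_static_signal():
    vols = np.ones((16, 6, 6, 6)) * 1.3
    mask = _uniform_mask()
    rv = compute_rvent(_series(vols), mask)
    assert np.allclose(rv[:, mask], 0.0)


def test_rvent_formula_value():
    vols = np.ones((4, 4, 4, 4)) * 1.2
    vols[2] = 1.0                      # end-inspiration signal
    rv = compute_rvent(_series(vols), np.ones((4, 4, 4), dtype=bool))
    assert np.allclose(rv[2], 0.2 / 1.0)


def test_rvent_flags_nonpositive_signal():
    vols = np.ones((4, 4, 4, 4))
    vols[1, 2, 2, 2] = 0.0
    mask = np.ones((4, 4, 4), dtype=bool)
    rv = compute_rvent(_series(vols), mask)
    assert np.isnan(rv[1, 2, 2, 2])


def _sinusoid_cycle(T=16, shape=(6, 6, 6), amp=0.3, lag_mask=None,
                    lag=0.0):
    t = np.arange(T) / T
    cyc = amp * np.sin(np.pi * t)[:, None, None, None] * np.ones(shape)
    if lag_mask is not None:
        lagged = amp * np.sin(np.pi * ((t - lag) % 1.0))
        cyc[:, lag_mask] = lagged[:, None]
    return cyc


def test_cm_is_one_for_reference_like_voxels():
    mask = _uniform_mask()
    cyc = _sinusoid_cycle()
    cm = flow_volume_cm(cyc, mask, PrefulConfig())
    assert np.allclose(cm[mask], 1.0, atol=1e-9)


def test_cm_negative_for_half_cycle_shift():
    mask = _uniform_mask()
    shifted = np.zeros(mask.shape, dtype=bool)
    shifted[1, 1, 1] = True
    cyc = _sinusoid_cycle(lag_mask=shifted, lag=0.5)
    cm = flow_volume_cm(cyc, mask, PrefulConfig())
    assert cm[1, 1, 1] < 0


def test_cm_detects_quarter_cycle_lag():
    mask = _uniform_mask((8, 8, 8))
    lagged = np.zeros(mask.shape, dtype=bool)
    lagged[2:4, 2:4, 2:4] = True
    cyc = _sinusoid_cycle(shape=(8, 8, 8), lag_mask=lagged, lag=0.25)
    cm = flow_volume_cm(cyc, mask, PrefulConfig())
    assert np.all(cm[lagged & mask] < 0.9)
    assert np.all(cm[mask & ~lagged] > 0.95)


def test_cm_lag_search_variant_forgives_delay():
    mask = _uniform_mask((8, 8, 8))
    lagged = np.zeros(mask.shape, dtype=bool)
    lagged[2:4, 2:4, 2:4] = True
    cyc = _sinusoid_cycle(shape=(8, 8, 8), lag_mask=lagged, lag=0.25)
    cm = flow_volume_cm(cyc, mask, PrefulConfig(cm_max_lag=4))
    assert np.all(cm[lagged & mask] > 0.9)


def test_cm_empty_reference_band_errors():
    mask = _uniform_mask()
    cyc = np.zeros((16,) + mask.shape)
    with pytest.raises(ValueError):
        flow_volume_cm(cyc, np.zeros_like(mask), PrefulConfig())


def test_vttp_symmetric_filling_peaks_mid_cycle():
    """Healthy filling peaks at ~50% of the ventilation cycle."""
    mask = _uniform_mask()
    cyc = _sinusoid_cycle()
    vttp, mean_vttp = compute_vttp(cyc, mask)
    assert mean_vttp == pytest.approx(50.0, abs=100.0 / 16 / 2)


def test_vttp_lagged_voxels_shifted():
    mask = _uniform_mask()
    lagged = np.zeros(mask.shape, dtype=bool)
    lagged[1:3, 1:3, 1:3] = True
    cyc = _sinusoid_cycle(lag_mask=lagged, lag=0.125)
    vttp, _ = compute_vttp(cyc, mask)
    assert np.all(np.abs(vttp[lagged & mask] - 62.5) <= 100.0 / 16)


def test_vttp_constant_cycle_undefined():
    mask = _uniform_mask()
    cyc = np.zeros((16,) + mask.shape)
    vttp, mean_vttp = compute_vttp(cyc, mask)
    assert np.all(np.isnan(vttp[mask]))
    assert np.isnan(mean_vttp)


# --- defect maps -----------------------------------------------------------

def test_uniform_rvent_no_defects():
    mask = _uniform_mask()
    rv = np.full(mask.shape, 0.3)
    cm = np.ones(mask.shape)
    maps = defect_maps(rv, cm, mask, PrefulConfig())
    assert maps.vdp_rvent == 0.0
    assert maps.vdp_fvlcm == 0.0


def test_vdp_counts_known_defect_fraction():
    """20% of voxels far below threshold -> VDP exactly 20%."""
    mask = _uniform_mask((10, 10, 10))
    n = mask.sum()
    rv = np.full(mask.shape, 1.0)
    flat = np.nonzero(mask.ravel())[0]
    defect_idx = flat[:int(0.2 * n)]
    rv.ravel()[defect_idx] = 0.01
    cm = np.ones(mask.shape)
    maps = defect_maps(rv, cm, mask, PrefulConfig())
    assert maps.vdp_rvent == pytest.approx(100.0 * len(defect_idx) / n)


def test_defect_masks_nested_in_parenchyma():
    mask = _uniform_mask()
    rng = np.random.default_rng(0)
    rv = rng.random(mask.shape)
    cm = rng.uniform(-1, 1, mask.shape)
    maps = defect_maps(rv, cm, mask, PrefulConfig())
    assert not np.any(maps.defect_rvent & ~mask)
    assert not np.any(maps.defect_fvlcm & ~mask)
    assert 0 <= maps.vdp_rvent <= 100 and 0 <= maps.vdp_fvlcm <= 100


def test_empty_mask_errors():
    with pytest.raises(ValueError):
        defect_maps(np.ones((4, 4, 4)), np.ones((4, 4, 4)),
                    np.zeros((4, 4, 4), dtype=bool), PrefulConfig())


# --- full chain ------------------------------------------------------------

@pytest.fixture(scope="module")
def rendered_series():
    """Clean phantom-rendered respiratory series (no reconstruction)."""
    spec = PhantomSpec(grid_size=32, seed=2)
    m = build_phantom(spec)
    B = 8
    phases = -np.pi + 2 * np.pi * (np.arange(B) + 0.5) / B
    phis = ((phases + np.pi) / (2 * np.pi)) % 1.0
    amps = breathing_wave(phis)
    vols = np.stack([m.volume_at(a, cycle_phase=p)
                     for a, p in zip(amps, phis)])
    series = ImageSeries(volumes=vols, bin_phases=phases,
                         voxel_mm=spec.voxel_mm,
                         bin_amplitudes=amps - 0.5)
    return m, series


def test_full_chain_recovers_mean_ventilation(rendered_series):
    m, series = rendered_series
    maps = run_preful(series, PrefulConfig(breathing_period_s=4.0))
    mean_rv = np.nanmean(maps.rvent_ei[maps.parenchyma_mask])
    assert mean_rv == pytest.approx(m.spec.tidal_amplitude, rel=0.15)
    assert maps.vdp_rvent < 5.0
    assert maps.mean_vttp == pytest.approx(50.0, abs=5.0)


def test_full_chain_scale_invariant(rendered_series):
    """Global intensity scaling leaves every ventilation output unchanged."""
    m, series = rendered_series
    cfg = PrefulConfig(breathing_period_s=4.0)
    a = run_preful(series, cfg)
    scaled = ImageSeries(volumes=series.volumes * 37.5,
                         bin_phases=series.bin_phases,
                         voxel_mm=series.voxel_mm,
                         bin_amplitudes=series.bin_amplitudes)
    b = run_preful(scaled, cfg)
    assert b.vdp_rvent == pytest.approx(a.vdp_rvent, abs=1e-9)
    assert b.vdp_fvlcm == pytest.approx(a.vdp_fvlcm, abs=1e-9)
    assert b.mean_vttp == pytest.approx(a.mean_vttp, abs=1e-9)
    assert np.allclose(np.nan_to_num(b.rvent_ei),
                       np.nan_to_num(a.rvent_ei), atol=1e-8)
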