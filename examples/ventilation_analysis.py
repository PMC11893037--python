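"""PREFUL ventilation analysis of a respiratory-resolved image series.

Renders a clean phantom series with a known ventilation defect, runs the
full PREFUL chain (cycle sorting, bias correction, registration to
end-inspiration, 16-phase interpolation, filtering, segmentation, maps)
and compares the recovered regional-ventilation statistics with the
phantom's ground truth.
"""

import numpy as np

from ventrecon import (DefectSpec, ImageSeries, PhantomSpec, PrefulConfig,
                       breathing_wave, build_phantom, run_preful)

spec = PhantomSpec(
    grid_size=32, seed=2,
    defects=(DefectSpec(center_voxel=(9, 15, 17), radius_mm=40.0,
                        amplitude_scale=0.1),))
model = build_phantom(spec)

B = 8
phases = -np.pi + 2 * np.pi * (np.arange(B) + 0.5) / B
cycle_fracs = ((phases + np.pi) / (2 * np.pi)) % 1.0
states = breathing_wave(cycle_fracs)
volumes = np.stack([model.volume_at(a, cycle_phase=p)
                    for a, p in zip(states, cycle_fracs)])
series = ImageSeries(volumes=volumes, bin_phases=phases,
                     voxel_mm=spec.voxel_mm,
                     bin_amplitudes=states - 0.5)

maps = run_preful(series, PrefulConfig(breathing_period_s=4.0))

par = maps.parenchyma_mask
truth = model.ground_truth(1.0)
print(f"parenchyma voxels: {par.sum()}")
print(f"mean RVent:  {np.nanmean(maps.rvent_ei[par]):.3f} mL/mL "
      f"(prescribed fractional ventilation {spec.tidal_amplitude})")
print(f"VDP_RVent:   {maps.vdp_rvent:.1f}%  "
      f"(true amplitude-defect fraction "
      f"{100 * truth['defect_mask'][truth['parenchyma_mask']].mean():.1f}%)")
print(f"VDP_FVL-CM:  {maps.vdp_fvlcm:.1f}%")
print(f"mean VTTP:   {maps.mean_vttp:.1f}% of cycle "
      "(healthy filling peaks near 50%)")
print("\nThe defect sphere fills at 10% of the normal rate, so it falls "
      "below the 40%-of-90th-percentile RVent threshold and drives "
      "VDP_RVent toward the prescribed defect fraction.")
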