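"""Simulate a free-breathing acquisition and sort it into respiratory bins.

Builds a small breathing-thorax phantom, generates a FLORET-style
trajectory and bellows trace, synthesizes multicoil k-space, and runs the
respiratory gating chain.  Prints the per-bin counts and sharing: every
bin holds the same number of excitations, and no bin borrows more than
half its members from neighbors.
"""

import numpy as np

from ventrecon import (BinningConfig, PhantomSpec, TrajectoryConfig,
                       bin_bellows, build_phantom, generate_floret,
                       make_coil_maps, nyquist_coverage,
                       simulate_acquisition, simulate_bellows)

n = 32
spec = PhantomSpec(grid_size=n, fov_mm=320, n_coils=2, seed=7)
model = build_phantom(spec)

tcfg = TrajectoryConfig(fov_mm=320, res_mm=320 / n, samples_per_readout=48,
                        n_excitations=6000)
traj = generate_floret(tcfg)
print(f"trajectory: {traj.n_excitations} readouts x "
      f"{traj.samples_per_readout} samples, kmax {traj.kmax:.4f} cycles/mm")
print(f"Nyquist cell coverage: {nyquist_coverage(traj, tcfg):.2f} "
      "(fraction of k-space cells visited)")

bellows = simulate_bellows(spec, 6000, tr_s=0.02, amp_jitter=0.05,
                           period_jitter=0.05, noise_sd=0.02)
sens = make_coil_maps(2, n)
kdata = simulate_acquisition(model, traj, bellows, sens, noise_sd=0.5)
print(f"k-space: {kdata.samples.shape} (coils, excitations, samples)")

bins, smoothed = bin_bellows(bellows, BinningConfig(n_bins=8,
                                                    total_budget=None),
                             breathing_period_s=spec.breathing_period_s)
print(f"\n{bins.n_bins} bins x {bins.per_bin_count} excitations "
      f"(excluded: {len(bins.excluded)})")
for b in range(bins.n_bins):
    shared = bins.shared_count(b)
    print(f"  bin {b}: target phase {bins.target_phases[b]:+.2f} rad, "
          f"mean bellows {bins.mean_amplitude[b]:+.3f}, "
          f"shared {100 * shared / bins.per_bin_count:.0f}%")
print("\nBins near phase -pi/+pi sit at end-expiration (trough); the "
      "sharing percentages stay at or below 50% by construction.")
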