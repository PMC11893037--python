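"""Motion-compensated low-rank reconstruction of a simulated acquisition.

Simulates a small breathing acquisition, bins it, estimates coil
sensitivities and k-space preconditioning weights, and solves the
nuclear-norm-regularized reconstruction.  Prints the composite objective
per motion re-estimation pass (it should not increase) and the error of
each respiratory phase against the phantom rendered at that phase's state.
"""

import numpy as np

from ventrecon import (BinningConfig, PhantomSpec, ReconConfig,
                       TrajectoryConfig, ball_limit, bellows_to_state,
                       bin_bellows, bin_kspace, build_phantom,
                       compute_preconditioner, cycle_phase_from_trace,
                       estimate_sensitivities, generate_floret,
                       make_coil_maps, mocolor, simulate_acquisition,
                       simulate_bellows)

n = 32
spec = PhantomSpec(grid_size=n, fov_mm=320, n_coils=4, seed=3)
model = build_phantom(spec)
traj = generate_floret(TrajectoryConfig(fov_mm=320, res_mm=320 / n,
                                        samples_per_readout=64,
                                        n_excitations=6000))
bellows = simulate_bellows(spec, 6000, tr_s=0.035, amp_jitter=0.05,
                           period_jitter=0.05, noise_sd=0.01)
coils = make_coil_maps(4, n)
kdata = simulate_acquisition(model, traj, bellows, coils, noise_sd=0.5)

bins, smoothed = bin_bellows(kdata.bellows,
                             BinningConfig(n_bins=4, total_budget=None),
                             breathing_period_s=spec.breathing_period_s)
kbins = bin_kspace(kdata, bins)
sens = estimate_sensitivities(kbins, (n, n, n))
precond = compute_preconditioner(kbins.coords, kbins.fov_mm, (n, n, n))

series, motion = mocolor(kbins, sens, precond, ReconConfig(), verbose=True)

states = bellows_to_state(smoothed, spec.breathing_period_s)
phases = cycle_phase_from_trace(smoothed)
print("\nper-phase error against the phantom at matched state "
      "(band-limited to the sampled k-space ball):")
for b in range(series.n_phases):
    idx = bins.bin_indices[b]
    a = float(np.median(states[idx]))
    ph = float(np.median(phases[idx]))
    truth = np.abs(ball_limit(model.volume_at(a, cycle_phase=ph)))
    mag = np.abs(series.volumes[b])
    scale = (mag * truth).sum() / (mag * mag).sum()
    nrmse = np.linalg.norm(scale * mag - truth) / np.linalg.norm(truth)
    print(f"  phase {b}: respiratory state {a:.2f}, NRMSE {nrmse:.3f}")
print("\nEnd-expiration phases carry the most data (tidal breathing "
      "dwells near FRC), so their errors are usually lowest.")
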