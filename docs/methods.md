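# Methods

`ventrecon` implements a complete free-breathing proton lung-MRI
ventilation-mapping chain — sampling simulation, respiratory gating,
motion-compensated low-rank reconstruction, and phase-resolved functional
lung (PREFUL) analysis — validated end-to-end on a synthetic breathing
thorax with known regional ventilation. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Sampling geometry

The simulated acquisition plays Fermat-spiral interleaves,
`r(θ) = kmax·sqrt(θ/θmax)`, outward from the k-space center, modulated
onto cones whose axes form up to three mutually orthogonal hubs; each
excitation is one arm. Samples are spaced uniformly in arc length so a
readout of J samples covers its arm evenly, and the number of spiral
turns is set so that arc-length spacing matches one Nyquist cell at the
prescribed sampling percentage. Interleave ordering uses the golden-angle
azimuthal increment; cone latitudes follow a van der Corput sequence in
sin(latitude). The two sequences must be mutually incommensurate: the
golden *fraction* is algebraically related to the golden angle
(1 − 1/φ = 1/φ²), so pairing them collapses the (azimuth, latitude)
sequence onto a line and leaves k-space cells systematically unvisited.
Gradient waveforms, slew limits and T2* decay are not modeled.

Defaults mirror a clinical prescription scaled to desk size: FOV 320 mm,
three hubs, 45° hub half-angle, and (for the default pipeline) a 48³
matrix (6.7 mm voxels), 64 samples per readout, 20,000 excitations at
TR = 3.8 ms (~76 s of simulated scanning; the clinical counterpart uses
~140,000 excitations over ~7 min at 1.6 mm).

## Breathing-thorax phantom

The phantom is defined in material (end-expiration) coordinates: body
wall, abdomen, mediastinum, two lung ellipsoids, optional trachea and
bright lung vessels. Breathing is a one-dimensional cranio-caudal stretch
of each lung column whose pointwise expansion rate equals the voxel's
fractional-ventilation amplitude FV, so

* the displacement integrates from zero at the apex to the full
  diaphragm excursion `tidal_amplitude × lung height` at the base,
* parenchymal density follows `ρ(a) = ρ_EE / (1 + a·FV)` with
  respiratory state `a ∈ [0,1]`,
* the geometric Jacobian is exactly `1 + a·FV`, so lung mass is conserved
  by construction (verified numerically to <1% with supersampled
  rendering; rendering supersamples the material columns so interface
  blending does not create mass).

Defaults: `tidal_amplitude = 0.3` (so FV = 0.30 mL/mL in normal
parenchyma — deep tidal breathing, chosen to give the desk-scale
reconstruction a robust ventilation signal), `lung_density_ee = 0.25`
against a body wall of 0.85, breathing period 4 s with 5% cycle-to-cycle
amplitude and period jitter.

Ventilation defects are clusters of overlapping spheres ("lobar-like"
blobs) in which FV is scaled by `amplitude_scale`, with a graded ~1.5
voxel border. Both choices are deliberate: scattering many small sharp
spheres at 6.7 mm voxels puts over a third of the defect volume into
partial-volume boundary, which no analysis could classify cleanly, and
real hypoventilated regions are contiguous with graded margins.
Phase-lagged regions delay the local filling waveform by a fraction of
the cycle (the canonical waveform is `a(φ) = sin²(πφ)`); they drive
flow-volume-loop and time-to-peak abnormality while leaving ventilation
amplitude intact. The default lag is 0.2 cycles: a lagged voxel's
end-inspiration ventilation is `FV·cos²(π·lag)`, and keeping that above
the 40%-of-90th-percentile defect threshold requires `lag < ~0.235`,
while loop correlation at lag 0.2 is still far below the 0.9 defect
threshold — i.e. the region is invisible to the static metric and obvious
to the dynamic one, which is the phenomenon under test.

The bellows trace is a quasi-sinusoid with jitter, optional drift and
logged outlier spikes. Bellows amplitude maps to respiratory state by
sliding three-cycle min-max normalization (robust to drift); cycle phase
comes from the analytic-signal (Hilbert) phase. Coil sensitivities are
four broad complex Gaussian lobes with gentle phase ramps, emulating the
smooth profiles that virtual-coil compression of a many-channel thorax
array produces; raw-data noise defaults to a level that yields
reconstructed SNR near the mid-teens.

The forward simulation renders the phantom at each excitation's state
(the cycle quantized into 48 phase groups for tractability), applies coil
maps and evaluates the NUFFT at that readout's coordinates.

## Respiratory binning

The smoothed bellows trace (moving average, default window = quarter
breathing period) is thresholded at ±2 SD to exclude outliers, Hilbert
phase is computed, and excitations are allocated to B equispaced phase
targets with *equal counts* per bin: each bin takes its n nearest
excitations by circular phase distance, borrowing from neighbors under a
50% per-bin sharing cap (a member counts as shared when its nearest
target is another bin). At the full budget of 240,000 the per-bin counts
are 30,000/20,000/15,000/12,000/10,000/7,500/6,000 for 8–40 bins. For
desk-scale runs the budget scales as `T = 1.7 × usable` (rounded to a
multiple of B) — the same budget-to-acquired ratio as the full-scale
prescription; a factor of 2 would demand exactly 50% sharing and violate
the cap for any bin whose primary count fluctuates below average.

## NUFFT

Kaiser-Bessel gridding (oversampling 2.0, width 4 by default; the
reconstruction operators use 1.5/3 for speed) with the kernel's analytic
transform as apodization. The adjoint is the exact conjugate transpose of
the forward factorization, so the operator pair passes a machine-precision
dot test independent of gridding accuracy; forward accuracy against a
brute-force NDFT is ~1e-3 at the defaults. Because a center-out
trajectory samples a ball and never the spectral corners, the SENSE
operator projects images onto the sampled ball — without this, iterative
solvers park semiconvergent noise in the unconstrained corner subspace.
Accuracy comparisons against ground truth therefore use ball-band-limited
references ("matched resolution").

## Coil-sensitivity estimation

Initial maps are the classical self-calibration ratio: density-compensated
adjoint images of the central k-space ball, divided by their
root-sum-of-squares, phase-referenced to a smoothed virtual body coil
(the coil sum) so the maps carry only a low-bandwidth common phase, then
signal-confidence-weighted smoothing. This ratio has a deterministic
boundary-mixing bias in low-signal regions (the lung interior), so two
passes of JSENSE-style refinement follow: a motion-averaged CG image of a
random excitation subset is held fixed while each map is re-fitted as a
small block of spectral coefficients (12³) by conjugate gradient against
the raw data. On the default phantom this brings the in-lung coil-vector
error from ~9% to ~3–4%, which the undersampled per-bin SENSE problem
rewards several-fold in image quality.

## Motion-compensated low-rank reconstruction

The solver addresses

    x = argmin_x ½ Σ_b ‖√P_b (F_b S x_b − y_b)‖² + λ_L ‖M x‖_*

by proximal gradient with three nested loops: gradient steps on the
preconditioned data fidelity (inner, 5), proximal cycles that warp the
phase stack to a reference phase, soft-threshold its singular values and
unwarp (outer, 3), and motion-field re-estimation from the current images
(superior, 3). Per-bin CG-SENSE initializes the stack. Preconditioning
weights are single-channel reciprocal-density (first density-compensation
iterate). The forward model is normalized to unit gram norm so the
gradient step is ρ (=1), and the soft-threshold is λ_L·ρ·σ₁, with σ₁ the
leading singular value of the initial phase stack — λ_L is therefore
dimensionless, and its default 0.01 sits where aliasing suppression and
dynamic-signal blur trade off (thresholds several times larger visibly
over-smooth the respiratory dynamics). The warp adjoint is approximated by
fixed-point field inversion, and prox warps use cubic interpolation —
with linear warps the interpolation error at coarse desk-scale voxels
makes the composite objective climb several percent per superior
iteration; with cubic it is non-increasing to well within 2%. The
reference phase is the lowest-amplitude (end-expiration) bin, where tidal
breathing concentrates data.

Motion fields — both here and in the final analysis — are estimated from
*locally normalized* images (each volume divided by its own smooth local
mean). This is essential, not cosmetic: inflation changes parenchymal
intensity itself, and demons-style forces on raw intensities "explain"
that density change with spurious compressions, erasing the ventilation
signal the pipeline exists to measure. Local normalization plays the same
role as the local cross-correlation metrics used by clinical registration
toolkits. The registration backend is a multiresolution symmetric-forces
demons (SimpleITK) with an optional translation stage; the contract is
metric non-worsening and determinism, not bit-compatibility with any
external toolkit.

## PREFUL analysis

The reconstructed phases are resorted into one canonical EE→EI→EE cycle
(end-expiration identified by bellows amplitude, or by maximal lung
signal), N4 bias-corrected, stepwise-registered to end-inspiration
(neighbor-to-neighbor field composition, metric restricted to a
rectangular lung-covering box; full multiresolution schedule
6×4×2×1 / 150×150×100×80), interpolated to 16 equidistant phases with a
circular Gaussian kernel (σ = 0.3 source-phase units), low-passed at
0.7 Hz (cutoff harmonic = 0.7 × breathing period), and smoothed with an
edge-preserving bilateral filter whose range scale tracks the image's own
noise estimate. N4 is restricted to two fitting levels: at finer spline
scales it absorbs genuine ~10-voxel ventilation contrast (a uniform-FV
defect blob looks exactly like a smooth intensity inhomogeneity at
end-inspiration) into the "bias" field. The whole chain normalizes the
series once at entry, making every output exactly invariant to global
intensity scaling.

Segmentation keeps the two largest low-intensity components inside the
body (dropping a trachea, which forms its own component), fills holes,
and removes bright tubular vessels (intensity + Frangi tubularness). The
parenchyma mask excludes a two-voxel pleural rim — one acquisition PSF
width at desk-scale voxels — because partial-volume voxels on the moving
lung boundary carry mixed signal that no registration can unmix.

Ventilation parameters, per voxel on the 16-phase cycle starting at EE:

* RVent(t) = (S_EE − S(t)) / S(t); the end-inspiration map is the static
  surrogate (mL/mL). With the phantom's density law, a perfectly
  processed voxel recovers exactly its FV.
* Flow-volume-loop correlation (CM): Pearson correlation between the
  voxel's and a reference region's concatenated standardized (volume,
  flow) series, flow being the circular first difference. The reference
  loop is the mean over voxels whose end-inspiration RVent lies in the
  75–95% quantile band. A lag-searching variant exists behind
  `cm_max_lag` but is off by default, precisely so that delayed filling
  is penalized.
* VTTP = argmax phase / n_phases × 100% (ties to the earliest phase;
  constant cycles are undefined/NaN). Healthy filling peaks near 50%.
* Defects: RVent below 40% of its in-mask 90th percentile; CM below the
  fixed 0.9. VDPs are defect-voxel percentages of the parenchyma.

## Quality metrics

ROI SNR (mean lung-parenchyma signal over background SD on the central
coronal slice, no Rayleigh correction), Sobel sharpness (mean 3D gradient
magnitude in-mask), the static gas-MRI-style VDP (signal below 60% of the
whole-lung mean after bias correction), and Bland-Altman + Pearson
comparison of VDP lists.

## Problem sizes and study conditions

The default validation configuration is a 48³ phantom, 8 respiratory
bins, 4 coils, 20,000 excitations of 64 samples; ~18% of the parenchyma
is prescribed as amplitude defects (`amplitude_scale = 0.15`) plus a ~6%
lagged-filling region. Component tests run at 16³–32³. These sizes are
the package's desk-scale operating point: large enough that binning,
registration and low-rank reconstruction all do real work, small enough
that the full chain completes in minutes.

## What the phantom does and does not show

Passing tests demonstrate internal consistency of the whole chain —
geometry, gating arithmetic, operator correctness, solver behavior, and
recovery of prescribed ventilation amplitude and dynamics — under a
motion model (1D columnar stretch), a noise model (white complex
Gaussian), and smooth synthetic coils. They do not demonstrate robustness
to cardiac motion, bulk motion, off-resonance/T2* decay, anatomically
realistic airway/vascular structure, partial-volume behavior at clinical
1.6 mm resolution, or scanner trajectory imperfections; none of these are
modeled. Clinical headline numbers (cohort VDP medians, correlation with
gas-ventilation MRI) depend on patient scans and are out of scope.

## Numerical choices and degenerate inputs

Seeded `numpy` generators drive every stochastic component; registration
and solvers contain no unseeded randomness, so fixed-seed runs are
bit-reproducible. Constant images are rejected by registration and phase
estimation; zero-variance bellows traces exclude nothing (with a
warning); zero k-space data reconstructs to zero; empty masks raise.
Circular-distance ties in binning break toward the lower excitation
index. The MoCoLoR divergence guard aborts after two >10% objective
rises.

## Known limitations

Per-voxel reconstruction fidelity at desk scale is limited by per-bin
angular sampling and coil-map self-calibration; the voxelwise
RVent-vs-truth regression is the most demanding end-to-end statistic and
the first to degrade if the per-bin spoke count is reduced. The warp
adjoint inside the solver is approximate (inverse-field warping), so the
objective is monotone only within tolerance. The simple threshold
segmenter assumes the phantom's intensity layout and is not a general
lung segmenter.
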