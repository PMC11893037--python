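"""Motion-compensated low-rank reconstruction of respiratory-resolved images.

Solves, per acquisition,

    x = argmin_x  1/2 sum_b || sqrt(P_b) (F_b S x_b - y_b) ||_2^2
                  + lambda_L * || M x ||_*

where x is the stack of B respiratory-phase volumes, F_b the per-bin NUFFT,
S the coil sensitivities, P_b diagonal k-space preconditioning weights,
M the per-phase motion warps onto a reference phase, and ||.||_* the
nuclear norm of the phase-by-voxel matrix.  The solver is proximal
gradient with three nested loops mirroring common practice for this
problem class:

* inner iterations -- gradient steps on the preconditioned data fidelity,
* outer iterations -- proximal cycles (warp, singular-value
  soft-threshold, unwarp),
* superior iterations -- re-estimation of the motion fields from the
  current phase images.

Initialization is per-bin CG-SENSE.  The warp adjoint is approximated by
inverse-field warping; the solver contract is a non-increasing composite
objective across superior iterations (within tolerance -- motion
re-estimation changes the regularizer itself and may transiently raise it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .binning import KSpaceBins
from .nufft import NufftOperator
from .registration import (RECON_MOTION_PARAMS, DeformationField,
                           RegistrationParams, apply_field, invert_field,
                           register_pair)


@dataclass
class SensitivityMaps:
    maps: np.ndarray                  # (C, nx, ny, nz) complex
    support: np.ndarray | None = None

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclass
class Preconditioner:
    """Nonnegative diagonal k-space weights, one array per bin, (I, J)."""

    weights: list[np.ndarray]

    def __post_init__(self):
        for w in self.weights:
            if not np.all(np.isfinite(w)) or np.any(w < 0):
                raise ValueError("preconditioner weights must be finite "
                                 "and nonnegative")


@dataclass
class ImageSeries:
    """B respiratory-phase volumes plus their gating metadata."""

    volumes: np.ndarray               # (B, nx, ny, nz), complex or real
    bin_phases: np.ndarray            # per-volume respiratory phase label
    voxel_mm: float
    bin_amplitudes: np.ndarray | None = None  # mean bellows amplitude

    @property
    def n_phases(self) -> int:
        return self.volumes.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.volumes)


@dataclass(frozen=True)
class ReconConfig:
    lambda_l: float = 0.01
    inner_iters: int = 5
    outer_iters: int = 3
    superior_iters: int = 3
    step_rho: float = 1.0
    recon_res_mm: float | None = None     # None -> trajectory resolution
    nufft_width: int = 3
    cg_init_iters: int = 8
    weighted_residual: bool = True        # P inside the objective

    def __post_init__(self):
        if self.lambda_l < 0:
            raise ValueError("lambda_l must be >= 0")
        if min(self.inner_iters, self.outer_iters, self.superior_iters) < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.step_rho <= 0:
            raise ValueError("step_rho must be positive")


class SenseOperator:
    """Preconditioned NUFFT-SENSE forward model for one respiratory bin.

    The image is spectrally projected onto the sampled k-space ball
    (|k| <= grid Nyquist radius) before the NUFFT: center-out trajectories
    carry no information about the spectral corners, and leaving that
    subspace unconstrained lets iterative solvers deposit semiconvergent
    noise there.  The projection is self-adjoint, so the operator pair
    remains an exact adjoint pair.
    """

    def __init__(self, coords_grid: np.ndarray, grid_shape, sens: np.ndarray,
                 weights: np.ndarray | None = None, width: int = 3,
                 ball_limit: bool = True, oversamp: float = 1.5):
        self.nufft = NufftOperator(coords_grid, grid_shape, width=width,
                                   oversamp=oversamp)
        self.sens = sens
        self.weights = (np.ones(self.nufft.n_samples) if weights is None
                        else weights.ravel())
        self._ball = None
        if ball_limit:
            axes = [np.arange(g) - g // 2 for g in grid_shape]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            radius = min(grid_shape) / 2
            self._ball = np.fft.ifftshift(
                gx**2 + gy**2 + gz**2 <= radius**2)

    def project(self, x: np.ndarray) -> np.ndarray:
        """Spectral projection onto the sampled ball (self-adjoint)."""
        if self._ball is None:
            return x
        spec = np.fft.fftn(np.fft.ifftshift(x)) * self._ball
        return np.fft.fftshift(np.fft.ifftn(spec))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(C, M) k-space samples of image x."""
        x = self.project(x)
        return np.stack([self.nufft.forward(x * s) for s in self.sens])

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.nufft.grid_shape, dtype=np.complex128)
        for c, s in enumerate(self.sens):
            out += np.conj(s) * self.nufft.adjoint(y[c])
        return self.project(out)

    def grad(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Gradient of 1/2 || sqrt(P) (A x - y) ||^2."""
        return self.adjoint(self.weights[None, :] * (self.forward(x) - y))

    def fidelity(self, x: np.ndarray, y: np.ndarray) -> float:
        r = self.forward(x) - y
        return float(0.5 * np.sum(self.weights[None, :] * np.abs(r) ** 2))

    def power_norm(self, n_iter: int = 6, seed: int = 0) -> float:
        """Largest eigenvalue of A^H P A (power iteration)."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.nufft.grid_shape) + 1j * \
            rng.standard_normal(self.nufft.grid_shape)
        lam = 1.0
        for _ in range(n_iter):
            x = self.adjoint(self.weights[None, :] * self.forward(x))
            lam = np.linalg.norm(x)
            if lam == 0:
                return 1.0
            x /= lam
        return float(lam)


# ---------------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------------

def estimate_sensitivities(kbins: KSpaceBins,
                           grid_shape: tuple[int, int, int],
                           lowpass_frac: float = 0.4,
                           max_excitations: int = 2000,
                           refine_iters: int = 2) -> SensitivityMaps:
    """Coil maps: low-frequency ratio estimate plus JSENSE refinement.

    The initial maps are adjoint-gridded low-resolution coil images
    divided by their root-sum-of-squares (the classical self-calibrating
    ratio).  ``refine_iters`` passes of JSENSE-style alternation then
    re-fit each map as a low-bandwidth spectral field by least squares
    against the raw multicoil data, given a motion-averaged coil-combined
    image -- this removes the boundary-mixing bias the ratio estimate
    suffers in low-signal regions such as the lung interior.
    """
    C = kbins.n_coils
    coords = np.concatenate([c.reshape(-1, 3) for c in kbins.coords])
    samples = np.concatenate(
        [s.reshape(C, -1) for s in kbins.samples], axis=1)
    coords_grid = coords * kbins.fov_mm
    n = min(grid_shape)
    r = np.linalg.norm(coords_grid, axis=1)
    keep = r <= lowpass_frac * n / 2
    coords_grid, samples, r = coords_grid[keep], samples[:, keep], r[keep]
    max_points = max_excitations * 64
    if coords_grid.shape[0] > max_points:
        # random (seeded) subset: strided subsampling of structured
        # readouts would alias coherently into the calibration images
        sel = np.random.default_rng(0).choice(coords_grid.shape[0],
                                              size=max_points,
                                              replace=False)
        coords_grid, samples, r = coords_grid[sel], samples[:, sel], r[sel]
    if C == 1:
        return SensitivityMaps(np.ones((1,) + tuple(grid_shape),
                                       dtype=np.complex128))
    # cosine-taper the cutoff to suppress truncation ringing in the maps
    taper = np.cos(0.5 * np.pi * r / (lowpass_frac * n / 2)) ** 2
    op = NufftOperator(coords_grid, grid_shape)
    # density-compensate the adjoint so the center-heavy sampling does not
    # over-blur the calibration images
    dens = op.sample_density()
    w = taper / np.maximum(dens, 1e-3 * dens.max())
    imgs = np.stack([op.adjoint(w * samples[c]) for c in range(C)])
    imgs = np.stack([gaussian_filter(im.real, 1.0)
                     + 1j * gaussian_filter(im.imag, 1.0) for im in imgs])
    sos = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    support = sos > 0.1 * sos.max()
    # virtual-body-coil phase reference: dividing by the phase of the coil
    # sum cancels the object phase shared by all coils.  The reference is
    # smoothed first so the maps only ever carry a low-bandwidth common
    # phase -- a rough reference would push the consistent image outside
    # the reconstruction's spectral ball
    vb = imgs.sum(axis=0)
    vb = gaussian_filter(vb.real, 2.0) + 1j * gaussian_filter(vb.imag, 2.0)
    ref = vb / np.maximum(np.abs(vb), 1e-12 * np.abs(vb).max())
    maps = imgs * np.conj(ref)[None] / np.maximum(sos, 1e-12 * sos.max())
    # signal-confidence-weighted smoothing: the ratio is unreliable in
    # low-signal regions (lung interior, background), so interpolate it
    # there from the surrounding high-signal tissue
    w = sos**2
    sigma = max(1.5, min(grid_shape) / 16.0)
    sm_w = gaussian_filter(w, sigma) + 1e-12 * w.max()
    maps = np.stack([
        (gaussian_filter((m * w).real, sigma)
         + 1j * gaussian_filter((m * w).imag, sigma)) / sm_w
        for m in maps])
    sos2 = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= np.maximum(sos2, 1e-12 * sos2.max())
    sens = SensitivityMaps(maps, support=support)
    if refine_iters > 0:
        sens = _jsense_refine(kbins, sens, grid_shape,
                              n_passes=refine_iters)
    return sens


def _jsense_refine(kbins: KSpaceBins, sens: SensitivityMaps, grid_shape,
                   n_passes: int = 2, coef_size: int = 12,
                   max_points: int = 250_000,
                   cg_iters: int = 12) -> SensitivityMaps:
    """JSENSE alternation: coil-combined image <-> low-bandwidth maps.

    Each map is parameterized by a small central block of spectral
    coefficients (``coef_size``^3) and fitted to the raw data by CG on the
    normal equations of  y_c = W F(x0 * B(coef_c)),  with x0 the current
    motion-averaged CG-SENSE image of a random subset of all excitations.
    """
    C = kbins.n_coils
    n = min(grid_shape)
    coords = np.concatenate([c.reshape(-1, 3)
                             for c in kbins.coords]) * kbins.fov_mm
    samples = np.concatenate([s.reshape(C, -1) for s in kbins.samples],
                             axis=1)
    if coords.shape[0] > max_points:
        sel = np.random.default_rng(1).choice(coords.shape[0],
                                              size=max_points,
                                              replace=False)
        coords, samples = coords[sel], samples[:, sel]
    op = NufftOperator(coords, grid_shape, width=3, oversamp=1.5)
    dens = op.sample_density()
    w = 1.0 / np.maximum(dens, 1e-3 * dens.max())
    mcoef = coef_size
    s0 = n // 2 - mcoef // 2
    blk = slice(s0, s0 + mcoef)

    def smooth_field(coef):
        pad = np.zeros(grid_shape, dtype=np.complex128)
        pad[blk, blk, blk] = coef
        return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(pad))) * n**1.5

    def smooth_field_adj(field):
        spec = np.fft.fftshift(np.fft.fftn(
            np.fft.ifftshift(field))) / n**1.5
        return spec[blk, blk, blk]

    for _ in range(n_passes):
        full_op = SenseOperator(coords, grid_shape, sens.maps, weights=w,
                                width=3, oversamp=1.5)
        x0, _ = cgsense_recon(samples.reshape(C, -1, 1), None, sens,
                              op=full_op, n_iters=10)
        new_maps = np.empty_like(sens.maps)
        for c in range(C):
            yc = w * samples[c]

            def fwd(coef):
                return w * op.forward(x0 * smooth_field(coef))

            def adj(y):
                return smooth_field_adj(np.conj(x0) * op.adjoint(y))

            b = adj(yc)
            coef = np.zeros((mcoef,) * 3, dtype=np.complex128)
            r = b.copy()
            p = r.copy()
            rs = np.vdot(r, r).real
            for _ in range(cg_iters):
                Ap = adj(fwd(p))
                denom = np.vdot(p, Ap).real
                if denom <= 0:
                    break
                alpha = rs / denom
                coef += alpha * p
                r -= alpha * Ap
                rs_new = np.vdot(r, r).real
                if rs_new <= 1e-14 * rs:
                    break
                p = r + (rs_new / rs) * p
                rs = rs_new
            new_maps[c] = smooth_field(coef)
        sos = np.sqrt(np.sum(np.abs(new_maps) ** 2, axis=0))
        sens = SensitivityMaps(
            new_maps / np.maximum(sos, 1e-12 * sos.max()),
            support=sens.support)
    return sens


def compute_preconditioner(coords_per_bin: list[np.ndarray], fov_mm: float,
                           grid_shape: tuple[int, int, int]
                           ) -> Preconditioner:
    """Single-channel diagonal k-space weights per bin.

    The weight of each sample is the reciprocal of the local gridded
    sampling density (the first density-compensation iterate), which
    flattens the frequency response of the gram operator: constant for
    fully sampled Cartesian patterns, growing with |k| for center-out
    trajectories.  Weights are normalized to unit mean per bin.
    """
    weights = []
    for coords in coords_per_bin:
        shape = coords.shape[:-1]
        flat = coords.reshape(-1, 3) * fov_mm
        if not np.any(np.abs(flat) > 0):
            raise ValueError("degenerate all-zero trajectory")
        op = NufftOperator(flat, grid_shape, width=3)
        dens = op.sample_density()
        w = 1.0 / np.maximum(dens, 1e-3 * dens.max())
        w /= w.mean()
        weights.append(w.reshape(shape))
    return Preconditioner(weights)


def cgsense_recon(y_bin: np.ndarray, coords_bin: np.ndarray,
                  sens: SensitivityMaps, weights: np.ndarray | None = None,
                  n_iters: int = 10, fov_mm: float | None = None,
                  width: int = 3,
                  op: SenseOperator | None = None
                  ) -> tuple[np.ndarray, list[float]]:
    """Preconditioned CG-SENSE for a single respiratory bin.

    Conjugate gradient on the normal equations A^H P A x = A^H P y from a
    zero start.  Returns the volume and the per-iteration quadratic
    objective 1/2||sqrt(P)(Ax - y)||^2, which is non-increasing.
    """
    C = y_bin.shape[0]
    y = y_bin.reshape(C, -1)
    if op is None:
        coords_grid = coords_bin.reshape(-1, 3) * fov_mm
        op = SenseOperator(coords_grid, sens.grid, sens.maps,
                           weights=weights, width=width)
    b = op.adjoint(op.weights[None, :] * y)
    x = np.zeros(op.nufft.grid_shape, dtype=np.complex128)
    obj = [op.fidelity(x, y)]
    if np.linalg.norm(b) == 0:
        return x, obj
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(n_iters):
        Ap = op.adjoint(op.weights[None, :] * op.forward(p))
        denom = np.vdot(p, Ap).real
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * Ap
        obj.append(op.fidelity(x, y))
        rs_new = np.vdot(r, r).real
        if rs_new <= 1e-14 * rs:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, obj


def nuclear_prox(stack: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding of the phase-by-voxel matrix."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite input to nuclear_prox")
    shape = stack.shape
    X = stack.reshape(shape[0], -1)
    if tau == 0:
        return stack.copy()
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return ((U * s) @ Vh).reshape(shape)


def nuclear_norm(stack: np.ndarray) -> float:
    s = np.linalg.svd(stack.reshape(stack.shape[0], -1), compute_uv=False)
    return float(s.sum())


@dataclass
class MotionFieldSet:
    fields: list[DeformationField]
    inverse_fields: list[DeformationField]
    ref_bin: int


def _estimate_motion(mags: np.ndarray, ref: int,
                     params: RegistrationParams, spacing: float
                     ) -> MotionFieldSet:
    from .registration import structural_normalize
    # fields come from locally-normalized images: inflation changes the
    # parenchymal intensity itself, and raw-intensity registration would
    # absorb that density signal into spurious compressions
    imgs = [structural_normalize(m) for m in mags]
    fields, inverses = [], []
    for b in range(mags.shape[0]):
        if b == ref:
            zero = DeformationField(
                np.zeros(mags.shape[1:] + (3,)), (spacing,) * 3)
            fields.append(zero)
            inverses.append(zero)
            continue
        f = register_pair(imgs[b], imgs[ref], params, (spacing,) * 3)
        fields.append(f)
        inverses.append(invert_field(f))
    return MotionFieldSet(fields, inverses, ref)


def mocolor(kbins: KSpaceBins, sens: SensitivityMaps,
            precond: Preconditioner, config: ReconConfig,
            motion_params: RegistrationParams = RECON_MOTION_PARAMS,
            ref_bin: int | None = None, verbose: bool = False
            ) -> tuple[ImageSeries, MotionFieldSet]:
    """Alternating motion estimation and low-rank proximal-gradient solve.

    The reference phase for motion estimation defaults to the bin with the
    lowest mean bellows amplitude (end-expiration, where tidal breathing
    spends most time).  Raises on divergence (composite objective rising
    >10% twice).
    """
    B = kbins.n_bins
    grid = sens.grid
    voxel_mm = kbins.fov_mm / grid[0]
    if B == 1 and config.lambda_l > 0:
        warnings.warn("single bin: low-rank term degenerates; running "
                      "preconditioned SENSE", stacklevel=2)

    # per-bin operators (trajectory cropped to the recon Nyquist ball)
    ops, ys = [], []
    for b in range(B):
        coords_grid = kbins.coords[b].reshape(-1, 3) * kbins.fov_mm
        y = kbins.samples[b].reshape(kbins.n_coils, -1)
        w = precond.weights[b].ravel().copy()
        keep = np.all(np.abs(coords_grid) <= grid[0] / 2, axis=1)
        coords_grid, y, w = coords_grid[keep], y[:, keep], w[keep]
        if not config.weighted_residual:
            w = np.ones_like(w)
        ops.append(SenseOperator(coords_grid, grid, sens.maps, weights=w,
                                 width=config.nufft_width))
        ys.append(y)

    # CG-SENSE initialization
    x = np.stack([cgsense_recon(ys[b].reshape(kbins.n_coils, -1, 1),
                                None, sens, op=ops[b],
                                n_iters=config.cg_init_iters)[0]
                  for b, _ in enumerate(ops)])

    # normalize so lambda_l is scale-meaningful
    scale = np.percentile(np.abs(x), 99.5)
    if scale > 0:
        x = x / scale
        ys = [y / scale for y in ys]

    if ref_bin is None:
        amp = kbins.bins.mean_amplitude
        ref_bin = int(np.argmin(amp)) if amp is not None else 0

    # normalize the forward model so the gram operator has unit norm: the
    # gradient step is then rho and the SVT threshold lambda_l * rho acts
    # on the unit image scale
    L = max(op.power_norm() for op in ops)
    for op in ops:
        op.weights = op.weights / L
    step = config.step_rho
    # the low-rank weight is dimensionless: the SVT threshold acts
    # relative to the spectral norm of the initial phase stack, so
    # lambda_l ~ 0.01 trades aliasing suppression against dynamic-signal
    # blur on the scale where both live
    sigma1 = float(np.linalg.svd(x.reshape(B, -1),
                                 compute_uv=False)[0]) if B > 1 else 1.0
    tau = config.lambda_l * config.step_rho * sigma1
    lam_abs = config.lambda_l * sigma1

    def objective(xs, motion):
        fid = sum(op.fidelity(xs[b], ys[b]) for b, op in enumerate(ops))
        if config.lambda_l == 0:
            return fid
        warped = np.stack([apply_field(xs[b], motion.fields[b])
                           for b in range(B)])
        return fid + lam_abs * nuclear_norm(warped)

    obj_hist = []
    n_rises = 0
    motion = None
    for sup in range(config.superior_iters):
        motion = _estimate_motion(np.abs(x), ref_bin, motion_params,
                                  voxel_mm)
        for outer in range(config.outer_iters):
            for inner in range(config.inner_iters):
                for b, op in enumerate(ops):
                    x[b] = x[b] - step * op.grad(x[b], ys[b])
            if config.lambda_l > 0 and B > 1:
                warped = np.stack([apply_field(x[b], motion.fields[b],
                                               order=3)
                                   for b in range(B)])
                warped = nuclear_prox(warped, tau)
                x = np.stack([apply_field(warped[b],
                                          motion.inverse_fields[b],
                                          order=3)
                              for b in range(B)])
                x[ref_bin] = warped[ref_bin]
        obj = objective(x, motion)
        obj_hist.append(obj)
        if verbose:
            print(f"superior {sup}: objective {obj:.4e}")
        if len(obj_hist) >= 2 and obj > 1.10 * obj_hist[-2]:
            n_rises += 1
            if n_rises >= 2:
                raise RuntimeError(
                    f"MoCoLoR diverging: objective history {obj_hist}")

    if scale > 0:
        x = x * scale
    series = ImageSeries(
        volumes=x,
        bin_phases=kbins.bins.target_phases.copy(),
        voxel_mm=voxel_mm,
        bin_amplitudes=(None if kbins.bins.mean_amplitude is None
                        else kbins.bins.mean_amplitude.copy()),
    )
    series.objective_history = obj_hist
    return series, motion
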