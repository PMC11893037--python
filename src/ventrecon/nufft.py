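"""Non-uniform FFT by Kaiser-Bessel gridding on an oversampled Cartesian grid.

The forward operator evaluates the non-uniform DFT

    s_j = sum_n x(n) exp(-2*pi*i k_j . n / N),   n centered on the grid,

for arbitrary 3D sample coordinates ``k_j`` (in cycles per field of view,
i.e. grid units), by apodization -> zero-padded FFT -> sparse kernel
interpolation.  The adjoint is the exact conjugate transpose of the forward
map (every factor -- diagonal apodization, zero-padding, FFT, sparse
interpolation -- is transposed individually), so the operator pair passes
a machine-precision adjoint (dot) test regardless of the gridding
approximation error.

Accuracy relative to the exact NDFT is governed by the oversampling factor
and kernel width; the defaults (2.0, 4) give ~1e-4 relative error, far
below the noise floor of any simulated acquisition here.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import i0


def _kb_beta(width: int, oversamp: float) -> float:
    # Beatty et al.'s minimum-aliasing-error choice of the shape parameter.
    arg = (width / oversamp) ** 2 * (oversamp - 0.5) ** 2 - 0.8
    return np.pi * np.sqrt(max(arg, 0.1))


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel C(u) on |u| <= width/2, in padded-grid units."""
    frac = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=np.float64)
    ok = frac > 0
    out[ok] = i0(beta * np.sqrt(frac[ok])) / i0(beta)
    return out


def _kb_apodization(n: int, grid: int, width: int, beta: float) -> np.ndarray:
    """Fourier transform of the KB kernel at centered image indices.

    c(m) = W/I0(beta) * sinh(sqrt(beta^2 - (pi W m / G)^2)) / sqrt(...),
    continued with sin for negative square-root arguments.
    """
    m = np.arange(n) - n // 2
    arg = beta**2 - (np.pi * width * m / grid) ** 2
    c = np.empty(n, dtype=np.float64)
    pos = arg > 0
    sq = np.sqrt(np.abs(arg))
    c[pos] = np.sinh(sq[pos]) / sq[pos]
    c[~pos] = np.sinc(sq[~pos] / np.pi)  # sin(x)/x
    return c * width / i0(beta)


class NufftOperator:
    """Planned type-2 (forward) / type-1 (adjoint) NUFFT for fixed coordinates.

    Parameters
    ----------
    coords :
        (M, 3) sample coordinates in cycles per FOV (grid units), i.e.
        ``k_cycles_per_mm * fov_mm``; valid range is [-N/2, N/2] per axis.
    grid_shape :
        Image grid dimensions (nx, ny, nz).
    oversamp, width :
        Gridding oversampling factor and kernel width (padded-grid samples).
    """

    def __init__(self, coords: np.ndarray, grid_shape: tuple[int, int, int],
                 oversamp: float = 2.0, width: int = 4):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (M, 3)")
        self.grid_shape = tuple(int(g) for g in grid_shape)
        self.oversamp = float(oversamp)
        self.width = int(width)
        self.n_samples = coords.shape[0]
        self._padded = tuple(int(np.ceil(g * oversamp / 2) * 2)
                             for g in self.grid_shape)
        beta = _kb_beta(self.width, self.oversamp)
        self._apod = [
            _kb_apodization(n, g, self.width, beta)
            for n, g in zip(self.grid_shape, self._padded)
        ]
        self._interp = self._build_interp(coords, beta)
        self._interp_h = self._interp.conj().T.tocsr()

    def _build_interp(self, coords: np.ndarray, beta: float) -> sp.csr_matrix:
        M = coords.shape[0]
        W = self.width
        G = self._padded
        idx_ax, w_ax = [], []
        for d in range(3):
            # padded-grid coordinate of each sample along this axis
            kappa = coords[:, d] * self.oversamp
            base = np.ceil(kappa - W / 2.0).astype(np.int64)
            offs = base[:, None] + np.arange(W)[None, :]          # (M, W)
            w_ax.append(_kb_kernel(offs - kappa[:, None], W, beta))
            idx_ax.append(np.mod(offs, G[d]))
        ix, iy, iz = idx_ax
        wx, wy, wz = w_ax
        cols = ((ix[:, :, None, None] * G[1] + iy[:, None, :, None]) * G[2]
                + iz[:, None, None, :]).reshape(M, -1)
        weights = (wx[:, :, None, None] * wy[:, None, :, None]
                   * wz[:, None, None, :]).reshape(M, -1)
        rows = np.repeat(np.arange(M, dtype=np.int64), W**3)
        mat = sp.csr_matrix(
            (weights.ravel(), (rows, cols.ravel())),
            shape=(M, int(np.prod(G))),
        )
        mat.sum_duplicates()
        return mat

    # -- padding helpers ---------------------------------------------------
    def _pad_slices(self):
        return tuple(
            slice(G // 2 - n // 2, G // 2 - n // 2 + n)
            for n, G in zip(self.grid_shape, self._padded)
        )

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Evaluate k-space samples of ``image`` at the planned coordinates."""
        if image.shape != self.grid_shape:
            raise ValueError(
                f"image shape {image.shape} != grid {self.grid_shape}")
        x = np.asarray(image, dtype=np.complex128)
        x = x / (self._apod[0][:, None, None]
                 * self._apod[1][None, :, None]
                 * self._apod[2][None, None, :])
        xpad = np.zeros(self._padded, dtype=np.complex128)
        xpad[self._pad_slices()] = x
        spec = np.fft.fftn(np.fft.ifftshift(xpad))
        return self._interp @ spec.ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact conjugate transpose of :meth:`forward`."""
        samples = np.asarray(samples, dtype=np.complex128)
        if samples.shape != (self.n_samples,):
            raise ValueError("samples length mismatch with planned coords")
        grid = (self._interp_h @ samples).reshape(self._padded)
        xpad = np.fft.fftshift(np.fft.ifftn(grid)) * np.prod(self._padded)
        x = xpad[self._pad_slices()]
        return x / (self._apod[0][:, None, None]
                    * self._apod[1][None, :, None]
                    * self._apod[2][None, None, :])

    def sample_density(self) -> np.ndarray:
        """Per-sample local sampling density, (G G^H) 1.

        Used by the single-channel k-space preconditioner: the reciprocal of
        this density is the classical first Pipe-Menon density-compensation
        iterate.
        """
        ones = np.ones(self.n_samples)
        return self._interp.real @ (self._interp_h.real @ ones)


def ball_limit(volume: np.ndarray, radius: float | None = None) -> np.ndarray:
    """Band-limit a volume to the centered spectral ball of given radius.

    Center-out trajectories sample a ball, not the full spectral cube, so
    this is the "matched resolution" reference when comparing a
    reconstruction with a ground-truth volume.
    """
    shape = volume.shape
    if radius is None:
        radius = min(shape) / 2
    axes = [np.arange(g) - g // 2 for g in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    mask = gx**2 + gy**2 + gz**2 <= radius**2
    spec = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(volume)))
    out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec * mask)))
    return out.real if np.isrealobj(volume) else out


def ndft_direct(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force non-uniform DFT oracle (small problems only)."""
    shape = image.shape
    grids = [np.arange(n) - n // 2 for n in shape]
    nx, ny, nz = np.meshgrid(*grids, indexing="ij")
    out = np.empty(coords.shape[0], dtype=np.complex128)
    flat = image.ravel()
    pos = np.stack([nx.ravel() / shape[0], ny.ravel() / shape[1],
                    nz.ravel() / shape[2]], axis=1)
    for j, k in enumerate(coords):
        out[j] = np.sum(flat * np.exp(-2j * np.pi * (pos @ k)))
    return out
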