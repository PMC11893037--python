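"""FLORET-style 3D center-out k-space trajectory generation.

The sampling scheme plays Fermat-spiral interleaves outward from the k-space
origin, modulated onto cones whose axes are grouped into up to three
mutually orthogonal "hubs".  Each excitation (readout) is one spiral arm on
one cone; interleaves are rotated azimuthally between excitations so that
any contiguous acquisition window covers azimuth quasi-uniformly -- the
temporal incoherence that retrospective respiratory binning relies on.

Only the sampling *geometry* is modeled.  Gradient slew/amplitude limits,
readout timing and T2* decay are out of scope: the coordinates produced
here feed a simulated acquisition, not a scanner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE = 2.0 * np.pi * (1.0 - 1.0 / ((1.0 + np.sqrt(5.0)) / 2.0))
#: golden-ratio fraction used for low-discrepancy cone-latitude sequencing
GOLDEN_FRAC = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class TrajectoryConfig:
    """Acquisition-geometry parameters.

    ``nyquist_pct`` scales the number of spiral turns per readout so that the
    achieved k-space cell coverage (see :func:`nyquist_coverage`) grows with
    it; 1.0 targets full Nyquist for the configured FOV/resolution.
    """

    fov_mm: float = 320.0
    res_mm: float = 1.6
    n_hubs: int = 3
    samples_per_readout: int = 64
    n_excitations: int = 20000
    nyquist_pct: float = 1.0
    hub_half_angle_deg: float = 45.0
    interleave_order: str = "golden"

    def __post_init__(self):
        if self.fov_mm <= 0 or self.res_mm <= 0:
            raise ValueError("fov_mm and res_mm must be positive")
        if self.n_hubs not in (1, 2, 3):
            raise ValueError("n_hubs must be 1, 2 or 3")
        if not (0.0 < self.nyquist_pct <= 2.0):
            raise ValueError("nyquist_pct must lie in (0, 2]")
        if self.samples_per_readout < 2:
            raise ValueError("samples_per_readout must be >= 2")
        if self.interleave_order not in ("golden", "sequential", "bit-reversed"):
            raise ValueError(f"unknown interleave_order {self.interleave_order!r}")

    @property
    def kmax(self) -> float:
        """Radial k-space extent in cycles/mm."""
        return 1.0 / (2.0 * self.res_mm)

    @property
    def matrix_size(self) -> int:
        return int(round(self.fov_mm / self.res_mm))


@dataclass
class TrajectorySet:
    """Per-excitation 3D k-space coordinates, cycles/mm."""

    coords: np.ndarray              # (n_excitations, samples_per_readout, 3)
    excitation_order: np.ndarray    # acquisition-time permutation (identity here)
    kmax: float
    fov_mm: float
    res_mm: float
    hub_axes: np.ndarray = field(default=None)  # (n_hubs, 3) orthonormal

    @property
    def n_excitations(self) -> int:
        return self.coords.shape[0]

    @property
    def samples_per_readout(self) -> int:
        return self.coords.shape[1]

    def flat_coords(self, excitations: np.ndarray | None = None) -> np.ndarray:
        """(M, 3) coordinate list, optionally restricted to some excitations."""
        c = self.coords if excitations is None else self.coords[excitations]
        return c.reshape(-1, 3)


_HUB_AXES = np.eye(3)[[2, 0, 1]]  # z, x, y -- pairwise orthogonal


def _van_der_corput(n: int, base: int = 2) -> np.ndarray:
    """Low-discrepancy sequence in [0, 1), independent of the golden angle."""
    out = np.zeros(n)
    denom = 1
    idx = np.arange(n)
    while np.any(idx > 0):
        denom *= base
        out += (idx % base) / denom
        idx //= base
        if denom > 1 << 40:
            break
    return out


def _bit_reverse(n: int) -> np.ndarray:
    bits = max(1, int(np.ceil(np.log2(max(n, 2)))))
    idx = np.arange(n)
    rev = np.zeros(n, dtype=np.int64)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    order = np.argsort(np.argsort(rev, kind="stable"), kind="stable")
    return order


def generate_floret(config: TrajectoryConfig) -> TrajectorySet:
    """Generate the full interleave set for one simulated acquisition.

    Excitations are dealt round-robin across hubs in acquisition order (a
    warning is emitted when they do not divide evenly).  Within a hub, each
    interleave gets an azimuthal rotation from the configured ordering and a
    cone latitude from a golden-ratio low-discrepancy sequence spanning
    ``[-hub_half_angle, +hub_half_angle]`` (uniform in sin latitude, which is
    uniform in solid angle).
    """
    J = config.samples_per_readout
    I = config.n_excitations
    kmax = config.kmax
    if I % config.n_hubs != 0:
        warnings.warn(
            f"{I} excitations not divisible by {config.n_hubs} hubs; "
            "remainder allocated round-robin", stacklevel=2)

    hub_of = np.arange(I) % config.n_hubs
    # index of the excitation within its own hub
    within = np.arange(I) // config.n_hubs

    # Spiral turns per readout: chosen so the sample spacing along the arc
    # stays near one Nyquist cell (arc length ~ pi * turns * kmax maps to J
    # samples), scaled by the prescribed Nyquist percentage.
    turns = max(0.5, config.nyquist_pct * 2.0 * J / (np.pi * config.matrix_size))

    # Fermat spiral r = kmax*sqrt(theta/theta_max), sampled uniformly in arc
    # length so the readout spends its samples evenly along the arm
    theta_max = 2.0 * np.pi * turns
    theta_fine = theta_max * np.linspace(0.0, 1.0, 16 * J) ** 2
    r_fine = kmax * np.sqrt(theta_fine / theta_max)
    d_arc = np.hypot(np.diff(r_fine), 0.5 * (r_fine[1:] + r_fine[:-1])
                     * np.diff(theta_fine))
    arc = np.concatenate([[0.0], np.cumsum(d_arc)])
    targets = np.linspace(0.0, arc[-1], J)
    theta_spiral = np.interp(targets, arc, theta_fine)
    radius = kmax * np.sqrt(theta_spiral / theta_max)

    counts = np.bincount(hub_of, minlength=config.n_hubs)
    azim0 = np.empty(I)
    for h in range(config.n_hubs):
        n_h = counts[h]
        w = within[hub_of == h]
        if config.interleave_order == "golden":
            azim0[hub_of == h] = (w * GOLDEN_ANGLE) % (2 * np.pi)
        elif config.interleave_order == "sequential":
            azim0[hub_of == h] = 2 * np.pi * w / max(n_h, 1)
        else:  # bit-reversed
            perm = _bit_reverse(n_h)
            azim0[hub_of == h] = 2 * np.pi * perm[w] / max(n_h, 1)

    # Cone latitude per interleave: low-discrepancy in sin(latitude),
    # from a van der Corput sequence (independent of the golden-angle
    # azimuth so the (azimuth, latitude) pairs tile the torus)
    sin_half = np.sin(np.deg2rad(config.hub_half_angle_deg))
    frac = _van_der_corput(int(within.max()) + 1)[within]
    sin_lat = (2.0 * frac - 1.0) * sin_half
    cos_lat = np.sqrt(1.0 - sin_lat**2)

    theta = azim0[:, None] + theta_spiral[None, :]         # (I, J)
    in_plane = radius[None, :] * cos_lat[:, None]
    local = np.stack(
        [in_plane * np.cos(theta),
         in_plane * np.sin(theta),
         radius[None, :] * sin_lat[:, None] * np.ones_like(theta)],
        axis=-1,
    )

    # rotate each hub's local z-axis onto its hub axis
    coords = np.empty((I, J, 3))
    basis = {
        0: np.eye(3)[[0, 1, 2]],   # z-hub: identity
        1: np.eye(3)[[1, 2, 0]],   # x-hub: local (x,y,z) -> (y,z,x)
        2: np.eye(3)[[2, 0, 1]],   # y-hub: local (x,y,z) -> (z,x,y)
    }
    for h in range(config.n_hubs):
        sel = hub_of == h
        coords[sel] = local[sel] @ basis[h]

    return TrajectorySet(
        coords=coords,
        excitation_order=np.arange(I),
        kmax=kmax,
        fov_mm=config.fov_mm,
        res_mm=config.res_mm,
        hub_axes=_HUB_AXES[: config.n_hubs].copy(),
    )


def nyquist_coverage(traj: TrajectorySet, config: TrajectoryConfig) -> float:
    """Fraction of Nyquist k-space cells visited by at least one sample.

    Cells have width 1/FOV; only cells whose centers lie inside the kmax
    ball count toward the denominator.
    """
    if traj.n_excitations == 0 or traj.coords.size == 0:
        raise ValueError("empty trajectory")
    dk = 1.0 / config.fov_mm
    kmax = config.kmax
    half = int(np.ceil(kmax / dk))
    pts = traj.flat_coords()
    cells = np.floor(pts / dk + 0.5).astype(np.int64)
    np.clip(cells, -half, half, out=cells)
    side = 2 * half + 1
    flat = ((cells[:, 0] + half) * side + (cells[:, 1] + half)) * side + (
        cells[:, 2] + half)
    visited = np.zeros(side**3, dtype=bool)
    visited[flat] = True

    ax = (np.arange(side) - half) * dk
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = (gx**2 + gy**2 + gz**2) <= kmax**2
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("degenerate grid: no cells inside kmax ball")
    return float(np.count_nonzero(visited.reshape(inside.shape) & inside)
                 / n_inside)
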