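"""Dynamic digital breathing-thorax phantom with known regional ventilation.

The phantom is the test bed for the whole pipeline: it provides raw
multicoil non-Cartesian k-space with a matching respiratory bellows trace,
plus voxelwise ground truth (fractional-ventilation amplitude, defect
masks, filling-phase lag) against which the PREFUL maps are scored.

Model
-----
A static thorax template (body wall, mediastinum, two lung ellipsoids,
optional trachea and vessels) is defined in material (end-expiration)
coordinates.  Breathing is a one-dimensional cranio-caudal stretch of each
lung column: the pointwise expansion rate equals the voxel's prescribed
fractional-ventilation amplitude FV, so the displacement tapers to zero at
the apex, the diaphragm translates caudally, and parenchymal density obeys

    rho(a) = rho_EE / (1 + a * FV),

where a in [0, 1] is the respiratory state (0 = end-expiration).  Because
the geometric Jacobian of the column stretch is exactly (1 + a*FV), lung
mass is conserved by construction; the numerical check is exposed as
:meth:`PhantomModel.lung_mass`.

Ventilation defects are spheres where FV is scaled down
(``amplitude_scale``) and/or where filling lags the breathing cycle
(``phase_lag``, in cycle fractions) -- the synthetic analogue of the
irregular filling that dynamic ventilation parameters are designed to
detect.  Cardiac motion, airway anatomy and T2*/off-resonance effects are
not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .nufft import NufftOperator
from .trajectory import TrajectorySet


@dataclass(frozen=True)
class DefectSpec:
    """A spherical ventilation defect.

    amplitude_scale multiplies the local FV amplitude (1 = normal filling,
    0 = no filling); phase_lag delays the filling waveform by a fraction of
    the breathing cycle and is what drives VTTP / flow-volume-loop
    abnormality without necessarily reducing ventilation amplitude.
    """

    center_voxel: tuple[int, int, int]
    radius_mm: float
    amplitude_scale: float = 0.0
    phase_lag: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.amplitude_scale <= 1.0):
            raise ValueError("amplitude_scale must lie in [0, 1]")
        if not (0.0 <= self.phase_lag < 0.5):
            raise ValueError("phase_lag must lie in [0, 0.5)")


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 48
    fov_mm: float = 320.0
    breathing_period_s: float = 4.0
    tidal_amplitude: float = 0.3
    lung_density_ee: float = 0.25
    defects: tuple[DefectSpec, ...] = ()
    n_coils: int = 4
    noise_sd: float = 0.0
    seed: int = 0
    with_trachea: bool = False
    with_vessels: bool = False

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.breathing_period_s <= 0:
            raise ValueError("breathing_period_s must be positive")
        if not (0.0 <= self.tidal_amplitude < 0.5):
            raise ValueError("tidal_amplitude must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.grid_size


@dataclass
class BellowsTrace:
    """Per-excitation respiratory amplitude, one reading per TR."""

    values: np.ndarray
    dt_s: float
    outlier_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class KSpaceData:
    """Simulated multicoil non-Cartesian acquisition."""

    samples: np.ndarray          # (coils, excitations, samples_per_readout)
    traj: TrajectorySet
    bellows: BellowsTrace
    noise_sd: float = 0.0

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]


def breathing_wave(phase: np.ndarray | float) -> np.ndarray | float:
    """Canonical respiratory state vs cycle fraction: sin^2(pi*phase).

    0 at end-expiration (phase 0), 1 at end-inspiration (phase 0.5).
    """
    return np.sin(np.pi * np.asarray(phase)) ** 2


class PhantomModel:
    """Callable breathing-thorax model; see module docstring."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        n = spec.grid_size
        self.shape = (n, n, n)
        c = (np.arange(n) - (n - 1) / 2) / (n / 2)   # [-1, 1) per axis
        x, y, z = np.meshgrid(c, c, c, indexing="ij")

        def ellipsoid(cx, cy, cz, rx, ry, rz):
            return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
                    + ((z - cz) / rz) ** 2) <= 1.0

        self.body = ellipsoid(0, 0, 0, 0.85, 0.65, 0.95)
        lung_l = ellipsoid(-0.40, 0.0, 0.15, 0.30, 0.42, 0.52)
        lung_r = ellipsoid(+0.40, 0.0, 0.15, 0.30, 0.42, 0.52)
        self.lung = (lung_l | lung_r) & self.body
        self.trachea = np.zeros(self.shape, dtype=bool)
        if spec.with_trachea:
            self.trachea = ((x**2 + (y + 0.05) ** 2) <= 0.07**2) & (
                z > 0.25) & self.body & ~self.lung
        self.vessels = np.zeros(self.shape, dtype=bool)
        if spec.with_vessels:
            for cx in (-0.40, 0.40):
                self.vessels |= (((x - cx) ** 2 + y**2) <= 0.05**2) & self.lung

        # material density template at end-expiration
        rho = np.zeros(self.shape)
        rho[self.body] = 0.85
        rho[z < -0.35] = np.where(self.body[z < -0.35], 0.95, 0.0)  # abdomen
        rho[self.lung] = spec.lung_density_ee
        rho[self.vessels] = 1.1
        rho[self.trachea] = 0.02
        self.template = rho

        # prescribed fractional-ventilation amplitude (material frame);
        # uniform base so the diaphragm excursion over the tallest column
        # equals tidal_amplitude * lung height, as configured
        self.fv = np.where(self.lung & ~self.vessels,
                           spec.tidal_amplitude, 0.0)
        self.lag = np.zeros(self.shape)
        self.amp_scale = np.ones(self.shape)
        vox = spec.voxel_mm
        ix, iy, iz = np.meshgrid(np.arange(n), np.arange(n),
                                 np.arange(n), indexing="ij")
        for d in spec.defects:
            cx_, cy_, cz_ = d.center_voxel
            r_vox = d.radius_mm / vox
            rr = np.sqrt((ix - cx_) ** 2 + (iy - cy_) ** 2
                         + (iz - cz_) ** 2)
            sphere = rr <= r_vox
            if not self.lung[cx_, cy_, cz_] or not np.all(
                    self.lung[sphere] | self.vessels[sphere]):
                raise ValueError(
                    f"defect at {d.center_voxel} extends outside the lung")
            # graded border (~1.5 voxel transition): real hypoventilated
            # regions do not end at a voxel-sharp edge
            w = np.clip((r_vox - rr) / 1.5, 0.0, 1.0)
            scale = 1.0 + (d.amplitude_scale - 1.0) * w
            self.fv *= scale
            self.amp_scale = np.minimum(self.amp_scale, scale)
            self.lag[sphere & self.lung] = d.phase_lag

        self._footprint = np.nonzero(self.lung.any(axis=2))

    # -- breathing kinematics ---------------------------------------------
    def _effective_state(self, a: float, cycle_phase: float | None):
        """Per-voxel respiratory state, accounting for filling lag."""
        a_eff = np.full(self.shape, float(a))
        if cycle_phase is not None and np.any(self.lag > 0):
            lagged = self.lag > 0
            a_eff[lagged] = breathing_wave(cycle_phase - self.lag[lagged])
        return a_eff

    def _warp_columns(self, values: np.ndarray, a: float,
                      cycle_phase: float | None, divide: bool,
                      nearest: bool = False, supersample: int = 1):
        """Render ``values`` at respiratory state ``a`` (column-wise warp)."""
        n = self.spec.grid_size
        ss = int(supersample)
        a_eff = self._effective_state(a, cycle_phase)
        fv_eff = a_eff * self.fv
        # fine material grid (piecewise-constant voxels sampled at ss points
        # each) so interface blending shrinks with the supersampling factor
        zf = (np.arange(n * ss) + 0.5) / ss - 0.5
        vidx = np.clip(np.round(zf).astype(np.int64), 0, n - 1)
        out = values.astype(np.float64)[:, :, vidx].copy()
        for i, j in zip(*self._footprint):
            col_fv = fv_eff[i, j, vidx]
            # displacement: integral of the expansion rate from the apex
            # (high z) down, so delta(apex) = 0 and the diaphragm shifts
            # caudally; Jacobian of z -> z + delta is exactly 1 + a*FV
            delta = -(np.cumsum(col_fv[::-1])[::-1] - col_fv) / ss
            p = zf + delta
            w = out[i, j, :] / (1.0 + col_fv) if divide else out[i, j, :]
            if nearest:
                idx = np.clip(np.searchsorted(p, zf), 0, n * ss - 1)
                lo = np.clip(idx - 1, 0, n * ss - 1)
                pick = np.where(np.abs(p[lo] - zf) <= np.abs(p[idx] - zf),
                                lo, idx)
                out[i, j, :] = w[pick]
            else:
                out[i, j, :] = np.interp(zf, p, w)
        return out

    def volume_at(self, a: float, cycle_phase: float | None = None
                  ) -> np.ndarray:
        """Real density volume at respiratory state ``a`` in [0, 1].

        ``cycle_phase`` (cycle fraction in [0, 1), 0 = end-expiration) is
        only needed when lagged defects are present; without it lagged
        regions fill synchronously.
        """
        if not (0.0 <= a <= 1.0):
            raise ValueError("respiratory state a must lie in [0, 1]")
        return self._warp_columns(self.template, a, cycle_phase, divide=True)

    __call__ = volume_at

    def lung_mask(self, a: float = 0.0,
                  cycle_phase: float | None = None) -> np.ndarray:
        ind = self._warp_columns(self.lung.astype(np.float64), a,
                                 cycle_phase, divide=False)
        return ind >= 0.5

    def parenchyma_mask(self, a: float = 0.0) -> np.ndarray:
        ind = self._warp_columns((self.lung & ~self.vessels).astype(float),
                                 a, None, divide=False)
        return ind >= 0.5

    def lung_mass(self, a: float, cycle_phase: float | None = None,
                  supersample: int = 4) -> float:
        """Numeric rho*volume integral over the deformed lung compartment."""
        dens = self._warp_columns(self.template, a, cycle_phase,
                                  divide=True, supersample=supersample)
        ind = self._warp_columns(self.lung.astype(float), a, cycle_phase,
                                 divide=False, supersample=supersample)
        return float(np.sum(dens * (ind >= 0.5)) / supersample)

    def diaphragm_excursion_mm(self, a: float) -> float:
        """Caudal displacement of the deepest lung column at state ``a``."""
        col_heights = self.fv.sum(axis=2)  # per-column integral of FV
        return float(a * col_heights.max() * self.spec.voxel_mm)

    def ground_truth(self, a: float = 1.0) -> dict[str, np.ndarray]:
        """Voxelwise truth maps rendered at state ``a`` (default EI frame).

        Keys: ``fv_amplitude`` (FV at full inflation), ``amp_scale``
        (defect amplitude modulation), ``phase_lag`` (cycle fractions),
        ``defect_mask`` (amplitude-reduced voxels), ``lag_mask``,
        ``vttp_pct`` (true ventilation time-to-peak, % of cycle),
        ``lung_mask``, ``parenchyma_mask``.
        """
        warp = lambda f, nn: self._warp_columns(f, a, None, divide=False,
                                                nearest=nn)
        fv = warp(self.fv, False)
        amp = warp(self.amp_scale, True)
        lag = warp(self.lag, True)
        lung = warp(self.lung.astype(float), True) >= 0.5
        par = warp((self.lung & ~self.vessels).astype(float), True) >= 0.5
        # true defect mask by the standard VDP rule applied to the true
        # ventilation map: below 40% of its 90th percentile
        thr = 0.4 * np.percentile(fv[par], 90) if par.any() else 0.0
        return {
            "fv_amplitude": fv,
            "amp_scale": amp,
            "phase_lag": lag,
            "defect_mask": (fv < thr) & par,
            "lag_mask": (lag > 0.0) & par,
            "vttp_pct": 100.0 * (0.5 + lag),
            "lung_mask": lung,
            "parenchyma_mask": par,
        }


def build_phantom(spec: PhantomSpec) -> PhantomModel:
    """Validate the spec and construct the breathing-thorax model."""
    return PhantomModel(spec)


def amplitude_defect_layout(model: PhantomModel, fraction: float,
                            amplitude_scale: float = 0.15,
                            seed: int = 7, phase_lag: float = 0.0,
                            radius_mm: float | None = None,
                            avoid: np.ndarray | None = None
                            ) -> tuple[DefectSpec, ...]:
    """Place defect spheres covering ~``fraction`` of the parenchyma.

    Small spheres are scattered (seeded) at interior lung positions found
    via the distance transform, so each sphere is guaranteed to lie fully
    inside the lung; spheres are added until the covered voxel fraction
    reaches the request (patchy, clinically plausible defects).  ``avoid``
    excludes previously claimed regions, letting amplitude and phase-lag
    defects coexist without overlap.
    """
    from scipy.ndimage import distance_transform_edt
    rng = np.random.default_rng(seed)
    lung = model.lung & ~model.vessels
    vox = model.spec.voxel_mm
    dist = distance_transform_edt(lung | model.vessels)
    avoid_dist = None
    if avoid is not None:
        avoid_dist = distance_transform_edt(~avoid)
    target = fraction * lung.sum()
    ix, iy, iz = np.meshgrid(*[np.arange(s) for s in model.shape],
                             indexing="ij")
    mask = np.zeros(model.shape, dtype=bool)
    specs: list[DefectSpec] = []
    # grow connected blobs of overlapping spheres (lobar-like defects):
    # clustering keeps the partial-volume boundary small relative to the
    # defect core, unlike scattering many isolated small spheres
    from scipy.ndimage import binary_dilation
    for _ in range(400):
        if mask.sum() >= target:
            break
        room = dist - 0.5
        if avoid_dist is not None:
            room = np.minimum(room, avoid_dist - 0.5)
        if radius_mm is not None:
            room = np.minimum(room, radius_mm / vox)
        # cap by the remaining volume so the target is not overshot
        r_need = ((target - mask.sum()) * 3.0 / (4.0 * np.pi)) ** (1 / 3)
        room = np.minimum(room, max(1.5 * r_need, 2.0))
        if mask.any():
            room[mask] = 0.0               # center outside the cluster...
            near = binary_dilation(mask, iterations=3)
            room[~near] = 0.0              # ...but touching it
        best = float(room.max())
        if best < 1.5:
            if mask.any():   # no adjacent room left; allow a new cluster
                room = dist - 0.5
                if avoid_dist is not None:
                    room = np.minimum(room, avoid_dist - 0.5)
                room[binary_dilation(mask, iterations=2)] = 0.0
                best = float(room.max())
            if best < 1.5:
                break
        cand = np.array(np.nonzero(room >= 0.9 * best)).T
        c = cand[rng.integers(len(cand))]
        r_vox = float(room[tuple(c)])
        sphere = ((ix - c[0]) ** 2 + (iy - c[1]) ** 2
                  + (iz - c[2]) ** 2) <= r_vox**2
        mask |= sphere
        specs.append(DefectSpec(center_voxel=tuple(int(v) for v in c),
                                radius_mm=r_vox * vox,
                                amplitude_scale=amplitude_scale,
                                phase_lag=phase_lag))
    if not specs:
        raise ValueError("no interior lung room for the requested defects")
    return tuple(specs)


def defect_region_mask(model: PhantomModel,
                       specs: tuple[DefectSpec, ...]) -> np.ndarray:
    """Material-frame union of the given defect spheres."""
    ix, iy, iz = np.meshgrid(*[np.arange(s) for s in model.shape],
                             indexing="ij")
    mask = np.zeros(model.shape, dtype=bool)
    vox = model.spec.voxel_mm
    for d in specs:
        cx, cy, cz = d.center_voxel
        r = d.radius_mm / vox
        mask |= ((ix - cx) ** 2 + (iy - cy) ** 2 + (iz - cz) ** 2) <= r**2
    return mask


# ---------------------------------------------------------------------------
# bellows simulation and state mapping
# ---------------------------------------------------------------------------

def simulate_bellows(spec: PhantomSpec, n_excitations: int, tr_s: float,
                     drift: float = 0.0, outlier_rate: float = 0.0,
                     amp_jitter: float = 0.0, period_jitter: float = 0.0,
                     noise_sd: float = 0.0) -> BellowsTrace:
    """Quasi-sinusoidal respiratory bellows trace, one sample per TR.

    ``drift`` is in amplitude units per minute; ``amp_jitter`` and
    ``period_jitter`` are fractional cycle-to-cycle standard deviations;
    ``outlier_rate`` injects sparse high-amplitude spikes (deep breaths /
    bulk motion), whose indices are logged on the returned trace.
    """
    if n_excitations < 1:
        raise ValueError("n_excitations must be >= 1")
    rng = np.random.default_rng(spec.seed + 104729)
    t = np.arange(n_excitations) * tr_s
    # cycle-by-cycle instantaneous frequency
    n_cycles = int(np.ceil(t[-1] / spec.breathing_period_s)) + 2
    periods = spec.breathing_period_s * (
        1.0 + period_jitter * rng.standard_normal(n_cycles)).clip(0.3)
    amps = (1.0 + amp_jitter * rng.standard_normal(n_cycles)).clip(0.1)
    cycle_edges = np.concatenate([[0.0], np.cumsum(periods)])
    cyc = np.clip(np.searchsorted(cycle_edges, t, side="right") - 1,
                  0, n_cycles - 1)
    frac = (t - cycle_edges[cyc]) / periods[cyc]
    values = -0.5 * amps[cyc] * np.cos(2 * np.pi * frac)
    values = values + drift * (t / 60.0)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(n_excitations)
    outliers = np.empty(0, dtype=np.int64)
    if outlier_rate > 0:
        n_out = rng.binomial(n_excitations, outlier_rate)
        outliers = np.sort(rng.choice(n_excitations, size=n_out,
                                      replace=False))
        spikes = rng.uniform(3.0, 6.0, size=n_out) * rng.choice(
            [-1.0, 1.0], size=n_out)
        values[outliers] += spikes * max(values.std(), 1e-9)
    return BellowsTrace(values=values, dt_s=tr_s, outlier_indices=outliers)


def bellows_to_state(trace: BellowsTrace, breathing_period_s: float
                     ) -> np.ndarray:
    """Map a bellows trace to respiratory state a in [0, 1].

    Sliding min-max normalization over a three-cycle window, which is
    robust to slow baseline drift; 0 = end-expiration (trough).
    """
    window = max(3, int(round(3.0 * breathing_period_s / trace.dt_s)) | 1)
    window = min(window, 2 * len(trace) - 1)
    lo = minimum_filter1d(trace.values, size=window, mode="nearest")
    hi = maximum_filter1d(trace.values, size=window, mode="nearest")
    rng_ = hi - lo
    flat = rng_ <= 1e-12 * max(np.abs(trace.values).max(), 1.0)
    a = np.zeros_like(trace.values)
    np.divide(trace.values - lo, rng_, out=a, where=~flat)
    return np.clip(a, 0.0, 1.0)


# ---------------------------------------------------------------------------
# coil maps and forward simulation
# ---------------------------------------------------------------------------

def make_coil_maps(n_coils: int, grid_size: int) -> np.ndarray:
    """Smooth complex coil sensitivity maps, (coils, n, n, n).

    Broad Gaussian lobes centered around the body perimeter with gentle
    linear phase ramps; a single coil yields a uniform map (the forward
    model then reduces to a plain NUFFT).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    n = grid_size
    if n_coils == 1:
        return np.ones((1, n, n, n), dtype=np.complex128)
    c = (np.arange(n) - (n - 1) / 2) / (n / 2)
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    maps = np.empty((n_coils, n, n, n), dtype=np.complex128)
    # broad, gently varying lobes, as produced by virtual-coil
    # compression of a many-channel thorax array
    angles = 2 * np.pi * np.arange(n_coils) / n_coils
    for k, th in enumerate(angles):
        cx, cy = 0.8 * np.cos(th), 0.7 * np.sin(th)
        cz = 0.2 * np.sin(2.0 * th)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * 1.4**2)
                       + (z - cz) ** 2 / (2 * 1.8**2)))
        phase = 0.2 * (np.cos(th) * x + np.sin(th) * y) + 0.08 * z
        maps[k] = (0.25 + mag) * np.exp(1j * np.pi * phase)
    return maps


def cycle_phase_from_trace(trace: BellowsTrace) -> np.ndarray:
    """Cycle fraction in [0, 1) per excitation, 0 at end-expiration."""
    from .binning import instantaneous_phase
    theta = instantaneous_phase(trace)
    return ((theta + np.pi) / (2 * np.pi)) % 1.0


def simulate_acquisition(phantom: PhantomModel, traj: TrajectorySet,
                         bellows: BellowsTrace, sens: np.ndarray,
                         noise_sd: float = 0.0, n_states: int = 48,
                         seed: int | None = None) -> KSpaceData:
    """NUFFT-synthesize per-excitation multicoil k-space of the phantom.

    Each excitation sees the phantom at its instantaneous respiratory state
    (bellows mapped through :func:`bellows_to_state`) and cycle phase.  For
    tractability the cycle is quantized into ``n_states`` phase groups; one
    volume render and one NUFFT plan serve all excitations in a group.
    """
    if len(bellows) != traj.n_excitations:
        raise ValueError(
            f"bellows length {len(bellows)} != excitations "
            f"{traj.n_excitations}")
    spec = phantom.spec
    n = spec.grid_size
    if sens.shape[1:] != phantom.shape:
        raise ValueError("sensitivity maps grid mismatch")
    kgrid = traj.coords * spec.fov_mm   # cycles per FOV
    if np.abs(kgrid).max() > n / 2 + 1e-6:
        raise ValueError(
            "trajectory extends beyond the phantom grid's Nyquist bound; "
            "match res_mm to fov_mm/grid_size")

    a_all = bellows_to_state(bellows, spec.breathing_period_s)
    if np.ptp(bellows.values) <= 1e-12:      # static phantom
        groups = {0: np.arange(traj.n_excitations)}
        states = {0: (0.0, None)}
    else:
        phi_all = cycle_phase_from_trace(bellows)
        gid = np.floor(phi_all * n_states).astype(int) % n_states
        groups, states = {}, {}
        for g in np.unique(gid):
            sel = np.nonzero(gid == g)[0]
            groups[g] = sel
            states[g] = (float(np.median(a_all[sel])),
                         float((g + 0.5) / n_states))

    C = sens.shape[0]
    J = traj.samples_per_readout
    out = np.zeros((C, traj.n_excitations, J), dtype=np.complex128)
    for g, sel in groups.items():
        a, phi = states[g]
        vol = phantom.volume_at(a, cycle_phase=phi)
        coords = kgrid[sel].reshape(-1, 3)
        op = NufftOperator(coords, phantom.shape)
        for c in range(C):
            out[c, sel, :] = op.forward(vol * sens[c]).reshape(len(sel), J)
    if noise_sd > 0:
        rng = np.random.default_rng(
            spec.seed + 7919 if seed is None else seed)
        out += noise_sd * (rng.standard_normal(out.shape)
                           + 1j * rng.standard_normal(out.shape))
    return KSpaceData(samples=out, traj=traj, bellows=bellows,
                      noise_sd=noise_sd)
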