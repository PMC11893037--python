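"""Respiratory self-gating: sort excitations into equal-count phase bins.

The bellows trace is smoothed with a moving average, readings beyond +/- k
standard deviations of the mean are excluded, and each remaining excitation
is tagged with the instantaneous phase of the analytic (Hilbert) signal.
Excitations are then allocated to B bins centered on equispaced phase
targets, every bin receiving exactly n = total_budget / B members.  Dynamic
view sharing lets a bin borrow members whose nearest target is a
neighboring bin, up to a bounded fraction of its size, which is how a fixed
per-bin count can exceed the usable excitation count / B.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .phantom import BellowsTrace, KSpaceData
from .trajectory import TrajectorySet

#: per-bin counts printed for B in {8,...,40} at the full 240k budget
FULL_BUDGET = 240_000


@dataclass(frozen=True)
class BinningConfig:
    n_bins: int = 24
    smoothing_window: int | None = None   # excitations; None -> T_breath/4
    exclusion_k: float = 2.0
    total_budget: int | None = FULL_BUDGET  # None -> scaled to usable count
    max_share_fraction: float = 0.5

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.smoothing_window is not None and self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.exclusion_k <= 0:
            raise ValueError("exclusion_k must be positive")
        if not (0.0 <= self.max_share_fraction <= 0.5):
            raise ValueError("max_share_fraction must lie in [0, 0.5]")


@dataclass
class RespiratoryBinSet:
    bin_indices: list[np.ndarray]       # per-bin excitation indices
    target_phases: np.ndarray           # per-bin phase target in (-pi, pi]
    phase_edges: list[tuple[float, float]]  # circular phase extent per bin
    excluded: np.ndarray                # excluded excitation indices
    share_matrix: np.ndarray            # (B, B) shared-member counts
    mean_amplitude: np.ndarray | None = None  # per-bin mean bellows reading

    @property
    def n_bins(self) -> int:
        return len(self.bin_indices)

    @property
    def per_bin_count(self) -> int:
        return len(self.bin_indices[0])

    def shared_count(self, b: int) -> int:
        """Members of bin b whose primary (nearest-phase) bin is another."""
        return int(self.share_matrix[b].sum() - self.share_matrix[b, b])

    def to_json(self, path) -> None:
        payload = {
            "target_phases": self.target_phases.tolist(),
            "excluded": self.excluded.tolist(),
            "bins": [idx.tolist() for idx in self.bin_indices],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class KSpaceBins:
    """Per-bin k-space sample arrays with matching trajectory subsets."""

    samples: list[np.ndarray]     # each (coils, n_bin_excitations, J)
    coords: list[np.ndarray]      # each (n_bin_excitations, J, 3) cycles/mm
    bins: RespiratoryBinSet
    fov_mm: float
    res_mm: float

    @property
    def n_bins(self) -> int:
        return len(self.samples)

    @property
    def n_coils(self) -> int:
        return self.samples[0].shape[0]


def preprocess_bellows(trace: BellowsTrace, window: int) -> BellowsTrace:
    """Centered moving average; the window shrinks at the boundaries."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= len(trace):
        raise ValueError("smoothing window must be shorter than the trace")
    if window == 1:
        return BellowsTrace(trace.values.copy(), trace.dt_s,
                            trace.outlier_indices)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(trace.values)])
    n = len(trace)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return BellowsTrace(smoothed, trace.dt_s, trace.outlier_indices)


def exclude_outliers(trace: BellowsTrace, k: float = 2.0) -> np.ndarray:
    """Indices with |value - mean| > k * SD (over the given trace)."""
    if len(trace) < 2:
        raise ValueError("trace must have at least 2 samples")
    v = trace.values
    sd = v.std()
    if sd == 0:
        warnings.warn("zero-variance bellows trace; nothing excluded",
                      stacklevel=2)
        return np.empty(0, dtype=np.int64)
    return np.nonzero(np.abs(v - v.mean()) > k * sd)[0]


def instantaneous_phase(trace: BellowsTrace) -> np.ndarray:
    """Analytic-signal phase in (-pi, pi] of the mean-detrended trace."""
    if len(trace) < 8:
        raise ValueError("trace too short for a meaningful Hilbert phase")
    v = trace.values - trace.values.mean()
    if np.ptp(v) == 0:
        raise ValueError("instantaneous phase undefined for constant trace")
    return np.angle(hilbert(v))


def _circdist(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def scaled_budget(n_usable: int, n_bins: int) -> int:
    """Desk-scale total budget: ~1.7x the usable count, rounded to B.

    Mirrors the full-scale ratio of the 240k budget to a typical usable
    count (~140k), which keeps the borrowed fraction safely below the 50%
    per-bin sharing cap.
    """
    return max(n_bins, int(np.floor(1.7 * n_usable / n_bins)) * n_bins)


def allocate_bins(phases: np.ndarray, excluded: np.ndarray,
                  config: BinningConfig,
                  amplitudes: np.ndarray | None = None) -> RespiratoryBinSet:
    """Equal-count nearest-phase allocation with bounded view sharing.

    Every usable excitation is first claimed by its nearest phase target
    (its *primary* bin).  Each bin keeps its n nearest primaries; bins short
    of n then borrow, nearest-first, from unclaimed excitations (primaries
    beyond a crowded bin's n) and finally from neighbors' members, subject
    to the per-bin shared-member cap.  Ties in circular distance break
    toward the lower excitation index.
    """
    phases = np.asarray(phases, dtype=np.float64)
    B = config.n_bins
    usable_mask = np.ones(phases.size, dtype=bool)
    excluded = np.asarray(excluded, dtype=np.int64)
    usable_mask[excluded] = False
    usable = np.nonzero(usable_mask)[0]
    n_usable = usable.size

    targets = -np.pi + (2 * np.pi) * (np.arange(B) + 0.5) / B
    ph_use = phases[usable]
    dist = np.stack([_circdist(ph_use, t) for t in targets], axis=0)  # (B, U)
    primary = np.argmin(dist, axis=0)

    T = config.total_budget
    auto = T is None or (n_usable < 120_000 and T == FULL_BUDGET)
    if auto:
        T = scaled_budget(n_usable, B)
        # feasibility under the sharing cap: a bin can hold at most its
        # own primaries plus max_share_fraction*n borrowed members
        min_primaries = int(np.bincount(primary, minlength=B).min())
        if config.max_share_fraction < 0.5:
            n_cap = int(min_primaries / (1 - config.max_share_fraction))
        else:
            n_cap = 2 * min_primaries
        T = min(T, n_cap * B)
    n = T // B
    T = n * B
    s_max = int(np.floor(config.max_share_fraction * n))
    if n_usable < T * (1.0 - config.max_share_fraction) or n < 1:
        raise ValueError(
            f"insufficient usable excitations: need >= "
            f"{int(np.ceil(T * (1 - config.max_share_fraction)))}, "
            f"have {n_usable} (deficit "
            f"{int(np.ceil(T * (1 - config.max_share_fraction))) - n_usable})")

    members: list[list[int]] = []
    shared = np.zeros(B, dtype=np.int64)
    share_matrix = np.zeros((B, B), dtype=np.int64)
    claimed = np.zeros(n_usable, dtype=bool)   # claimed by its primary bin
    kept: list[np.ndarray] = []
    for b in range(B):
        own = np.nonzero(primary == b)[0]
        order = np.lexsort((usable[own], dist[b, own]))
        keep = own[order][:n]
        claimed[keep] = True
        kept.append(keep)

    for b in range(B):
        mem = list(kept[b])
        share_matrix[b, b] = len(mem)
        if len(mem) < n:
            # candidates: all other usable excitations, nearest first
            cand = np.setdiff1d(np.arange(n_usable), kept[b],
                                assume_unique=False)
            # unclaimed excitations first, then neighbors' claimed members;
            # nearest-first within each tier
            order = np.lexsort((usable[cand], dist[b, cand],
                                claimed[cand].astype(np.int64)))
            for c in cand[order]:
                if len(mem) >= n:
                    break
                if claimed[c] or primary[c] != b:
                    # counts against the sharing cap (conservatively: any
                    # member whose primary bin is another bin)
                    if shared[b] >= s_max:
                        continue
                    shared[b] += 1
                    share_matrix[b, primary[c]] += (primary[c] != b)
                mem.append(int(c))
            if len(mem) < n:
                raise ValueError(
                    f"bin {b}: cannot reach {n} members under the "
                    f"{config.max_share_fraction:.0%} sharing cap "
                    f"(deficit {n - len(mem)})")
        members.append(mem)

    bin_indices = [np.sort(usable[np.asarray(m, dtype=np.int64)])
                   for m in members]
    edges = []
    for b in range(B):
        ph = phases[bin_indices[b]]
        rel = (ph - targets[b] + np.pi) % (2 * np.pi) - np.pi
        edges.append((float(targets[b] + rel.min()),
                      float(targets[b] + rel.max())))
    mean_amp = None
    if amplitudes is not None:
        amplitudes = np.asarray(amplitudes, dtype=np.float64)
        mean_amp = np.array([amplitudes[idx].mean() for idx in bin_indices])
    return RespiratoryBinSet(
        bin_indices=bin_indices,
        target_phases=targets,
        phase_edges=edges,
        excluded=np.sort(excluded),
        share_matrix=share_matrix,
        mean_amplitude=mean_amp,
    )


def bin_kspace(kdata: KSpaceData, bins: RespiratoryBinSet) -> KSpaceBins:
    """Apply a bin allocation to raw k-space data and trajectories."""
    I = kdata.samples.shape[1]
    samples, coords = [], []
    for idx in bins.bin_indices:
        if idx.size and (idx.min() < 0 or idx.max() >= I):
            raise IndexError("bin excitation index out of range")
        samples.append(kdata.samples[:, idx, :])
        coords.append(kdata.traj.coords[idx])
    return KSpaceBins(samples=samples, coords=coords, bins=bins,
                      fov_mm=kdata.traj.fov_mm, res_mm=kdata.traj.res_mm)


def bin_bellows(trace: BellowsTrace, config: BinningConfig,
                breathing_period_s: float | None = None
                ) -> tuple[RespiratoryBinSet, BellowsTrace]:
    """Full gating chain: smooth -> exclude -> phase -> allocate."""
    if config.smoothing_window is not None:
        window = config.smoothing_window
    elif breathing_period_s is not None:
        window = max(1, int(round(0.25 * breathing_period_s / trace.dt_s)))
    else:
        window = max(1, len(trace) // 400)
    smoothed = preprocess_bellows(trace, min(window, len(trace) - 1))
    excluded = exclude_outliers(smoothed, config.exclusion_k)
    phases = instantaneous_phase(smoothed)
    bins = allocate_bins(phases, excluded, config,
                         amplitudes=smoothed.values)
    return bins, smoothed
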