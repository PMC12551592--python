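"""Analog photon tracking: dose grids, phase-space planes, track/replay.

The tracker is analog (no implicit capture or splitting); the only variance
device is phase-space recycling, mirroring the two-stage study design.  Dose
is scored with the kerma approximation: the energy transferred to charged
particles at a photon interaction vertex is deposited in the enclosing
phantom voxel, with per-primary batch statistics for the variance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import kernels
from .geometry import GeometryModel
from .materials import MaterialPack

FORWARD_PLANE_Z = -51.0
BACKSCATTER_PLANE_Z = -50.5


@dataclass(frozen=True)
class PlaneSpec:
    """A phase-space scoring plane at fixed Z.

    ``direction`` is +1 to capture photons moving toward +Z (back toward the
    isocenter) and -1 for photons moving toward -Z (toward the imager).
    """

    z: float
    direction: int
    terminate: bool = False

    def __post_init__(self):
        if self.direction not in (-1, +1):
            raise ValueError("direction must be +1 or -1")


class PhaseSpaceBatch:
    """Columnar photon phase-space records.

    Positions are (x, y) on a constant-Z plane; the plane Z comes either from
    the attached :class:`PlaneSpec` or from an explicit per-record ``z``
    column (used for free-form test beams).
    """

    FIELDS = ("energy", "x", "y", "u", "v", "w", "weight", "history_id")

    def __init__(self, energy, x, y, u, v, w, weight, history_id,
                 plane: Optional[PlaneSpec] = None, z=None,
                 n_primaries: int = 0):
        self.energy = np.asarray(energy, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.u = np.asarray(u, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.w = np.asarray(w, dtype=float)
        self.weight = np.asarray(weight, dtype=float)
        self.history_id = np.asarray(history_id, dtype=np.int64)
        self.plane = plane
        if z is None and plane is not None:
            z = np.full(len(self.energy), plane.z)
        self._z = None if z is None else np.asarray(z, dtype=float)
        self.n_primaries = int(n_primaries)
        self.validate()

    def __len__(self):
        return len(self.energy)

    @property
    def z(self) -> np.ndarray:
        if self._z is None:
            raise ValueError("phase-space batch has no z: attach a PlaneSpec "
                             "or pass an explicit z column")
        return self._z

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())

    def mean_energy(self) -> float:
        """Weighted mean energy of the records."""
        if len(self) == 0:
            raise ValueError("empty phase-space batch")
        return float(np.average(self.energy, weights=self.weight))

    def validate(self):
        n = len(self.energy)
        for f in self.FIELDS:
            if len(getattr(self, f)) != n:
                raise ValueError("phase-space columns differ in length")
        if n and (self.weight <= 0).any():
            raise ValueError("weights must be positive")
        norm = self.u**2 + self.v**2 + self.w**2
        if n and np.abs(np.sqrt(norm) - 1.0).max() > 1e-9:
            raise ValueError("directions must be unit vectors")
        if self.plane is not None and n:
            if self.plane.direction > 0 and (self.w <= 0).any():
                raise ValueError(
                    "backscatter-plane records must move toward +Z")
            if self.plane.direction < 0 and (self.w >= 0).any():
                raise ValueError("forward-plane records must move toward -Z")

    def subset(self, mask) -> "PhaseSpaceBatch":
        return PhaseSpaceBatch(
            *(getattr(self, f)[mask] for f in self.FIELDS),
            plane=self.plane,
            z=None if self._z is None else self._z[mask],
            n_primaries=self.n_primaries)


class DoseGrid:
    """Voxelized kerma tally inside the phantom.

    Depth axis runs along -Z from the beam-entry surface: 124 bins of 2 mm
    over 0-248 mm plus 100 sub-bins of 0.02 mm over 248-250 mm.  Lateral
    resolution is 24 mm in both X and Y, centred on the phantom axis.
    Accumulators hold per-primary batch sums for mean and variance.
    """

    NX, NY = 17, 13
    N_DEPTH = kernels.N_DEPTH
    LATERAL = 2.4  # cm

    def __init__(self, x_center: float, z_top: float):
        self.x_center = float(x_center)
        self.z_top = float(z_top)
        self.gx0 = self.x_center - self.NX * self.LATERAL / 2.0
        self.gy0 = -self.NY * self.LATERAL / 2.0
        nvox = self.N_DEPTH * self.NX * self.NY
        self.s1 = np.zeros(nvox)
        self.s2 = np.zeros(nvox)
        self.n_primaries = 0

    @staticmethod
    def depth_edges() -> np.ndarray:
        """Depth bin edges in mm (0-250)."""
        coarse = np.arange(kernels.N_COARSE + 1) * 2.0
        fine = 248.0 + np.arange(1, kernels.N_FINE + 1) * 0.02
        return np.concatenate([coarse, fine])

    @staticmethod
    def depth_centers() -> np.ndarray:
        e = DoseGrid.depth_edges()
        return 0.5 * (e[:-1] + e[1:])

    def congruent(self, other: "DoseGrid") -> bool:
        return (abs(other.x_center - self.x_center) < 1e-12 and
                abs(other.z_top - self.z_top) < 1e-12)

    def _cube(self, arr):
        return arr.reshape(self.N_DEPTH, self.NX, self.NY)

    @property
    def sum_grid(self):
        return self._cube(self.s1)

    def dose(self):
        """Mean deposited energy per primary, MeV (full 3-D grid)."""
        if self.n_primaries == 0:
            raise ValueError("empty dose grid: no primaries tracked")
        return self._cube(self.s1) / self.n_primaries

    def variance_of_mean(self):
        n = self.n_primaries
        if n < 2:
            raise ValueError("need at least two primaries for a variance")
        m = self._cube(self.s1) / n
        return np.maximum(self._cube(self.s2) / n - m**2, 0.0) / (n - 1)

    def central_axis(self):
        """(dose per primary, SE) along the phantom central axis, per bin."""
        ix, iy = self.NX // 2, self.NY // 2
        return (self.dose()[:, ix, iy],
                np.sqrt(self.variance_of_mean()[:, ix, iy]))

    def total_energy(self) -> float:
        return float(self.s1.sum())

    def accumulate(self, other: "DoseGrid"):
        if not self.congruent(other):
            raise ValueError("dose grids are not congruent")
        self.s1 += other.s1
        self.s2 += other.s2
        self.n_primaries += other.n_primaries

    def added(self, other: "DoseGrid") -> "DoseGrid":
        """Voxelwise sum of two tallies over the same primaries (D1 + D2)."""
        if not self.congruent(other):
            raise ValueError("dose grids are not congruent")
        out = DoseGrid(self.x_center, self.z_top)
        out.s1 = self.s1 + other.s1
        out.s2 = self.s2 + other.s2  # upper bound: cross-terms unavailable
        out.n_primaries = self.n_primaries
        return out


@dataclass
class TallySummary:
    """Weighted-energy ledger for one tracking run (MeV)."""

    launched_energy: float
    launched_weight: float
    deposited_phantom: float
    deposited_elsewhere: float
    escaped: float
    captured_terminated: float
    plane_weights: tuple
    plane_counts: tuple

    def closure(self) -> float:
        """Relative energy-ledger imbalance; ~0 for a correct run."""
        out = (self.deposited_phantom + self.deposited_elsewhere +
               self.escaped + self.captured_terminated)
        if self.launched_energy == 0:
            return 0.0
        return abs(out - self.launched_energy) / self.launched_energy


def _plane_arrays(planes: Sequence[PlaneSpec]):
    n = max(len(planes), 1)
    pz = np.zeros(n)
    pd = np.zeros(n, dtype=np.int64)
    pt = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(planes):
        pz[i], pd[i], pt[i] = p.z, p.direction, 1 if p.terminate else 0
    return pz, pd, pt


def _alloc_captures(capacity: int):
    return (np.empty(capacity), np.empty(capacity), np.empty(capacity),
            np.empty(capacity), np.empty(capacity), np.empty(capacity),
            np.empty(capacity), np.empty(capacity, dtype=np.int64),
            np.empty(capacity, dtype=np.int64))


def _stack():
    n = kernels._STACK
    return (np.empty(n), np.empty(n), np.empty(n), np.empty(n), np.empty(n),
            np.empty(n), np.empty(n), np.empty(n),
            np.empty(n, dtype=np.int64))


class KernelRun:
    """One kernel invocation: tallies, dose accumulators, capture buffers."""

    def __init__(self, geom: GeometryModel, planes: Sequence[PlaneSpec],
                 grid: Optional[DoseGrid], pack: MaterialPack, capacity: int):
        self.geom = geom
        self.planes = list(planes)
        self.pack = pack
        self.score_grid = grid if grid is not None else DoseGrid(0.0, 0.0)
        self.enable_phantom = grid is not None
        nvox = self.score_grid.s1.shape[0]
        self.pend = np.zeros(nvox)
        self.pend_hid = np.full(nvox, -1, dtype=np.int64)
        self.plane_z, self.plane_dir, self.plane_term = _plane_arrays(planes)
        self.caps = _alloc_captures(capacity)
        self.cap_n = np.zeros(2, dtype=np.int64)
        self.plane_wsum = np.zeros(max(len(planes), 1))
        self.plane_count = np.zeros(max(len(planes), 1), dtype=np.int64)
        self.tally = np.zeros(8)

    def geo_args(self):
        args = list(self.geom.kernel_args(self.pack))
        if not self.enable_phantom:
            args[-1] = -1
        return tuple(args)

    def score_args(self):
        g = self.score_grid
        return (g.gx0, g.gy0, g.z_top, g.NX, g.NY,
                self.pend, self.pend_hid, g.s1, g.s2)

    def plane_args(self):
        return (self.plane_z, self.plane_dir, self.plane_term,
                len(self.planes))

    def cap_args(self):
        return self.caps + (self.cap_n, self.plane_wsum, self.plane_count)

    def overflowed(self) -> bool:
        return bool(self.cap_n[1])

    def batches(self, n_primaries: int):
        n = int(self.cap_n[0])
        (cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt, cap_hid,
         cap_plane) = self.caps
        out = []
        for ip, plane in enumerate(self.planes):
            m = cap_plane[:n] == ip
            out.append(PhaseSpaceBatch(
                cap_E[:n][m].copy(), cap_x[:n][m].copy(), cap_y[:n][m].copy(),
                cap_u[:n][m].copy(), cap_v[:n][m].copy(), cap_w[:n][m].copy(),
                cap_wt[:n][m].copy(), cap_hid[:n][m].copy(),
                plane=plane, n_primaries=n_primaries))
        return out

    def summary(self) -> TallySummary:
        t = self.tally
        return TallySummary(
            launched_energy=t[kernels.T_LAUNCH_E],
            launched_weight=t[kernels.T_LAUNCH_W],
            deposited_phantom=t[kernels.T_DEP_PHANTOM],
            deposited_elsewhere=t[kernels.T_DEP_ELSE],
            escaped=t[kernels.T_ESCAPE_E],
            captured_terminated=t[kernels.T_CAPTURED_E],
            plane_weights=tuple(self.plane_wsum[:len(self.planes)]),
            plane_counts=tuple(self.plane_count[:len(self.planes)]))


def _resolve_seed(seed):
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("tracking requires an integer seed (per-history "
                        "counter-based streams)")
    return int(seed)


def track(geom: GeometryModel, particles: PhaseSpaceBatch,
          planes: Sequence[PlaneSpec], grid: Optional[DoseGrid],
          seed, pack: Optional[MaterialPack] = None,
          recycle: int = 1, capacity: Optional[int] = None):
    """Track a batch of photons (optionally recycled) through the geometry.

    Returns ``(grid, [captured batch per plane], TallySummary)``.  Deposits
    are accumulated into ``grid`` (a fresh congruent grid is used internally
    so capture-buffer overflow retries never double-count).  Every history
    draws from its own counter-based stream keyed by (seed, history id), so
    results are reproducible and pair across geometries run with the same
    seed.
    """
    if pack is None:
        pack = MaterialPack()
    n = len(particles)
    if capacity is None:
        capacity = max(int(2.5 * n * recycle) + 1024, 4096)
    seed = _resolve_seed(seed)
    z = particles.z if n else np.zeros(0)
    while True:
        scratch = None if grid is None else DoseGrid(grid.x_center,
                                                     grid.z_top)
        run = KernelRun(geom, planes, scratch, pack, capacity)
        kernels.run_record_histories(
            particles.energy, particles.x, particles.y, z,
            particles.u, particles.v, particles.w, particles.weight,
            particles.history_id, recycle,
            *_stack(), *pack.mu_args(), *pack.fluor_args(),
            *run.geo_args(), *run.score_args(), *run.plane_args(),
            *run.cap_args(), run.tally, seed)
        if not run.overflowed():
            break
        capacity *= 2
    if grid is not None:
        scratch.n_primaries = n
        grid.accumulate(scratch)
    return grid, run.batches(n), run.summary()


def track_source(geom: GeometryModel, inv_cdf: np.ndarray, n_histories: int,
                 half_x: float, half_y: float, z_src: float,
                 planes: Sequence[PlaneSpec], grid: Optional[DoseGrid],
                 seed, pack: Optional[MaterialPack] = None,
                 capacity: Optional[int] = None, hid0: int = 0):
    """Sample and track collimated source photons (stage-1 driver)."""
    if pack is None:
        pack = MaterialPack()
    if capacity is None:
        capacity = max(int(2.5 * n_histories) + 1024, 4096)
    seed = _resolve_seed(seed)
    while True:
        scratch = None if grid is None else DoseGrid(grid.x_center,
                                                     grid.z_top)
        run = KernelRun(geom, planes, scratch, pack, capacity)
        kernels.run_source_histories(
            n_histories, hid0, inv_cdf, half_x, half_y, z_src,
            *_stack(), *pack.mu_args(), *pack.fluor_args(),
            *run.geo_args(), *run.score_args(), *run.plane_args(),
            *run.cap_args(), run.tally, seed)
        if not run.overflowed():
            break
        capacity *= 2
    if grid is not None:
        scratch.n_primaries = n_histories
        grid.accumulate(scratch)
    return grid, run.batches(n_histories), run.summary()


def replay(records: PhaseSpaceBatch, recycle: int,
           rng=None) -> PhaseSpaceBatch:
    """Re-emit each record ``recycle`` times with weight divided by recycle.

    Downstream randomness is independent per replica because the tracker
    consumes the random stream sequentially; total emitted weight equals the
    captured weight (to floating-point rounding).
    """
    if recycle < 1:
        raise ValueError("recycle must be >= 1")
    if recycle == 1:
        return records
    rep = np.repeat
    return PhaseSpaceBatch(
        *(rep(getattr(records, f), recycle) for f in
          ("energy", "x", "y", "u", "v", "w")),
        rep(records.weight / recycle, recycle),
        rep(records.history_id, recycle),
        plane=records.plane,
        z=None if records._z is None else rep(records._z, recycle),
        n_primaries=records.n_primaries)
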