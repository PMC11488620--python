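"""Shared data containers passed between pipeline stages.

Conventions: volumetric data are ``(nx, ny, nz, T)`` float arrays with an
accompanying boolean brain mask of shape ``(nx, ny, nz)``; voxel-by-time
matrices are ``(V, T)`` where ``V`` counts in-mask voxels in C order; time
is always the last axis and is indexed in volumes (TR units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NetworkAtlas:
    """A set of spatial network weight maps on a common 3D lattice.

    maps : (n_networks, nx, ny, nz) array of weights in [0, 1]; each
        network must have at least one strictly positive voxel.
    """

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("atlas maps must be (n_networks, nx, ny, nz)")
        if np.any(self.maps < 0) or np.any(self.maps > 1):
            raise ValueError("atlas weights must lie in [0, 1]")
        if np.any(self.maps.reshape(self.n_networks, -1).max(axis=1) <= 0):
            raise ValueError("every network needs at least one positive voxel")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    @property
    def support(self) -> np.ndarray:
        """Boolean union of all network supports (a synthetic 'brain' mask)."""
        return self.maps.sum(axis=0) > 0

    def pairwise_overlap(self, i: int, j: int) -> float:
        """Fraction of the smaller network's voxels shared with the other."""
        a = self.maps[i] > 0
        b = self.maps[j] > 0
        denom = min(a.sum(), b.sum())
        return float((a & b).sum() / denom) if denom else 0.0


@dataclass
class MotionRecord:
    """Per-volume rigid-body motion and the derived scrubbing mask.

    params : (T, 6) translations in mm then rotations in radians.
    fd : framewise displacement in mm, FD[0] = 0 by definition.
    scrub_mask : True where the volume is retained (below the FD threshold).
    """

    params: np.ndarray
    fd: np.ndarray
    scrub_mask: np.ndarray

    @property
    def mean_fd(self) -> float:
        return float(self.fd[1:].mean()) if len(self.fd) > 1 else 0.0


@dataclass
class BoldSession:
    """One subject-session resting-state 4D time series.

    data : (nx, ny, nz, T); mask : (nx, ny, nz) bool; tr in seconds.
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float
    subject: str = ""
    session: str = ""
    motion: MotionRecord | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match the session grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def scrub_mask(self) -> np.ndarray:
        if self.motion is None:
            return np.ones(self.n_volumes, dtype=bool)
        return self.motion.scrub_mask

    def voxel_matrix(self) -> np.ndarray:
        """In-mask voxels as a (V, T) matrix (C-order voxel enumeration)."""
        return self.data[self.mask]


@dataclass
class PlantedTruth:
    """Ground-truth bookkeeping for a synthetic subject-session.

    trains : (n_networks, T) binary activity trains.
    block_onsets/offsets : per network, volume indices of block starts and
        one-past-the-end offsets (half-open intervals).
    planted_duration_pct : per network, 100 * active volumes / T.
    """

    trains: np.ndarray
    block_onsets: list[np.ndarray]
    block_offsets: list[np.ndarray]
    planted_duration_pct: np.ndarray
    seed: int

    @property
    def edge_volumes(self) -> np.ndarray:
        """All volumes where some network switches on or off."""
        edges: set[int] = set()
        n_vol = self.trains.shape[1]
        for on, off in zip(self.block_onsets, self.block_offsets):
            edges.update(int(v) for v in on)
            edges.update(int(v) for v in off if v < n_vol)
        return np.array(sorted(edges), dtype=int)


@dataclass
class InnovationSet:
    """Deconvolution output for one session, restricted to in-mask voxels.

    activity : (V, T) piecewise-constant activity-inducing signals.
    innovations : (V, T) first differences of activity (column 0 is zero).
    """

    activity: np.ndarray
    innovations: np.ndarray
    lambda_used: np.ndarray
    objective_trace: np.ndarray  # (n_iter, V), non-increasing down columns
    mask: np.ndarray
    tr: float
    subject: str = ""
    session: str = ""
    scrub_mask: np.ndarray | None = field(default=None)

    @property
    def n_voxels(self) -> int:
        return self.activity.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.activity.shape[1]
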