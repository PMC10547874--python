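"""Binarization of source currents into spatiotemporal activation clouds.

A source is "active" at a sample when the absolute current exceeds that
source's threshold, defined as mean + standard deviation of the absolute
current over the whole epoch.  The rule is scale-equivariant: rescaling a
source's series rescales its threshold and leaves the activation mask
unchanged.  Binarization is whole-brain; network analyses restrict the
resulting mask to the sources of one network afterwards.

Voxelization maps active-source positions onto a ``G**3`` occupancy grid
(``G`` a power of two) inside a per-subject bounding box shared by all
windows and networks, so grids are comparable across the whole record.  For
the 4-D cloud of a window the local time axis is quantised to ``G`` bins as
well, giving an isotropic ``G**4`` index space.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import NETWORKS, REGIONS, CurrentMatrix, SourceSpace

__all__ = [
    "ThresholdVector",
    "ActivationSet",
    "GridSpec",
    "compute_thresholds",
    "binarize",
    "restrict",
    "voxelize",
    "voxelize4d",
]


@dataclasses.dataclass
class ThresholdVector:
    """Per-source activation thresholds (same units as the current)."""

    theta: np.ndarray
    scope: str = "epoch"  # "epoch" or "window"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < 0):
            raise ValueError("thresholds are computed from absolute values; negative")


@dataclasses.dataclass
class ActivationSet:
    """Boolean activation mask, one row per source, one column per sample."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("activation mask must be 2-D")

    @property
    def n_events(self) -> int:
        return int(self.mask.sum())

    def events(self) -> np.ndarray:
        """All activation events as ``(source, sample)`` index pairs."""
        return np.argwhere(self.mask)


def compute_thresholds(
    matrix: CurrentMatrix | np.ndarray, scope: str = "epoch"
) -> ThresholdVector:
    """Per-source threshold: mean + SD of the absolute current.

    The standard deviation is the sample SD (divisor T-1).  With the default
    ``epoch`` scope the statistics run over the entire record; ``window``
    scope is handled by calling this on a window slice.  A constant-zero
    source gets threshold 0 and, because the activation rule is a strict
    inequality, is never active; a warning is emitted.
    """
    values = matrix.values if isinstance(matrix, CurrentMatrix) else np.asarray(matrix)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 time samples to compute thresholds")
    absval = np.abs(values)
    theta = absval.mean(axis=1) + absval.std(axis=1, ddof=1)
    n_silent = int((theta == 0).sum())
    if n_silent:
        warnings.warn(
            f"{n_silent} constant-zero source(s) have threshold 0 and will "
            "never activate",
            stacklevel=2,
        )
    return ThresholdVector(theta=theta, scope=scope)


def binarize(
    matrix: CurrentMatrix | np.ndarray, thresholds: ThresholdVector
) -> ActivationSet:
    """Strict-inequality binarization: active iff ``|value| > theta``."""
    values = matrix.values if isinstance(matrix, CurrentMatrix) else np.asarray(matrix)
    if thresholds.theta.shape[0] != values.shape[0]:
        raise ValueError(
            f"threshold length {thresholds.theta.shape[0]} does not match "
            f"{values.shape[0]} sources"
        )
    return ActivationSet(mask=np.abs(values) > thresholds.theta[:, None])


def restrict(
    activation: ActivationSet, space: SourceSpace, region: str
) -> ActivationSet:
    """Keep only events on sources of one region; other rows become all-false.

    ``Brain`` is the identity (all sources, including unassigned ones).
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    keep = space.region_mask(region)
    mask = activation.mask.copy()
    mask[~keep, :] = False
    return ActivationSet(mask=mask)


@dataclasses.dataclass
class GridSpec:
    """Axis-aligned bounding box plus grid resolution.

    The box is computed once per subject from *all* source positions and
    padded by a relative epsilon so the supremum of each axis falls inside
    the last cell; it is deliberately not recomputed per window or per
    network.
    """

    lo: np.ndarray
    hi: np.ndarray
    side: int = 64

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.side < 2 or (self.side & (self.side - 1)) != 0:
            raise ValueError("grid side must be a power of two >= 2")
        if np.any(self.hi <= self.lo):
            raise ValueError("bounding box must have positive extent on each axis")

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, side: int = 64, pad: float = 1e-9
    ) -> "GridSpec":
        positions = np.asarray(positions, dtype=float)
        lo = positions.min(axis=0)
        hi = positions.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return cls(lo=lo, hi=hi + pad * span, side=side)

    def cell_coords(self, positions: np.ndarray) -> np.ndarray:
        """Integer cell coordinates ``floor(G (x - lo) / (hi - lo))``, clamped."""
        positions = np.asarray(positions, dtype=float)
        frac = (positions - self.lo) / (self.hi - self.lo)
        return np.clip(
            np.floor(self.side * frac).astype(np.int64), 0, self.side - 1
        )

    def time_bins(self, t_local: np.ndarray, window_len: int) -> np.ndarray:
        """Quantise local sample indices of a window to ``G`` time bins."""
        t_local = np.asarray(t_local, dtype=np.int64)
        return np.clip(
            (self.side * t_local) // window_len, 0, self.side - 1
        )


def voxelize(points_3d: np.ndarray, grid_spec: GridSpec) -> np.ndarray:
    """Dense 3-D occupancy grid of a point set (duplicates are idempotent)."""
    g = grid_spec.side
    grid = np.zeros((g, g, g), dtype=bool)
    points_3d = np.asarray(points_3d, dtype=float)
    if points_3d.size:
        cells = grid_spec.cell_coords(points_3d)
        grid[cells[:, 0], cells[:, 1], cells[:, 2]] = True
    return grid


def voxelize4d(
    points_4d: np.ndarray, grid_spec: GridSpec, window_len: int
) -> np.ndarray:
    """Dense 4-D occupancy grid of ``(x, y, z, t_local)`` events.

    Intended for small grids (tests, fixtures); the pipeline counts boxes
    from sparse cell lists instead of materialising ``G**4`` cells.
    """
    g = grid_spec.side
    grid = np.zeros((g, g, g, g), dtype=bool)
    points_4d = np.asarray(points_4d)
    if points_4d.size:
        cells = grid_spec.cell_coords(points_4d[:, :3].astype(float))
        tb = grid_spec.time_bins(points_4d[:, 3].astype(np.int64), window_len)
        grid[cells[:, 0], cells[:, 1], cells[:, 2], tb] = True
    return grid
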