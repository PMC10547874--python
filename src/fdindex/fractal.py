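"""Fractal dimension estimators.

Two estimators drive the whole index:

* the box-counting dimension of an occupancy grid in any embedding
  dimension (here 3 for instantaneous activation clouds and 4 for the
  spatiotemporal cloud of a 1-s window), estimated as the least-squares
  slope of ``log N(eps)`` against ``log(1/eps)`` over a nested schedule of
  box sizes; and

* the Higuchi fractal dimension of a 1-D curve, estimated from mean
  normalised curve lengths ``L(k)`` at lags ``k = 1..kmax`` as the slope of
  ``log L(k)`` against ``log(1/k)``.

With nested box schedules the box-counting slope is provably confined to
``[0, embed_dim]`` (coarsening by a factor b can merge at most ``b**d``
boxes), and the Higuchi estimate is clamped to its theoretical range
``[1, 2]`` with the raw slope retained for diagnostics.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

__all__ = [
    "BoxCountResult",
    "HiguchiResult",
    "boxcount_fd",
    "boxcount_fd_cells",
    "boxcount_oracle",
    "higuchi_fd",
    "occupied_cells",
    "count_occupied",
    "fd_series_3d",
    "fd_4d",
]


@dataclasses.dataclass
class BoxCountResult:
    """Box counts over a scale schedule and the fitted dimension."""

    scales: np.ndarray
    counts: np.ndarray
    fd: float
    r2: float
    embed_dim: int
    degenerate: bool = False


@dataclasses.dataclass
class HiguchiResult:
    """Higuchi curve lengths, fitted slope, and the clamped dimension."""

    kmax: int
    curve_lengths: np.ndarray
    fd: float
    raw_fd: float
    degenerate: bool = False


def _default_scales(side: int) -> np.ndarray:
    """Dyadic schedule 1, 2, 4, ..., side/2."""
    if side < 2:
        raise ValueError("grid side must be >= 2")
    scales = []
    s = 1
    while s <= side // 2:
        scales.append(s)
        s *= 2
    return np.asarray(scales, dtype=int)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y on x and the fit's R^2."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    ss_res = float(((yc - slope * xc) ** 2).sum())
    ss_tot = float(yc @ yc)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def occupied_cells(grid: np.ndarray) -> np.ndarray:
    """Coordinates ``(M, d)`` of the occupied cells of a dense grid."""
    return np.argwhere(np.asarray(grid, dtype=bool))


def count_occupied(cells: np.ndarray, scale: int) -> int:
    """Number of ``scale``-sided boxes containing at least one occupied cell.

    ``cells`` is an ``(M, d)`` integer array of occupied fine-cell
    coordinates; duplicate rows are allowed (the count is idempotent).
    """
    if len(cells) == 0:
        return 0
    coarse = cells // scale if scale > 1 else cells
    return len(np.unique(coarse, axis=0))


def boxcount_fd(
    grid: np.ndarray,
    scales: np.ndarray | list[int] | None = None,
    min_scales: int = 3,
) -> BoxCountResult:
    """Box-counting dimension of a dense d-dimensional occupancy grid.

    Parameters
    ----------
    grid
        Boolean array with equal sides (``side**d`` cells).
    scales
        Box sides in cells; each must divide the grid side.  Defaults to the
        dyadic schedule ``{1, 2, 4, ..., side/2}``.  Powers of another base
        (e.g. 3 for Cantor fixtures) are accepted.
    min_scales
        Fewer usable scales than this is an error: the log-log regression
        would be meaningless.
    """
    grid = np.asarray(grid, dtype=bool)
    side = grid.shape[0]
    if any(s != side for s in grid.shape):
        raise ValueError(f"grid sides must be equal, got {grid.shape}")
    cells = occupied_cells(grid)
    return boxcount_fd_cells(
        cells, side=side, embed_dim=grid.ndim, scales=scales, min_scales=min_scales
    )


def boxcount_fd_cells(
    cells: np.ndarray,
    side: int,
    embed_dim: int,
    scales: np.ndarray | list[int] | None = None,
    min_scales: int = 3,
) -> BoxCountResult:
    """Box-counting dimension from occupied-cell coordinates.

    Same contract as :func:`boxcount_fd` but takes the sparse ``(M, d)``
    cell list directly; this is the representation the pipeline uses, since
    activation clouds occupy a tiny fraction of the grid.
    """
    if scales is None:
        scales = _default_scales(side)
    scales = np.asarray(scales, dtype=int)
    if np.any(side % scales != 0):
        bad = scales[side % scales != 0]
        raise ValueError(f"scales {bad.tolist()} do not divide grid side {side}")
    if len(scales) < min_scales:
        raise ValueError(
            f"need at least {min_scales} scales, got {len(scales)}"
        )
    counts = np.array([count_occupied(cells, int(s)) for s in scales])
    if len(cells) == 0:
        return BoxCountResult(
            scales=scales,
            counts=counts,
            fd=0.0,
            r2=1.0,
            embed_dim=embed_dim,
            degenerate=True,
        )
    # slope of log N(eps) vs log(1/eps)
    slope, r2 = _ols_slope(-np.log(scales.astype(float)), np.log(counts))
    return BoxCountResult(
        scales=scales,
        counts=counts,
        fd=slope,
        r2=r2,
        embed_dim=embed_dim,
        degenerate=False,
    )


def boxcount_oracle(
    grid: np.ndarray, scales: np.ndarray | list[int]
) -> np.ndarray:
    """Naive box counting: loop over every box and test it for occupancy.

    Deliberately unoptimised; serves as the reference the fast
    implementation is checked against on small grids.
    """
    grid = np.asarray(grid, dtype=bool)
    side = grid.shape[0]
    counts = []
    for s in scales:
        s = int(s)
        if side % s:
            raise ValueError(f"scale {s} does not divide side {side}")
        n = 0
        for corner in itertools.product(range(0, side, s), repeat=grid.ndim):
            block = grid[tuple(slice(c, c + s) for c in corner)]
            if block.any():
                n += 1
        counts.append(n)
    return np.asarray(counts)


def higuchi_fd(series: np.ndarray, kmax: int = 8) -> HiguchiResult:
    """Higuchi fractal dimension of a 1-D series.

    For each lag ``k`` and offset ``m = 1..k`` (1-based) the normalised
    curve length is

        L_m(k) = (N-1) / (floor((N-m)/k) * k**2)
                 * sum_i |X(m + i*k) - X(m + (i-1)*k)|

    and ``L(k)`` is the mean over offsets.  The dimension is the slope of
    ``log L(k)`` versus ``log(1/k)``, clamped to ``[1, 2]``.

    A constant series has zero curve length at every lag; it is returned as
    ``fd = 1`` with the degenerate flag set.  Lags whose mean length is zero
    on a non-constant series (possible for pathological periodic inputs)
    are dropped from the regression.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 2 * kmax + 2:
        raise ValueError(
            f"series of length {n} too short for kmax={kmax}; "
            f"need at least {2 * kmax + 2} samples"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")

    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lm = np.empty(k)
        for m in range(1, k + 1):
            sub = x[m - 1 :: k]
            n_int = (n - m) // k  # number of increments at this offset
            if n_int < 1:
                lm[m - 1] = 0.0
                continue
            dist = np.abs(np.diff(sub[: n_int + 1])).sum()
            lm[m - 1] = dist * (n - 1) / (n_int * k * k)
        lengths[k - 1] = lm.mean()

    if np.all(lengths == 0):  # constant input
        return HiguchiResult(
            kmax=kmax,
            curve_lengths=lengths,
            fd=1.0,
            raw_fd=1.0,
            degenerate=True,
        )
    usable = lengths > 0
    ks = np.arange(1, kmax + 1, dtype=float)[usable]
    if usable.sum() < 2:
        return HiguchiResult(
            kmax=kmax,
            curve_lengths=lengths,
            fd=1.0,
            raw_fd=1.0,
            degenerate=True,
        )
    slope, _ = _ols_slope(-np.log(ks), np.log(lengths[usable]))
    return HiguchiResult(
        kmax=kmax,
        curve_lengths=lengths,
        fd=float(np.clip(slope, 1.0, 2.0)),
        raw_fd=slope,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# activation-cloud dimensions


def fd_series_3d(activation, space, region, grid_spec, window) -> np.ndarray:
    """3-D box-counting dimension at each time sample of a window.

    For every sample in ``window = (t0, t1)`` the active sources of the
    region form a 3-D point cloud; its box-counting dimension over the
    default dyadic schedule is one value of the returned series.  Samples
    with no activations yield 0 by convention.

    This is the straightforward reference implementation; the pipeline uses
    an equivalent precomputed-index fast path.
    """
    t0, t1 = window
    keep = space.region_mask(region)
    cells = grid_spec.cell_coords(space.positions)
    out = np.zeros(t1 - t0)
    for j, t in enumerate(range(t0, t1)):
        active = np.flatnonzero(activation.mask[:, t] & keep)
        res = boxcount_fd_cells(cells[active], side=grid_spec.side, embed_dim=3)
        out[j] = res.fd
    return out


def fd_4d(activation, space, region, grid_spec, window) -> BoxCountResult:
    """4-D box-counting dimension of a window's spatiotemporal cloud.

    The window's events ``(source, t)`` are mapped to cells of an isotropic
    ``G**4`` grid: spatial cells from the shared per-subject bounding box,
    the local time axis quantised to ``G`` bins.  An empty window returns
    dimension 0 with the degenerate flag set.
    """
    t0, t1 = window
    keep = space.region_mask(region)
    sub = activation.mask[:, t0:t1] & keep[:, None]
    src, t_local = np.nonzero(sub)
    cells3 = grid_spec.cell_coords(space.positions[src])
    tb = grid_spec.time_bins(t_local, t1 - t0)
    cells4 = np.column_stack([cells3, tb])
    return boxcount_fd_cells(cells4, side=grid_spec.side, embed_dim=4)
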