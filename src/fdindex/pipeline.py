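"""Per-subject FDI pipeline: windowing, per-network dimensions, aggregation.

For every subject the record is tiled into non-overlapping 1-s windows.
Within each window and each analysis region the pipeline computes

* the 3DFD series: one 3-D box-counting dimension per time sample,
* HFD(3DFD): the Higuchi dimension of that series (cortical
  differentiation),
* 4DFD: the 4-D box-counting dimension of the window's spatiotemporal
  cloud (cortical integration), and
* FDI = 4DFD x HFD(3DFD),

then averages the window FDI values into one value per subject and region.
Thresholds are computed once per subject over the whole epoch (the
``window`` scope recomputes them inside each window for sensitivity
analyses).  Windows with no activation events are flagged degenerate and
excluded from the subject average.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .activation import ActivationSet, GridSpec, binarize, compute_thresholds
from .fractal import BoxCountResult, HiguchiResult, boxcount_fd_cells, higuchi_fd
from .io import REGIONS, CohortTable, CurrentMatrix, SourceSpace

__all__ = [
    "WindowFDI",
    "SubjectNetworkFDI",
    "split_windows",
    "compute_fdi",
    "aggregate_subject",
    "aggregate_all",
    "group_trend",
    "run_cohort",
]


@dataclasses.dataclass
class WindowFDI:
    """One window x region record of the pipeline."""

    subject_id: str
    network: str
    window_index: int
    fd3_series: np.ndarray
    hfd: HiguchiResult
    fd4: BoxCountResult
    fdi: float
    degenerate: bool


@dataclasses.dataclass
class SubjectNetworkFDI:
    """Subject-level FDI: mean over the non-degenerate windows of a region."""

    subject_id: str
    network: str
    fdi_mean: float
    n_windows: int
    window_values: np.ndarray


def split_windows(
    matrix: CurrentMatrix | int,
    window_seconds: float = 1.0,
    fs: float | None = None,
) -> list[tuple[int, int]]:
    """Non-overlapping window bounds ``[t0, t1)`` tiling the record.

    Accepts a :class:`CurrentMatrix` or a plain sample count with ``fs``.
    A trailing partial window is dropped.
    """
    if isinstance(matrix, CurrentMatrix):
        n, rate = matrix.n_samples, matrix.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a sample count")
        n, rate = int(matrix), fs
    w = round(window_seconds * rate)
    if w < 2:
        raise ValueError("window too short")
    if w > n:
        raise ValueError(f"window of {w} samples exceeds record length {n}")
    return [(t0, t0 + w) for t0 in range(0, n - w + 1, w)]


class _RegionCounter:
    """Per-region box counting with per-scale precomputed linear indices.

    The spatial cell of every source is fixed per subject (shared bounding
    box), so for each scale the coarse linear index of every source can be
    computed once; counting boxes at a time sample reduces to a ``unique``
    over the active subset.
    """

    def __init__(self, cells: np.ndarray, side: int):
        scales = []
        s = 1
        while s <= side // 2:
            scales.append(s)
            s *= 2
        self.scales = np.asarray(scales, dtype=int)
        self.side = side
        self.lin3: list[np.ndarray] = []
        self.coarse_side: list[int] = []
        for s in scales:
            g = side // s
            c = cells // s
            self.lin3.append(((c[:, 0] * g + c[:, 1]) * g + c[:, 2]).astype(np.int64))
            self.coarse_side.append(g)
        x = -np.log(self.scales.astype(float))
        self._xc = x - x.mean()
        self._sxx = float(self._xc @ self._xc)

    def _slope(self, counts: np.ndarray) -> float:
        y = np.log(counts)
        return float(self._xc @ (y - y.mean())) / self._sxx

    def fd3(self, active: np.ndarray) -> float:
        """3-D dimension of the active subset at one sample (0 if empty)."""
        if active.size == 0:
            return 0.0
        counts = np.array(
            [np.unique(lin[active]).size for lin in self.lin3], dtype=float
        )
        return self._slope(counts)

    def fd4(self, src: np.ndarray, tbin: np.ndarray) -> BoxCountResult:
        """4-D dimension of a window's events (sources x G time bins)."""
        if src.size == 0:
            return BoxCountResult(
                scales=self.scales,
                counts=np.zeros(len(self.scales), dtype=int),
                fd=0.0,
                r2=1.0,
                embed_dim=4,
                degenerate=True,
            )
        counts = np.empty(len(self.scales), dtype=float)
        for i, s in enumerate(self.scales):
            g = self.coarse_side[i]
            lin4 = self.lin3[i][src] * g + tbin // s
            counts[i] = np.unique(lin4).size
        return BoxCountResult(
            scales=self.scales,
            counts=counts.astype(int),
            fd=self._slope(counts),
            r2=_r2(self._xc, np.log(counts)),
            embed_dim=4,
            degenerate=False,
        )


def _r2(xc: np.ndarray, y: np.ndarray) -> float:
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        return 1.0
    slope = float(xc @ yc) / float(xc @ xc)
    return 1.0 - float(((yc - slope * xc) ** 2).sum()) / ss_tot


def compute_fdi(
    matrix: CurrentMatrix,
    space: SourceSpace,
    networks: tuple[str, ...] = REGIONS,
    grid: int = 64,
    kmax: int = 8,
    scope: str = "epoch",
    window_seconds: float = 1.0,
) -> list[WindowFDI]:
    """Full FDI computation for one subject.

    Returns one :class:`WindowFDI` per window x region, in window-major
    order.  Deterministic: identical inputs give identical outputs, and
    windows are independent given the thresholds.
    """
    if matrix.n_sources != space.n_sources:
        raise ValueError("matrix and source space disagree on source count")
    unknown = set(networks) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown regions {sorted(unknown)}")
    windows = split_windows(matrix, window_seconds)
    w_len = windows[0][1] - windows[0][0]
    if w_len < 2 * kmax + 2:
        raise ValueError(
            f"{w_len}-sample windows are too short for kmax={kmax}"
        )
    if scope == "epoch":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask_full = binarize(matrix, compute_thresholds(matrix)).mask
    elif scope == "window":
        mask_full = np.zeros(matrix.values.shape, dtype=bool)
        for t0, t1 in windows:
            sub = matrix.values[:, t0:t1]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thr = compute_thresholds(sub, scope="window")
            mask_full[:, t0:t1] = binarize(sub, thr).mask
    else:
        raise ValueError(f"unknown threshold scope {scope!r}")

    grid_spec = GridSpec.from_positions(space.positions, side=grid)
    cells = grid_spec.cell_coords(space.positions)

    region_rows = {r: np.flatnonzero(space.region_mask(r)) for r in networks}
    counters = {r: _RegionCounter(cells[rows], grid) for r, rows in region_rows.items()}
    # time bin of each local sample, shared by all windows of equal length
    tbin_of_local = grid_spec.time_bins(np.arange(w_len), w_len)

    results: list[WindowFDI] = []
    for w_idx, (t0, t1) in enumerate(windows):
        for region in networks:
            rows = region_rows[region]
            counter = counters[region]
            sub = mask_full[np.ix_(rows, np.arange(t0, t1))]
            fd3 = np.empty(t1 - t0)
            for j in range(t1 - t0):
                fd3[j] = counter.fd3(np.flatnonzero(sub[:, j]))
            hfd = higuchi_fd(fd3, kmax=kmax)
            src, t_local = np.nonzero(sub)
            fd4 = counter.fd4(src, tbin_of_local[t_local])
            results.append(
                WindowFDI(
                    subject_id=matrix.subject_id,
                    network=region,
                    window_index=w_idx,
                    fd3_series=fd3,
                    hfd=hfd,
                    fd4=fd4,
                    fdi=fd4.fd * hfd.fd,
                    degenerate=fd4.degenerate,
                )
            )
    return results


def aggregate_subject(windows: list[WindowFDI]) -> SubjectNetworkFDI:
    """Average the window FDI values of one subject x region.

    Degenerate (event-free) windows are excluded from the mean and from
    ``n_windows``; a warning reports how many were dropped.
    """
    if not windows:
        raise ValueError("no windows to aggregate")
    sids = {w.subject_id for w in windows}
    nets = {w.network for w in windows}
    if len(sids) != 1 or len(nets) != 1:
        raise ValueError("aggregate_subject expects one subject x region")
    good = [w.fdi for w in windows if not w.degenerate]
    n_dropped = len(windows) - len(good)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} degenerate window(s) excluded from the FDI average "
            f"of {windows[0].subject_id}/{windows[0].network}",
            stacklevel=2,
        )
    values = np.asarray(good)
    return SubjectNetworkFDI(
        subject_id=windows[0].subject_id,
        network=windows[0].network,
        fdi_mean=float(values.mean()) if values.size else float("nan"),
        n_windows=len(good),
        window_values=values,
    )


def aggregate_all(windows: list[WindowFDI]) -> list[SubjectNetworkFDI]:
    """Aggregate a mixed window list into per-(subject, region) records."""
    keys: dict[tuple[str, str], list[WindowFDI]] = {}
    for w in windows:
        keys.setdefault((w.subject_id, w.network), []).append(w)
    return [aggregate_subject(v) for v in keys.values()]


def group_trend(
    windows: list[WindowFDI], group_of: dict[str, str]
) -> pd.DataFrame:
    """Group-mean FDI per region and window index (the trend curves).

    Returns a tidy frame with columns ``network``, ``window_index``,
    ``group`` and ``fdi_mean``; each value averages the corresponding 1-s
    window over all subjects of the group.
    """
    rows = [
        {
            "network": w.network,
            "window_index": w.window_index,
            "group": group_of[w.subject_id],
            "fdi": w.fdi,
        }
        for w in windows
        if not w.degenerate
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["network", "window_index", "group"], as_index=False)["fdi"]
        .mean()
        .rename(columns={"fdi": "fdi_mean"})
    )


def run_cohort(
    space: SourceSpace,
    matrices: list[CurrentMatrix],
    table: CohortTable,
    networks: tuple[str, ...] = REGIONS,
    grid: int = 64,
    kmax: int = 8,
    scope: str = "epoch",
    window_seconds: float = 1.0,
) -> tuple[CohortTable, list[WindowFDI]]:
    """Run the pipeline for every subject and fill ``FDI_<region>`` columns."""
    all_windows: list[WindowFDI] = []
    per_subject: dict[str, dict[str, float]] = {}
    for matrix in matrices:
        windows = compute_fdi(
            matrix,
            space,
            networks=networks,
            grid=grid,
            kmax=kmax,
            scope=scope,
            window_seconds=window_seconds,
        )
        all_windows.extend(windows)
        for agg in aggregate_all(windows):
            per_subject.setdefault(agg.subject_id, {})[
                f"FDI_{agg.network}"
            ] = agg.fdi_mean
    df = table.df.copy()
    for region in networks:
        col = f"FDI_{region}"
        df[col] = [per_subject.get(sid, {}).get(col, np.nan) for sid in df["subject_id"]]
    return CohortTable(df), all_windows
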