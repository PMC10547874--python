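"""Readers and writers for source models, current matrices and cohort tables.

All delimited formats are tab-separated with a header row and "." as the
decimal mark.  Full-scale current matrices (15,002 sources x 75,000 samples
is ~9 GB as text) are stored one-per-subject in an HDF5 container with a
``values`` dataset and ``fs`` / ``subject_id`` attributes; delimited text is
accepted everywhere for small inputs and fixtures.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: The five resting-state functional networks analysed separately.
NETWORKS = ("AUD", "DAN", "DMN", "SAN", "VIS")

#: Analysis regions: the five networks plus the whole-brain source set.
REGIONS = NETWORKS + ("Brain",)

#: Label for sources outside the five networks (still part of "Brain").
NO_NETWORK = "NONE"

_VALID_LABELS = frozenset(NETWORKS) | {NO_NETWORK}

_SCIP_COLUMNS = ("VLi", "VLd", "VF", "WM", "PS")
_PANSS_COLUMNS = ("PANSS_P", "PANSS_N", "PANSS_G")


class ValidationError(ValueError):
    """Raised when an input file or array violates a structural contract."""


@dataclasses.dataclass
class SourceSpace:
    """Cortical source model: dipole positions plus a network label each.

    Parameters
    ----------
    positions
        ``(N, 3)`` float array of source coordinates in millimetres.  The
        units are recorded for provenance only; box counting depends on
        relative geometry alone.
    networks
        ``(N,)`` array of labels in ``{AUD, DAN, DMN, SAN, VIS, NONE}``.
        ``NONE`` marks sources outside the five networks; they still take
        part in whole-brain analysis.
    """

    positions: np.ndarray
    networks: np.ndarray
    units: str = "mm"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.networks = np.asarray(self.networks, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"positions must be (N, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 1:
            raise ValidationError("source space must contain at least one source")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("source positions must be finite")
        if len(np.unique(self.positions, axis=0)) < 2:
            raise ValidationError("need at least 2 distinct source positions")
        if self.networks.shape != (self.positions.shape[0],):
            raise ValidationError("one network label per source is required")
        bad = [
            (i, lab)
            for i, lab in enumerate(self.networks)
            if lab not in _VALID_LABELS
        ]
        if bad:
            listing = ", ".join(f"row {i}: {lab!r}" for i, lab in bad[:10])
            raise ValidationError(f"unknown network labels: {listing}")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of the sources belonging to ``region``.

        ``Brain`` selects every source, including ``NONE``-labelled ones.
        """
        if region == "Brain":
            return np.ones(self.n_sources, dtype=bool)
        if region not in NETWORKS:
            raise ValidationError(
                f"unknown region {region!r}; expected one of {REGIONS}"
            )
        return self.networks == region


@dataclasses.dataclass
class CurrentMatrix:
    """One subject's source currents: ``(N, T)`` signed values at ``fs`` Hz."""

    subject_id: str
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got {self.values.ndim}-D")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-finite current at (source {r}, sample {c})"
            )

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds (T / fs)."""
        return self.values.shape[1] / self.fs


@dataclasses.dataclass
class CohortTable:
    """Subject-level table: group, covariates, clinical scores, FDI columns.

    Wraps a :class:`pandas.DataFrame` with one row per subject.  Expected
    columns: ``subject_id``, ``group`` (HC/SCZ), ``age``, ``sex`` (M/F),
    ``education`` (Primary/Secondary/High), the SCIP-S subscales
    (VLi, VLd, VF, WM, PS), the PANSS subscales (PANSS_P, PANSS_N, PANSS_G;
    present for SCZ rows only), and one ``FDI_<region>`` column per analysis
    region once the pipeline has run.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValidationError(f"cohort table missing column {col!r}")
        bad_groups = set(df["group"].unique()) - {"HC", "SCZ"}
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        hc = df["group"] == "HC"
        panss_present = [c for c in _PANSS_COLUMNS if c in df.columns]
        if panss_present and hc.any():
            if df.loc[hc, panss_present].notna().any().any():
                warnings.warn(
                    "HC rows carry PANSS values; these scales are only "
                    "administered to patients",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def fdi_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("FDI_")]


# ---------------------------------------------------------------------------
# readers / writers


def read_source_space(path: str | Path) -> SourceSpace:
    """Read a TSV source model with columns id, x, y, z, network."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "x", "y", "z", "network"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"source space file missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate source ids: {dupes[:10]}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(coords.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-numeric coordinate at row {r}, column {coords.columns[c]!r}"
        )
    df = df.sort_values("id", kind="stable")
    return SourceSpace(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        networks=df["network"].to_numpy(dtype=object),
    )


def write_source_space(space: SourceSpace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(space.n_sources),
            "x": space.positions[:, 0],
            "y": space.positions[:, 1],
            "z": space.positions[:, 2],
            "network": space.networks,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_current_matrix(
    path: str | Path,
    fs: float | None = None,
    space: SourceSpace | None = None,
    subject_id: str | None = None,
) -> CurrentMatrix:
    """Read a current matrix from TSV (rows = sources) or an HDF5 container.

    For HDF5 input the ``fs`` attribute stored in the file takes effect when
    the ``fs`` argument is omitted; an explicit argument overrides it.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            file_fs = f.attrs.get("fs")
            file_sid = f.attrs.get("subject_id")
        if fs is None:
            if file_fs is None:
                raise ValidationError("fs neither given nor stored in file")
            fs = float(file_fs)
        if subject_id is None:
            subject_id = str(file_sid) if file_sid is not None else path.stem
    else:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
        if fs is None:
            raise ValidationError("fs is required for delimited matrices")
        if subject_id is None:
            subject_id = path.stem
    matrix = CurrentMatrix(subject_id=subject_id, values=values, fs=fs)
    if space is not None and matrix.n_sources != space.n_sources:
        raise ValidationError(
            f"matrix has {matrix.n_sources} rows but source space has "
            f"{space.n_sources} sources"
        )
    return matrix


def write_current_matrix(matrix: CurrentMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=matrix.values)
            f.attrs["fs"] = matrix.fs
            f.attrs["subject_id"] = matrix.subject_id
    else:
        np.savetxt(path, matrix.values, delimiter="\t")


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, na_rep="")
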