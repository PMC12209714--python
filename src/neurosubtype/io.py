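"""Readers and writers for morphometry tables and NIfTI volumes.

The tabular format is one row per subject: ``subject_id``, ``group``
(patient/control), the nuisance covariates ``age`` (years) and ``tiv``
(total intracranial volume), followed by one nonnegative gray-matter-volume
column per atlas region.  Tab- and comma-delimited files are both accepted;
region columns are always matched by name, never by position, so tables
from different parcellations cannot be silently misaligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("subject_id", "group", "age", "tiv")
GROUP_LEVELS = ("patient", "control")


class MorphometryError(ValueError):
    """Raised when a morphometry table or volume fails validation."""


@dataclass
class MorphometryTable:
    """Subjects-by-regions volume matrix with group labels and covariates.

    Attributes
    ----------
    data
        DataFrame with columns ``subject_id, group, age, tiv`` followed by
        one column per region.  ``group`` contains ``"patient"`` or
        ``"control"``.
    parcellation_name
        Name of the region scheme (e.g. a 246-region whole-brain atlas).
    region_ids
        Ordered region column names; always equal to the region columns of
        ``data``.
    """

    data: pd.DataFrame
    parcellation_name: str = "unnamed"
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_ids:
            self.region_ids = [c for c in self.data.columns if c not in MANDATORY_COLUMNS]
        validate_table(self.data, self.region_ids)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    @property
    def is_patient(self) -> np.ndarray:
        return self.data["group"].to_numpy() == "patient"

    @property
    def volumes(self) -> np.ndarray:
        """(n_subjects, n_regions) float array, region order = ``region_ids``."""
        return self.data[self.region_ids].to_numpy(dtype=float)

    def covariate_matrix(self, names: tuple[str, ...] = ("age", "tiv")) -> np.ndarray:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise MorphometryError(f"covariate column(s) not found: {missing}")
        return self.data[list(names)].to_numpy(dtype=float)


def validate_table(data: pd.DataFrame, region_ids: list[str]) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in data.columns:
            raise MorphometryError(f"missing mandatory column '{col}'")
    dup = data["subject_id"][data["subject_id"].duplicated()]
    if len(dup):
        raise MorphometryError(f"duplicate subject_id: {sorted(set(dup.astype(str)))}")
    bad_groups = set(data["group"].unique()) - set(GROUP_LEVELS)
    if bad_groups:
        raise MorphometryError(
            f"unrecognized group label(s) {sorted(bad_groups)}; expected {GROUP_LEVELS}"
        )
    if not region_ids:
        raise MorphometryError("table has no region columns")
    for col in ("age", "tiv", *region_ids):
        values = data[col]
        if not np.issubdtype(values.dtype, np.number):
            bad_rows = values[pd.to_numeric(values, errors="coerce").isna()]
            row = bad_rows.index[0] if len(bad_rows) else "?"
            raise MorphometryError(f"non-numeric value in column '{col}' (row {row})")
        if values.isna().any():
            row = int(values[values.isna()].index[0])
            raise MorphometryError(f"missing value in column '{col}' (row {row})")
    vols = data[region_ids].to_numpy(dtype=float)
    if (vols < 0).any():
        r, c = np.argwhere(vols < 0)[0]
        raise MorphometryError(
            f"negative volume in column '{region_ids[c]}' (row {r})"
        )


def read_morphometry_table(
    path: str | Path,
    parcellation_name: str | None = None,
    missing: str = "reject",
) -> MorphometryTable:
    """Read and validate a delimited morphometry table.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    parcellation_name
        Name recorded on the returned table; defaults to the file stem.
    missing
        ``"reject"`` (default) fails on any missing value; ``"drop"``
        excludes incomplete rows and logs how many were removed, so that
        subject exclusion is always auditable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"morphometry table not found: {path}")
    if missing not in ("reject", "drop"):
        raise ValueError(f"missing policy must be 'reject' or 'drop', got {missing!r}")
    with open(path, newline="") as fh:
        first_line = fh.readline()
    sep = "\t" if first_line.count("\t") >= first_line.count(",") else ","
    # round_trip parsing keeps values bit-identical through a write/read cycle
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MorphometryError(f"{path}: missing mandatory column '{col}'")
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = df["group"].astype(str).str.strip().str.lower()
    if missing == "drop":
        n_before = len(df)
        df = df.dropna().reset_index(drop=True)
        n_dropped = n_before - len(df)
        if n_dropped:
            logger.warning("%s: dropped %d row(s) with missing values", path, n_dropped)
    region_ids = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    # keep region columns numeric; pandas may have read them as object if a
    # stray string slipped in, which validate_table will report with context
    return MorphometryTable(
        data=df,
        parcellation_name=parcellation_name or path.stem,
        region_ids=region_ids,
    )


def write_morphometry_table(
    table: MorphometryTable, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a table as delimited text; round-trips exactly through ``repr``
    floating-point formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = list(MANDATORY_COLUMNS) + table.region_ids
    table.data[cols].to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    return path


# --------------------------------------------------------------------------
# NIfTI volumes


@dataclass
class LabelVolume:
    """3D integer atlas label grid with its affine."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise MorphometryError(f"label volume must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise MorphometryError("label volume contains non-integer labels")
            self.labels = np.round(self.labels).astype(np.int32)
        if (self.labels < 0).any():
            raise MorphometryError("label volume contains negative labels")
        if not (self.labels > 0).any():
            raise MorphometryError("no labeled regions (all labels zero)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.asarray(nib.affines.voxel_sizes(self.affine))


def read_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(labels=np.asanyarray(img.dataobj), affine=img.affine)


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(volume.labels.astype(np.int32), volume.affine), str(path))
    return path


def read_subject_volumes(paths: list[str | Path]) -> tuple[np.ndarray, np.ndarray]:
    """Load per-subject 3D volumes, enforcing a common geometry.

    Returns a (n_subjects, x, y, z) stack and the shared affine.
    """
    if not paths:
        raise MorphometryError("no subject volumes given")
    arrays, affines, shapes = [], [], []
    for p in paths:
        img = nib.load(str(p))
        arrays.append(np.asanyarray(img.dataobj).astype(float))
        affines.append(img.affine)
        shapes.append(arrays[-1].shape)
    ref = shapes[0]
    for p, s in zip(paths, shapes):
        if s != ref:
            raise MorphometryError(f"geometry mismatch: {paths[0]} has shape {ref}, {p} has shape {s}")
    for p, a in zip(paths, affines):
        if not np.allclose(a, affines[0]):
            raise MorphometryError(f"affine mismatch between {paths[0]} and {p}")
    return np.stack(arrays), affines[0]


def write_stat_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a statistic map (t, d, q, ...) with the geometry of its inputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path
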