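"""Reading, writing and construction of functional brain networks.

A subject enters the pipeline either as regional BOLD time series
(regions x timepoints, delimited text) or as a precomputed symmetric
connectivity matrix.  Time series are turned into a network by Pearson
correlation between every pair of regional signals, followed by Fisher's
r-to-z transform, which stabilises the sampling distribution of the
correlation coefficients.

Conventions fixed here and relied on downstream:

* the diagonal (self-connection) is 0 everywhere — self-loops carry no
  information for random walks and Fisher-z of r=1 is infinite;
* correlations of magnitude 1 are clipped to ``1 - 1e-7`` before the
  r-to-z transform so z stays finite;
* matrix files are plain delimited text (comma or tab, auto-detected),
  no header; manifests are headered CSV ``subject_id,group,path``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSignalError,
    ParseError,
    StateError,
    ValidationError,
)

#: correlations with |r| = 1 are clipped to +/- (1 - FISHER_CLIP_EPS)
FISHER_CLIP_EPS = 1e-7

_SYMMETRY_TOL = 1e-10


@dataclass
class RegionalTimeSeries:
    """Regional BOLD signals for one subject: ``data[i]`` is region i's series."""

    subject_id: str
    data: np.ndarray  # (n_regions, n_timepoints)
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be 2-D (regions x timepoints)")
        n, t = self.data.shape
        if n < 2:
            raise ValidationError(f"need at least 2 regions, got {n}")
        if t < 3:
            raise ValidationError(f"need at least 3 timepoints, got {t}")
        if not np.isfinite(self.data).all():
            raise ValidationError("time-series data contains non-finite values")
        if not self.region_labels:
            self.region_labels = [f"node_{i}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ValidationError("region_labels length does not match n_regions")
        variances = self.data.var(axis=1)
        for i, v in enumerate(variances):
            if v == 0.0:
                raise DegenerateSignalError(
                    f"region '{self.region_labels[i]}' (index {i}) has zero variance"
                )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric n x n functional network with zero diagonal.

    ``is_fisher_z`` distinguishes raw correlation units (off-diagonals in
    [-1, 1]) from r-to-z transformed values (unbounded).
    """

    subject_id: str
    values: np.ndarray
    is_fisher_z: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if not np.isfinite(self.values).all():
            raise ValidationError("connectivity matrix contains non-finite values")
        if np.abs(self.values - self.values.T).max() > _SYMMETRY_TOL:
            raise ValidationError("connectivity matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("diagonal must be exactly 0 (self-loop convention)")
        if not self.is_fisher_z:
            off = self.values[~np.eye(self.values.shape[0], dtype=bool)]
            if off.size and (off.min() < -1.0 or off.max() > 1.0):
                raise ValidationError("correlation values must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectManifest:
    """Cohort table: one row per subject with its group label and file path."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "path"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValidationError("manifest is empty")
        if self.table["subject_id"].duplicated().any():
            dups = self.table.loc[self.table["subject_id"].duplicated(), "subject_id"]
            raise ValidationError(f"duplicate subject_id(s): {sorted(set(dups))}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def groups(self) -> list[str]:
        return list(self.table["group"])

    def validate_two_groups(self) -> tuple[str, str]:
        levels = sorted(set(self.table["group"]))
        if len(levels) != 2:
            raise ValidationError(
                f"classification task needs exactly two group labels, got {levels}"
            )
        return levels[0], levels[1]


def _sniff_delimiter(first_line: str) -> str | None:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None  # whitespace


def _load_delimited(path) -> np.ndarray:
    try:
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not lines:
        raise ParseError(f"{path}: file is empty")
    delim = _sniff_delimiter(lines[0])
    rows = []
    width = None
    for i, ln in enumerate(lines):
        fields = ln.split(delim) if delim else ln.split()
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ParseError(
                f"{path}: ragged row {i} (expected {width} fields, got {len(fields)})"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric field in row {i}: {exc}") from exc
    return np.asarray(rows, dtype=float)


def read_time_series(
    path,
    subject_id: str | None = None,
    orientation: str = "regions_rows",
    region_labels: list[str] | None = None,
) -> RegionalTimeSeries:
    """Read a delimited time-series file.

    ``orientation`` is ``"regions_rows"`` (default: rows are regions) or
    ``"regions_cols"`` (the file is transposed on read).
    """
    if orientation not in ("regions_rows", "regions_cols"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    data = _load_delimited(path)
    if orientation == "regions_cols":
        data = data.T
    sid = subject_id if subject_id is not None else str(path)
    return RegionalTimeSeries(sid, data, region_labels or [])


def pearson_network(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of regional signals; diagonal set to 0."""
    variances = ts.data.var(axis=1)
    for i, v in enumerate(variances):
        if v == 0.0:
            raise DegenerateSignalError(
                f"region '{ts.region_labels[i]}' (index {i}) has zero variance"
            )
    r = np.corrcoef(ts.data)
    # guard against fp drift outside [-1, 1]
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(ts.subject_id, r, is_fisher_z=False)


def fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher's r-to-z transform, z = atanh(r), applied off-diagonal.

    Entries with |r| = 1 are clipped to ``+/-(1 - 1e-7)`` first so the
    transform stays finite.  Raises :class:`StateError` if the matrix is
    already in z units.
    """
    if cm.is_fisher_z:
        raise StateError(f"subject {cm.subject_id!r}: matrix already Fisher-z transformed")
    r = cm.values.copy()
    limit = 1.0 - FISHER_CLIP_EPS
    r = np.clip(r, -limit, limit)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(cm.subject_id, z, is_fisher_z=True)


def connectivity_from_array(
    subject_id: str, values: np.ndarray, is_fisher_z: bool = False
) -> ConnectivityMatrix:
    """Wrap a raw square array, zeroing the diagonal per the package convention."""
    values = np.asarray(values, dtype=float).copy()
    if values.ndim == 2 and values.shape[0] == values.shape[1]:
        np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(subject_id, values, is_fisher_z=is_fisher_z)


def read_matrix(path, subject_id: str | None = None, is_fisher_z: bool = False) -> ConnectivityMatrix:
    """Read a square delimited matrix file as a connectivity matrix."""
    values = _load_delimited(path)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ParseError(f"{path}: expected a square matrix, got shape {values.shape}")
    sid = subject_id if subject_id is not None else str(path)
    return connectivity_from_array(sid, values, is_fisher_z=is_fisher_z)


def write_matrix(values, path) -> None:
    """Write a matrix (or ConnectivityMatrix) as tab-delimited text at full precision."""
    if isinstance(values, ConnectivityMatrix):
        values = values.values
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.17g")


def write_time_series(ts: RegionalTimeSeries, path) -> None:
    """Write a time series as tab-delimited text, rows = regions."""
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.17g")


def read_manifest(path, require_two_groups: bool = True) -> SubjectManifest:
    """Read a headered CSV manifest ``subject_id,group,path``."""
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: manifest is empty") from exc
    manifest = SubjectManifest(table)
    if require_two_groups:
        manifest.validate_two_groups()
    return manifest


def write_manifest(manifest: SubjectManifest, path) -> None:
    manifest.table.to_csv(path, index=False)
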