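"""Core containers and readers/writers for tables and volumes.

Time-series tables are delimited text with time on rows and variables on
columns; an optional single header row carries variable names.  Volumetric
data (4D series, masks, integer label volumes, output maps) use NIfTI-1 via
nibabel.  Voxel columns always follow a fixed first-axis-fastest (Fortran)
linear scan of the grid so that the voxel-to-column mapping is deterministic
and identical across every operation in a run; the scan order and voxel
coordinates are recorded in ``TimeSeriesSet.meta``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad header, wrong shape)."""


@dataclass
class TimeSeriesSet:
    """A T x N block of covariance-stationary signals.

    Rows are time points sampled every ``dt`` seconds (the TR for fMRI
    data), columns are variables (voxels, regions, or simulated series).
    """

    data: np.ndarray
    dt: float = 1.0
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"data must be 2-D (T x N), got shape {self.data.shape}")
        t, n = self.data.shape
        if t < 2:
            raise FormatError(f"need at least 2 time points, got {t}")
        if n < 1:
            raise FormatError("need at least 1 variable")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise FormatError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.labels is None:
            self.labels = [f"v{i + 1}" for i in range(n)]
        else:
            self.labels = [str(s) for s in self.labels]
        if len(self.labels) != n:
            raise FormatError(
                f"{len(self.labels)} labels for {n} columns"
            )
        if len(set(self.labels)) != n:
            raise FormatError("labels must be unique")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_vars(self) -> int:
        return self.data.shape[1]

    def column(self, idx: int) -> np.ndarray:
        return self.data[:, idx]

    def replace(self, data: np.ndarray, **meta_updates) -> "TimeSeriesSet":
        """New set with the same dt/labels but different data."""
        meta = {**self.meta, **meta_updates}
        return TimeSeriesSet(data=data, dt=self.dt, labels=list(self.labels), meta=meta)


@dataclass
class VolumeMask:
    """Boolean 3-D mask plus its voxel-to-world affine."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {self.grid.ndim}-D")
        if not self.grid.any():
            raise FormatError("mask contains no voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def flat_indices(self) -> np.ndarray:
        """Linear indices of mask voxels in first-axis-fastest order."""
        return np.flatnonzero(self.grid.ravel(order="F"))


@dataclass
class LabelVolume:
    """Integer parcellation volume (0 = background), AAL-style."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError("label volume must be 3-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            as_int = self.grid.astype(int)
            if not np.array_equal(as_int, self.grid):
                raise FormatError("labels must be integers")
            self.grid = as_int
        if (self.grid < 0).any():
            raise FormatError("labels must be nonnegative")
        self.affine = np.asarray(self.affine, dtype=float)


@dataclass
class RunConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow the study conditions this package reproduces: AR model
    order 1, ten conditioning variables for the data-driven selection, a
    0.3 edge-weight threshold for binary graphs, 27-voxel minimum cluster
    extent, 0.5 mm scrubbing threshold and the 0.01-0.08 Hz band.
    """

    p: int = 1
    n_d: int = 10
    alpha: float = 0.05
    weight_threshold: float = 0.3
    louvain_restarts: int = 10_000
    min_cluster_voxels: int = 27
    fd_threshold_mm: float = 0.5
    band: tuple[float, float] = (0.01, 0.08)
    seed: int = 0
    # preprocessing extras
    head_radius_mm: float = 50.0
    filter_order: int = 2
    # deconvolution extras
    event_threshold_sd: float = 1.0
    hrf_duration_s: float = 32.0
    wiener_lambda: float | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("model order p must be >= 1")
        if self.n_d < 1:
            raise ValueError("n_d must be >= 1")
        for name in ("alpha", "weight_threshold", "fd_threshold_mm", "head_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.louvain_restarts < 1 or self.min_cluster_voxels < 1:
            raise ValueError("restart/cluster counts must be >= 1")
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise ValueError(f"band must satisfy 0 <= low < high, got {self.band}")

    def with_overrides(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# delimited tables


def _parse_cell(tok: str, row: int, col: int) -> float:
    try:
        val = float(tok)
    except ValueError:
        raise FormatError(
            f"non-numeric value {tok!r} at row {row}, column {col}"
        ) from None
    if not np.isfinite(val):
        raise FormatError(f"non-finite value {tok!r} at row {row}, column {col}")
    return val


def read_timeseries_table(
    path: str | Path, delimiter: str = ",", dt: float = 1.0
) -> TimeSeriesSet:
    """Read a delimited numeric table (time on rows, variables on columns).

    A single non-numeric first row is treated as a header of labels.  Ragged
    rows and non-numeric or non-finite body cells raise :class:`FormatError`
    naming the offending cell.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path} is empty")
    rows = [ln.split(delimiter) for ln in lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"ragged table: row {i} has {len(r)} fields, expected {width}"
            )
    labels = None
    body_start = 0
    try:
        [float(tok) for tok in rows[0]]
    except ValueError:
        labels = [tok.strip() for tok in rows[0]]
        body_start = 1
    body = rows[body_start:]
    data = np.empty((len(body), width))
    for i, r in enumerate(body):
        for j, tok in enumerate(r):
            data[i, j] = _parse_cell(tok.strip(), i + body_start, j)
    return TimeSeriesSet(
        data=data, dt=dt, labels=labels, meta={"source": str(path)}
    )


def write_timeseries_table(
    ts: TimeSeriesSet, path: str | Path, delimiter: str = ",", header: bool = True
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(delimiter.join(ts.labels) + "\n")
        for row in ts.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_motion_params(path: str | Path, delimiter: str | None = None) -> np.ndarray:
    """Read a T x 6 rigid-body motion table (3 translations mm, 3 rotations rad)."""
    table = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if table.shape[1] < 6:
        raise FormatError(
            f"motion table needs 6 columns, got {table.shape[1]}"
        )
    return table[:, :6]


# ---------------------------------------------------------------------------
# volumes


def load_mask(path: str | Path) -> VolumeMask:
    img = nib.load(str(path))
    return VolumeMask(grid=np.asarray(img.dataobj) > 0, affine=img.affine)


def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(grid=np.rint(np.asarray(img.dataobj)).astype(int), affine=img.affine)


def read_volume_series(
    path_4d: str | Path | nib.Nifti1Image,
    mask: VolumeMask,
    dt: float | None = None,
) -> TimeSeriesSet:
    """Extract one column per mask voxel from a 4-D NIfTI image.

    Column order is the fixed first-axis-fastest linear scan of the grid.
    ``dt`` is read from the image time-step header field unless given
    explicitly; a missing/zero header time step without an explicit ``dt``
    is an error.
    """
    img = path_4d if isinstance(path_4d, nib.spatialimages.SpatialImage) else nib.load(str(path_4d))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got {data.ndim}-D")
    if data.shape[:3] != mask.grid.shape:
        raise FormatError(
            f"image spatial shape {data.shape[:3]} != mask shape {mask.grid.shape}"
        )
    if dt is None:
        zooms = img.header.get_zooms()
        dt = float(zooms[3]) if len(zooms) > 3 else 0.0
        if dt <= 0:
            raise ValueError(
                "image header has no usable time step; pass dt explicitly"
            )
    t = data.shape[3]
    flat = mask.flat_indices()
    series = data.reshape(-1, t, order="F")[flat].T  # T x N
    ii, jj, kk = np.unravel_index(flat, mask.grid.shape, order="F")
    meta = {
        "voxel_coords": np.stack([ii, jj, kk], axis=1),
        "scan_order": "first-axis-fastest (Fortran)",
        "affine": np.asarray(img.affine),
    }
    return TimeSeriesSet(data=series, dt=dt, labels=[f"vox{i}" for i in range(len(flat))], meta=meta)


def write_voxel_map(
    values: np.ndarray, mask: VolumeMask, path: str | Path | None = None
) -> nib.Nifti1Image:
    """Scatter one value per mask voxel back into a 3-D volume (0 elsewhere)."""
    values = np.asarray(values, dtype=float).ravel()
    flat = mask.flat_indices()
    if values.size != flat.size:
        raise FormatError(
            f"{values.size} values for {flat.size} mask voxels"
        )
    vol = np.zeros(mask.grid.size)
    vol[flat] = values
    vol = vol.reshape(mask.grid.shape, order="F")
    img = nib.Nifti1Image(vol, mask.affine)
    if path is not None:
        nib.save(img, str(path))
    return img
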