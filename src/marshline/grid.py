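"""Raster grid container, ESRI ASCII grid I/O, and alignment checks.

All grids in this package share one convention: row 0 is the northernmost
row, cell (0, 0) sits in the northwest corner, and cell centers carry the
coordinates. Coordinates are projected (UTM-style easting/northing in
metres); no reprojection is attempted. The ESRI ASCII grid format is used
for on-disk rasters because it is plain text and universally readable by
GIS software.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Land-cover codes shared across the package.
WATER = 0
WETLAND = 1

#: Default NODATA sentinel for both continuous and categorical grids.
NODATA = -9999.0


@dataclass(frozen=True)
class GridMeta:
    """Geometry and metadata of a raster grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (must be positive).
    cell_size : float
        Cell edge length in metres (square cells).
    xll, yll : float
        Easting/northing of the lower-left *corner* of the grid, metres.
    nodata : float
        Sentinel marking missing cells; must not collide with valid data.
    crs : str
        Free-text tag; coordinates are assumed to be in one projected,
        UTM-style system.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 2.0
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = NODATA
    crs: str = "local-utm"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (easting, northing) arrays of cell-center coordinates.

        Row 0 is north, so northing decreases with row index.
        """
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        easting = self.xll + (cols + 0.5) * self.cell_size
        northing = self.yll + (self.n_rows - rows - 0.5) * self.cell_size
        return np.broadcast_arrays(easting[None, :], northing[:, None])


@dataclass
class Grid:
    """A 2-D raster: a numpy array plus its :class:`GridMeta`."""

    data: np.ndarray
    meta: GridMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.meta.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match meta {self.meta.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data != self.meta.nodata

    def with_data(self, data: np.ndarray) -> "Grid":
        return Grid(np.asarray(data), self.meta)


@dataclass(frozen=True)
class AlignmentReport:
    """Structured diagnostic from :func:`check_alignment`."""

    ok: bool
    mismatch: str | None = None
    detail: str = ""


def check_alignment(*grids: Grid,
                    cell_tol: float = 1e-6,
                    origin_tol: float = 1e-3) -> AlignmentReport:
    """Verify that grids share shape, cell size, and origin.

    Returns a diagnostic naming the first mismatching property rather than
    raising, so batch pipelines can report all inputs before aborting.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare")
    ref = grids[0].meta
    for i, g in enumerate(grids[1:], start=1):
        m = g.meta
        if m.shape != ref.shape:
            return AlignmentReport(False, "shape",
                                   f"grid 0 is {ref.shape}, grid {i} is {m.shape}")
        if abs(m.cell_size - ref.cell_size) > cell_tol:
            return AlignmentReport(False, "cell_size",
                                   f"{ref.cell_size} vs {m.cell_size}")
        if abs(m.xll - ref.xll) > origin_tol or abs(m.yll - ref.yll) > origin_tol:
            return AlignmentReport(
                False, "origin",
                f"({ref.xll}, {ref.yll}) vs ({m.xll}, {m.yll})")
    return AlignmentReport(True)


def require_aligned(*grids: Grid) -> None:
    """Raise ``ValueError`` if grids are misaligned (thin wrapper)."""
    report = check_alignment(*grids)
    if not report.ok:
        raise ValueError(f"misaligned grids: {report.mismatch} ({report.detail})")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_grid(grid: Grid, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write a grid as an ESRI ASCII (.asc) raster."""
    path = Path(path)
    m = grid.meta
    header = (
        f"ncols {m.n_cols}\n"
        f"nrows {m.n_rows}\n"
        f"xllcorner {m.xll!r}\n"
        f"yllcorner {m.yll!r}\n"
        f"cellsize {m.cell_size!r}\n"
        f"NODATA_value {m.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.asarray(grid.data, dtype=float), fmt=fmt)
    return path


def read_grid(path: str | Path,
              expected_kind: str = "continuous",
              classes: tuple[int, ...] | None = None) -> Grid:
    """Read an ESRI ASCII grid.

    Parameters
    ----------
    path
        File to read; must be an ESRI ASCII grid (``ncols``/``nrows`` header).
    expected_kind
        ``"continuous"`` (float values) or ``"categorical"`` (integer
        classes; values are validated against ``classes`` when given).
    classes
        Permitted class values for categorical grids, NODATA excluded.
    """
    if expected_kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown expected_kind {expected_kind!r}")
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0].lower().lstrip("-").replace(
                    "_", "").isalpha():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        if "ncols" not in header or "nrows" not in header:
            raise ValueError(f"{path} is not an ESRI ASCII grid")
        data = np.loadtxt(fh, ndmin=2)
    meta = GridMeta(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=float(header.get("cellsize", 1.0)),
        xll=float(header.get("xllcorner", 0.0)),
        yll=float(header.get("yllcorner", 0.0)),
        nodata=float(header.get("nodata_value", NODATA)),
    )
    if data.shape != meta.shape:
        raise ValueError(f"{path}: body shape {data.shape} != header {meta.shape}")
    if expected_kind == "categorical":
        ints = np.rint(data)
        if not np.array_equal(ints, data):
            raise ValueError(f"{path}: non-integer values in categorical grid")
        data = ints.astype(int)
        meta = dataclasses.replace(meta, nodata=float(int(meta.nodata)))
        if classes is not None:
            valid = data != int(meta.nodata)
            bad = np.setdiff1d(np.unique(data[valid]), np.asarray(classes))
            if bad.size:
                raise ValueError(
                    f"{path}: values {bad.tolist()} outside class set {classes}")
    return Grid(data, meta)


def regrid_nearest(src: Grid, target: GridMeta) -> Grid:
    """Nearest-neighbor resampling of ``src`` onto ``target`` geometry.

    Intended for class rasters delivered on a slightly different grid than
    the simulation (e.g. digitized knowledge-assessment maps); cells whose
    centers fall outside the source extent become NODATA.
    """
    te, tn = target.cell_centers()
    s = src.meta
    col = np.floor((te - s.xll) / s.cell_size).astype(int)
    row = np.floor((s.yll + s.n_rows * s.cell_size - tn) / s.cell_size).astype(int)
    inside = (col >= 0) & (col < s.n_cols) & (row >= 0) & (row < s.n_rows)
    out = np.full(target.shape, target.nodata, dtype=np.asarray(src.data).dtype)
    out[inside] = np.asarray(src.data)[row[inside], col[inside]]
    return Grid(out, target)
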