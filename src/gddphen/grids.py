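"""Lightweight regular lat/lon rasters with plain-text (ESRI ASCII) I/O.

A :class:`GridGeoref` describes a regular geographic grid in the ESRI
ASCII-grid convention: the grid origin is the lower-left *corner*, cells are
square in degrees, and data rows run north to south (row 0 is the
northernmost row).  Cell values are floats with NaN as the missing marker.

No installed package in this stack reads ESRI ASCII grids, so the (tiny)
format is implemented here; it is the package's on-disk raster format for
both fixtures and outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, FormatError

NODATA = -9999.0


@dataclass(frozen=True)
class GridGeoref:
    """Georeferencing of a regular lat/lon grid (ESRI ASCII convention)."""

    nrows: int
    ncols: int
    xllcorner: float  # longitude of the lower-left corner, degrees
    yllcorner: float  # latitude of the lower-left corner, degrees
    cellsize: float   # degrees

    def __post_init__(self):
        if self.cellsize <= 0:
            raise FormatError("cellsize must be positive")
        if self.nrows <= 0 or self.ncols <= 0:
            raise FormatError("grid must have positive dimensions")

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 = northernmost."""
        top = self.yllcorner + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    @property
    def lon_centers(self) -> np.ndarray:
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def cell_of(self, latitude: float, longitude: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside."""
        col = int(np.floor((longitude - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((latitude - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def matches(self, other: "GridGeoref") -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )


@dataclass
class Grid:
    """A single-band float raster; NaN marks missing cells."""

    georef: GridGeoref
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.georef.nrows, self.georef.ncols):
            raise AlignmentError(
                f"data shape {self.data.shape} does not match georef "
                f"({self.georef.nrows}, {self.georef.ncols})"
            )

    def value_at(self, latitude: float, longitude: float) -> float | None:
        """Cell value at a point; None if the point is outside the grid."""
        cell = self.georef.cell_of(latitude, longitude)
        if cell is None:
            return None
        return float(self.data[cell])


@dataclass
class RangeMask:
    """Boolean species-range grid aligned to a temperature grid."""

    georef: GridGeoref
    mask: np.ndarray = field(repr=False)
    species: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.georef.nrows, self.georef.ncols):
            raise AlignmentError(
                f"mask shape {self.mask.shape} does not match georef "
                f"({self.georef.nrows}, {self.georef.ncols})"
            )


@dataclass
class TemperatureStack:
    """Gridded daily tmin/tmax (°C) for one calendar year.

    Arrays are (days, rows, cols); day 0 is Jan 1.  NaN marks cells with
    missing temperature data.
    """

    georef: GridGeoref
    year: int
    tmin: np.ndarray = field(repr=False)
    tmax: np.ndarray = field(repr=False)

    def __post_init__(self):
        from calendar import isleap

        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        expected = 366 if isleap(self.year) else 365
        n_days = self.tmin.shape[0] if self.tmin.ndim == 3 else -1
        # a stack shorter than the year is a partial/forecast window from Jan 1
        if not 1 <= n_days <= expected:
            raise AlignmentError(
                f"stack needs 1..{expected} days for {self.year}, got {n_days}"
            )
        shape = (n_days, self.georef.nrows, self.georef.ncols)
        if self.tmin.shape != shape or self.tmax.shape != shape:
            raise AlignmentError(
                f"stack arrays must have shape {shape}, got "
                f"{self.tmin.shape}/{self.tmax.shape}"
            )
        both = np.isfinite(self.tmin) & np.isfinite(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise FormatError(f"tmax < tmin in stack for year {self.year}")

    @property
    def tmean(self) -> np.ndarray:
        return (self.tmin + self.tmax) / 2.0

    def save_npz(self, path) -> None:
        g = self.georef
        np.savez_compressed(
            path, tmin=self.tmin, tmax=self.tmax, year=self.year,
            georef=np.array([g.nrows, g.ncols, g.xllcorner, g.yllcorner,
                             g.cellsize]),
        )

    @classmethod
    def load_npz(cls, path) -> "TemperatureStack":
        with np.load(path) as z:
            nrows, ncols, xll, yll, cs = z["georef"]
            return cls(
                georef=GridGeoref(int(nrows), int(ncols), float(xll),
                                  float(yll), float(cs)),
                year=int(z["year"]),
                tmin=z["tmin"],
                tmax=z["tmax"],
            )


def require_aligned(a: GridGeoref, b: GridGeoref) -> None:
    if not a.matches(b):
        raise AlignmentError(f"grids are not aligned: {a} vs {b}")


def write_ascii_grid(grid: Grid, path) -> None:
    """Write in ESRI ASCII-grid format (NaN -> NODATA_value)."""
    g = grid.georef
    data = np.where(np.isfinite(grid.data), grid.data, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xllcorner!r}\n")
        fh.write(f"yllcorner {g.yllcorner!r}\n")
        fh.write(f"cellsize {g.cellsize!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    missing = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"} - header.keys()
    if missing:
        raise FormatError(f"ASCII grid header missing: {sorted(missing)}")
    georef = GridGeoref(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    data = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return Grid(georef=georef, data=data)
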