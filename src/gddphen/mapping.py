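"""Threshold-crossing day-of-year maps from gridded daily temperatures.

Running a fitted threshold over a daily temperature stack yields, per cell,
the first DOY on which the accumulated growing degree days reach the
threshold — a real-time or forecast map of the predicted phenophase
transition.  The standard production workflow clips that map twice: first to
the species' geographic range (predictions outside it are meaningless), then
to the climate-envelope subset of the range where the model is considered
extensible.

Two sentinels are distinct in the integer output raster: ``NOT_MET`` (the
threshold is never reached that year) and ``NODATA`` (missing temperature
input or clipped away).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import Grid, GridGeoref, RangeMask, TemperatureStack, require_aligned
from .thermal_time import ThermalTimeModel

logger = logging.getLogger(__name__)

NOT_MET = -1
NODATA = -9999


@dataclass
class DoyMap:
    """Integer grid of threshold-crossing DOYs with sentinel cells."""

    georef: GridGeoref
    data: np.ndarray = field(repr=False)
    year: int = 0
    model_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=int)
        if self.data.shape != (self.georef.nrows, self.georef.ncols):
            from .errors import AlignmentError

            raise AlignmentError("DoyMap data shape does not match georef")

    @property
    def met(self) -> np.ndarray:
        return self.data > 0

    def min_max_doy(self) -> tuple[int, int] | None:
        """(min, max) DOY over met cells, or None if nothing met."""
        if not self.met.any():
            return None
        vals = self.data[self.met]
        return int(vals.min()), int(vals.max())


def threshold_doy_map(stack: TemperatureStack, model: ThermalTimeModel) -> DoyMap:
    """Per cell, the first DOY whose AGDD reaches the model threshold.

    Cells with any missing temperature day are NODATA; cells whose year-end
    AGDD stays below the threshold are NOT_MET.
    """
    gdd = np.maximum(0.0, stack.tmean - model.base_temp)
    agdd = np.cumsum(gdd, axis=0)
    threshold = model.threshold_agdd

    valid = np.isfinite(agdd[-1])
    if threshold <= 0:
        data = np.where(valid, 1, NODATA)
    else:
        met = agdd[-1] >= threshold
        # argmax finds the first crossing along the day axis
        first = np.argmax(agdd >= threshold, axis=0) + 1
        data = np.where(valid & met, first, NOT_MET)
        data = np.where(valid, data, NODATA)
    return DoyMap(
        georef=stack.georef,
        data=data.astype(int),
        year=stack.year,
        model_id=f"{model.species}/{model.phenophase}",
    )


def clip_map(doy_map: DoyMap, mask: RangeMask) -> DoyMap:
    """Set cells outside the mask to NODATA.

    Applied twice in the standard workflow: to the species range, then to
    the envelope-clipped range.
    """
    require_aligned(doy_map.georef, mask.georef)
    data = np.where(mask.mask, doy_map.data, NODATA)
    return DoyMap(georef=doy_map.georef, data=data,
                  year=doy_map.year, model_id=doy_map.model_id)


def write_doy_map_ascii(doy_map: DoyMap, path) -> None:
    """Write the map as an ESRI ASCII grid (integer values, NODATA=-9999)."""
    from .grids import write_ascii_grid

    grid = Grid(georef=doy_map.georef,
                data=np.where(doy_map.data == NODATA, np.nan,
                              doy_map.data.astype(float)))
    write_ascii_grid(grid, path)


def read_doy_map_ascii(path) -> DoyMap:
    from .grids import read_ascii_grid

    grid = read_ascii_grid(path)
    data = np.where(np.isfinite(grid.data), grid.data, NODATA)
    return DoyMap(georef=grid.georef, data=data.astype(int))


def write_doy_map_png(doy_map: DoyMap, path, title: str = "") -> None:
    """PNG quicklook: met cells on a continuous DOY ramp, sentinels blanked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(doy_map.met, doy_map.data.astype(float), np.nan)
    g = doy_map.georef
    extent = [g.xllcorner, g.xllcorner + g.ncols * g.cellsize,
              g.yllcorner, g.yllcorner + g.nrows * g.cellsize]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(shown, origin="upper", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax, label="DOY threshold met")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title or doy_map.model_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
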