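"""Climate-envelope assessment of where a model can be extended.

A fitted threshold is only trusted in climates the calibration points
sampled.  Spring (January-April, "JFMA") mean temperature serves as the
proxy climate axis: it correlates strongly with the accumulated-heat
variable driving the models.  The *climate envelope* is the closed interval
[min, max] of long-term spring temperature at the calibration sites; the
species range raster is clipped to cells whose spring temperature lies in
that interval, and geographic extensibility is the (area-weighted) percent
of the range retained.
"""

from __future__ import annotations

import json
import logging
from calendar import monthrange
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape

from .errors import (
    AlignmentError,
    DataCompletenessError,
    EmptyEnvelopeError,
    InputError,
)
from .grids import Grid, GridGeoref, RangeMask, TemperatureStack, require_aligned

logger = logging.getLogger(__name__)

SPRING_MONTHS = (1, 2, 3, 4)


@dataclass(frozen=True)
class ClimateEnvelope:
    """Min/max spring temperature (°C) over the calibration points."""

    t_min: float
    t_max: float
    n_points: int

    def __post_init__(self):
        if self.t_min > self.t_max:
            raise InputError("envelope t_min exceeds t_max")

    def to_dict(self) -> dict:
        return {"t_min": float(self.t_min), "t_max": float(self.t_max),
                "n_points": int(self.n_points)}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ClimateEnvelope":
        with open(path) as fh:
            d = json.load(fh)
        return cls(t_min=d["t_min"], t_max=d["t_max"], n_points=d["n_points"])


def _month_slices(year: int) -> dict[int, slice]:
    """Day-index slices (0-based from Jan 1) for each calendar month."""
    out, start = {}, 0
    for month in range(1, 13):
        ndays = monthrange(year, month)[1]
        out[month] = slice(start, start + ndays)
        start += ndays
    return out


def spring_climatology(stacks: dict[int, TemperatureStack]) -> Grid:
    """Long-term mean Jan-Apr temperature grid from daily stacks.

    Per cell and year: the mean of the four monthly means of daily
    (tmin+tmax)/2; years are then averaged.  A stack that does not cover
    January through April raises a completeness error.  Cells missing in any
    contributing day propagate as missing.
    """
    if not stacks:
        raise InputError("no stacks supplied")
    georef = None
    yearly = []
    for year, stack in sorted(stacks.items()):
        if georef is None:
            georef = stack.georef
        else:
            require_aligned(georef, stack.georef)
        slices = _month_slices(year)
        needed = slices[SPRING_MONTHS[-1]].stop
        if stack.tmean.shape[0] < needed:
            raise DataCompletenessError(
                f"stack for {year} does not cover January-April"
            )
        monthly = [stack.tmean[slices[m]].mean(axis=0) for m in SPRING_MONTHS]
        yearly.append(np.mean(monthly, axis=0))
    return Grid(georef=georef, data=np.mean(yearly, axis=0))


def envelope_from_points(
    grid: Grid, sites: pd.DataFrame
) -> tuple[ClimateEnvelope, list[str]]:
    """Envelope [min, max] of the grid values at calibration sites.

    Extraction takes the value of the cell containing each point.  Sites
    outside the grid or on missing cells are listed in the rejects (not
    fatal); if every site is rejected the envelope is empty and an error is
    raised.
    """
    values, rejects = [], []
    for r in sites.itertuples():
        v = grid.value_at(r.latitude, r.longitude)
        if v is None or not np.isfinite(v):
            rejects.append(str(r.site_id))
        else:
            values.append(v)
    if not values:
        raise EmptyEnvelopeError(
            f"no calibration point yielded a spring value ({len(rejects)} rejected)"
        )
    if rejects:
        logger.warning("%d calibration site(s) fell outside the spring grid "
                       "or on missing cells", len(rejects))
    return (
        ClimateEnvelope(t_min=float(min(values)), t_max=float(max(values)),
                        n_points=len(values)),
        rejects,
    )


def clip_range_to_envelope(
    range_mask: RangeMask, grid: Grid, env: ClimateEnvelope
) -> RangeMask:
    """Retain range cells whose spring value lies in [t_min, t_max] (inclusive)."""
    require_aligned(range_mask.georef, grid.georef)
    inside = (
        np.isfinite(grid.data)
        & (grid.data >= env.t_min)
        & (grid.data <= env.t_max)
    )
    return RangeMask(georef=range_mask.georef,
                     mask=range_mask.mask & inside,
                     species=range_mask.species)


def percent_range_covered(
    clipped: RangeMask, full: RangeMask, area_weighted: bool = True
) -> float:
    """Percent of the full range retained after envelope clipping.

    Cell areas on a regular lat/lon grid scale with cos(latitude); the
    default weights cells accordingly.  ``area_weighted=False`` uses raw
    cell counts (useful for brute-force cross-checks).
    """
    require_aligned(clipped.georef, full.georef)
    if np.any(clipped.mask & ~full.mask):
        raise InputError("clipped mask is not a subset of the full mask")
    if not full.mask.any():
        raise InputError("full range mask is empty")
    if area_weighted:
        w = np.cos(np.deg2rad(full.georef.lat_centers))[:, None]
        w = np.broadcast_to(w, full.mask.shape)
        return float(100.0 * w[clipped.mask].sum() / w[full.mask].sum())
    return float(100.0 * clipped.mask.sum() / full.mask.sum())


def load_range_geojson(path_or_obj, species: str = "") -> shapely.Geometry:
    """Load a species-range polygon from GeoJSON (WGS84 lon/lat)."""
    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in obj["features"]]
        return shapely.union_all(geoms)
    if obj.get("type") == "Feature":
        return _geojson_shape(obj["geometry"])
    return _geojson_shape(obj)


def rasterize_range(
    geometry: shapely.Geometry, georef: GridGeoref, species: str = ""
) -> RangeMask:
    """Rasterize a polygon onto a grid with center-in-polygon membership."""
    lons, lats = np.meshgrid(georef.lon_centers, georef.lat_centers)
    inside = shapely.contains_xy(geometry, lons.ravel(), lats.ravel())
    return RangeMask(georef=georef,
                     mask=inside.reshape(georef.nrows, georef.ncols),
                     species=species)
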