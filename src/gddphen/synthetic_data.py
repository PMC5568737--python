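"""Synthetic phenology world with known ground truth.

The generator emulates the observation process behind a continental
status-data network: sites scattered along a latitudinal climate gradient,
per-site daily temperatures (sinusoidal seasonal cycle plus AR(1) noise and
a diurnal half-range), species whose true onset at a site is the day a known
AGDD threshold is crossed, individual plants jittered around the site onset,
and observers who visit every ``visit_interval`` days from a random phase —
so the prior-"no"/first-"yes" interval has controllable width.  Because the
true thresholds and onsets are known, every pipeline stage can be verified
by parameter recovery.

All randomness flows from a single :func:`numpy.random.default_rng` seeded
once per run; the same config and seed reproduce the same world exactly.
"""

from __future__ import annotations

import logging
from calendar import isleap
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .extensibility import rasterize_range, spring_climatology
from .grids import Grid, GridGeoref, RangeMask, TemperatureStack
from .thermal_time import TemperatureSeries, doy_threshold_met

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesSpec:
    """A synthetic species x phenophase with its true AGDD threshold."""

    species: str
    phenophase: str
    true_threshold_agdd: float


#: Default trio of synthetic species; thresholds span the range observed for
#: real temperate shrubs and trees (~450-1300 °C·day above a 0 °C base).
DEFAULT_SPECIES = (
    SpeciesSpec("synthspecies_early", "breaking_leaf_buds", 450.0),
    SpeciesSpec("synthspecies_mid", "leaves", 700.0),
    SpeciesSpec("synthspecies_late", "open_flowers", 1300.0),
)


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for the synthetic world.

    Temperature model per site/cell: daily mean
    ``T(d) = (intercept + lat_slope * lat) - amplitude * cos(2*pi*(d-1)/365.25)
    + AR(1) noise``, with tmin/tmax = T -/+ ``diurnal_half_range``.  The
    defaults give mean annual temperatures of ~13 °C at 30° N falling to
    ~4 °C at 48° N, a 24 °C seasonal swing, and day-to-day noise with 2 °C
    stationary sd and lag-1 autocorrelation 0.7 — a caricature of eastern
    North American climate adequate for exercising the method.
    """

    n_sites: int = 50
    lat_min: float = 30.0
    lat_max: float = 48.0
    lon_min: float = -95.0
    lon_max: float = -75.0
    intercept: float = 28.0          # °C at latitude 0
    lat_slope: float = -0.5          # °C per degree latitude
    seasonal_amplitude: float = 12.0  # °C, coldest at Jan 1
    noise_sd: float = 2.0            # stationary sd of AR(1) noise, °C
    ar1_coef: float = 0.7
    diurnal_half_range: float = 5.0  # °C
    species: tuple = DEFAULT_SPECIES
    individuals_per_site: int = 3
    onset_jitter_sd: float = 2.0     # days
    visit_interval: int = 7          # days
    visit_phase: str = "random"      # "random" or "fixed"
    years: tuple = (2011, 2012, 2013, 2014, 2015, 2016)
    # grid covering and extending poleward/equatorward of the site band
    grid_lat_min: float = 27.0
    grid_lat_max: float = 51.0
    grid_lon_min: float = -96.0
    grid_lon_max: float = -74.0
    cellsize: float = 1.0
    # rectangular species range; reaches poleward of the coldest site
    range_lat_min: float = 28.0
    range_lat_max: float = 50.0
    range_lon_min: float = -94.0
    range_lon_max: float = -76.0
    make_grids: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.onset_jitter_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.visit_interval < 1:
            raise ConfigurationError("visit_interval must be >= 1")
        if any(s.true_threshold_agdd <= 0 for s in self.species):
            raise ConfigurationError("true thresholds must be positive")
        if self.visit_phase not in ("random", "fixed"):
            raise ConfigurationError("visit_phase must be 'random' or 'fixed'")
        if not -1 < self.ar1_coef < 1:
            raise ConfigurationError("ar1_coef must lie in (-1, 1)")


@dataclass
class World:
    """Everything generate_world produces, plus the live RNG."""

    config: WorldConfig
    sites: pd.DataFrame
    temps: dict          # (site_id, year) -> TemperatureSeries
    stacks: dict         # year -> TemperatureStack (empty if make_grids=False)
    spring: Grid | None
    range_mask: RangeMask | None
    range_geojson: dict | None
    rng: np.random.Generator = field(repr=False, default=None)


def _ar1_noise(rng: np.random.Generator, n_days: int, shape: tuple,
               sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise, (n_days, *shape), marginal sd = ``sd``."""
    if sd == 0:
        return np.zeros((n_days, *shape))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    out = np.empty((n_days, *shape))
    out[0] = rng.normal(0.0, sd, size=shape)
    shocks = rng.normal(0.0, innov_sd, size=(n_days - 1, *shape))
    for d in range(1, n_days):
        out[d] = phi * out[d - 1] + shocks[d - 1]
    return out


def _daily_tmean(lat: np.ndarray, n_days: int, cfg: WorldConfig) -> np.ndarray:
    """Deterministic seasonal cycle, (n_days, *lat.shape)."""
    d = np.arange(1, n_days + 1)
    seasonal = -cfg.seasonal_amplitude * np.cos(2 * np.pi * (d - 1) / 365.25)
    base = cfg.intercept + cfg.lat_slope * np.asarray(lat, dtype=float)
    return seasonal.reshape((n_days,) + (1,) * base.ndim) + base


def generate_world(config: WorldConfig) -> World:
    """Sites, per-site daily temperatures, gridded stacks, spring grid, range."""
    rng = np.random.default_rng(config.seed)

    lats = rng.uniform(config.lat_min, config.lat_max, config.n_sites)
    lons = rng.uniform(config.lon_min, config.lon_max, config.n_sites)
    sites = pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(config.n_sites)],
            "latitude": lats,
            "longitude": lons,
            "region": "",
        }
    )

    temps: dict = {}
    for year in config.years:
        n_days = 366 if isleap(year) else 365
        tmean = _daily_tmean(lats, n_days, config)  # (days, n_sites)
        tmean = tmean + _ar1_noise(rng, n_days, (config.n_sites,),
                                   config.noise_sd, config.ar1_coef)
        for i, sid in enumerate(sites["site_id"]):
            temps[(sid, year)] = TemperatureSeries(
                site_id=sid, year=year,
                tmin=tmean[:, i] - config.diurnal_half_range,
                tmax=tmean[:, i] + config.diurnal_half_range,
            )

    stacks: dict = {}
    spring = range_mask = range_geojson = None
    if config.make_grids:
        nrows = int(round((config.grid_lat_max - config.grid_lat_min)
                          / config.cellsize))
        ncols = int(round((config.grid_lon_max - config.grid_lon_min)
                          / config.cellsize))
        georef = GridGeoref(nrows=nrows, ncols=ncols,
                            xllcorner=config.grid_lon_min,
                            yllcorner=config.grid_lat_min,
                            cellsize=config.cellsize)
        cell_lats = np.broadcast_to(georef.lat_centers[:, None], (nrows, ncols))
        for year in config.years:
            n_days = 366 if isleap(year) else 365
            tmean = _daily_tmean(cell_lats, n_days, config)
            tmean = tmean + _ar1_noise(rng, n_days, (nrows, ncols),
                                       config.noise_sd, config.ar1_coef)
            stacks[year] = TemperatureStack(
                georef=georef, year=year,
                tmin=tmean - config.diurnal_half_range,
                tmax=tmean + config.diurnal_half_range,
            )
        spring = spring_climatology(stacks)
        range_geojson = {
            "type": "Polygon",
            "coordinates": [[
                [config.range_lon_min, config.range_lat_min],
                [config.range_lon_max, config.range_lat_min],
                [config.range_lon_max, config.range_lat_max],
                [config.range_lon_min, config.range_lat_max],
                [config.range_lon_min, config.range_lat_min],
            ]],
        }
        from .extensibility import load_range_geojson

        geometry = load_range_geojson(range_geojson)
        range_mask = rasterize_range(geometry, georef, species="synthetic")

    return World(config=config, sites=sites, temps=temps, stacks=stacks,
                 spring=spring, range_mask=range_mask,
                 range_geojson=range_geojson, rng=rng)


def generate_true_onsets(world: World, species: SpeciesSpec | None = None
                         ) -> pd.DataFrame:
    """Ground-truth onset DOYs per site x species x year x individual.

    The site-level true onset is the day the site's AGDD crosses the
    species' true threshold; each individual's onset adds rounded Gaussian
    jitter clamped to the year.  Sites where the threshold is never met get
    ``true_onset_doy`` = NaN.
    """
    cfg = world.config
    specs = [species] if species is not None else list(cfg.species)
    rows = []
    for spec in specs:
        for (sid, year), series in world.temps.items():
            site_onset = doy_threshold_met(series, spec.true_threshold_agdd)
            n_days = len(series)
            for k in range(cfg.individuals_per_site):
                iid = f"{sid}_{spec.species}_{k}"
                if site_onset is None:
                    onset = np.nan
                else:
                    jitter = (
                        int(round(world.rng.normal(0.0, cfg.onset_jitter_sd)))
                        if cfg.onset_jitter_sd > 0 else 0
                    )
                    onset = float(np.clip(site_onset + jitter, 1, n_days))
                rows.append(
                    {
                        "site_id": sid,
                        "species": spec.species,
                        "phenophase": spec.phenophase,
                        "year": year,
                        "individual_id": iid,
                        "site_onset_doy": (float(site_onset)
                                           if site_onset is not None else np.nan),
                        "true_onset_doy": onset,
                    }
                )
    return pd.DataFrame(rows)


def generate_observations(truth: pd.DataFrame, world: World) -> pd.DataFrame:
    """Status records from periodic observer visits.

    Each individual is visited every ``visit_interval`` days starting from a
    per-individual-year phase drawn uniformly from 1..visit_interval (or
    fixed at 1), through year end.  A visit reports "yes" iff its DOY is on
    or after the individual's true onset, so the prior-"no"/first-"yes" gap
    never exceeds the visit interval.
    """
    cfg = world.config
    iv = cfg.visit_interval
    recs = []
    for r in truth.itertuples():
        n_days = 366 if isleap(int(r.year)) else 365
        phase = (int(world.rng.integers(1, iv + 1))
                 if cfg.visit_phase == "random" else 1)
        doys = np.arange(phase, n_days + 1, iv)
        onset = r.true_onset_doy
        status = np.where(
            np.isnan(onset), "no", np.where(doys >= onset, "yes", "no")
        )
        recs.append(
            pd.DataFrame(
                {
                    "site_id": r.site_id,
                    "individual_id": r.individual_id,
                    "species": r.species,
                    "phenophase": r.phenophase,
                    "date": pd.Timestamp(int(r.year), 1, 1)
                    + pd.to_timedelta(doys - 1, "D"),
                    "status": status,
                }
            )
        )
    if not recs:
        return pd.DataFrame(columns=["site_id", "individual_id", "species",
                                     "phenophase", "date", "status"])
    return pd.concat(recs, ignore_index=True)


@dataclass
class SimulatedDataset:
    world: World
    truth: pd.DataFrame
    records: pd.DataFrame


def simulate(config: WorldConfig) -> SimulatedDataset:
    """generate_world -> generate_true_onsets -> generate_observations."""
    world = generate_world(config)
    truth = generate_true_onsets(world)
    records = generate_observations(truth, world)
    return SimulatedDataset(world=world, truth=truth, records=records)


def with_params(config: WorldConfig, **kwargs) -> WorldConfig:
    """A copy of the config with selected fields replaced."""
    return replace(config, **kwargs)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset in the same dialects the readers consume."""
    import json
    from pathlib import Path

    import yaml

    from .grids import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.world.sites.to_csv(outdir / "sites.csv", index=False)
    rec = ds.records.copy()
    rec["date"] = rec["date"].dt.strftime("%Y-%m-%d")
    rec.to_csv(outdir / "status.csv", index=False)
    ds.truth.to_csv(outdir / "truth.csv", index=False)

    tdir = outdir / "temps"
    tdir.mkdir(exist_ok=True)
    by_site: dict[str, list[pd.DataFrame]] = {}
    for (sid, year), series in ds.world.temps.items():
        by_site.setdefault(sid, []).append(
            pd.DataFrame(
                {
                    "year": year,
                    "doy": np.arange(1, len(series) + 1),
                    "tmin": series.tmin,
                    "tmax": series.tmax,
                }
            )
        )
    for sid, frames in by_site.items():
        pd.concat(frames, ignore_index=True).to_csv(
            tdir / f"{sid}.csv", index=False
        )
    for year, stack in ds.world.stacks.items():
        stack.save_npz(tdir / f"stack_{year}.npz")
    if ds.world.spring is not None:
        write_ascii_grid(ds.world.spring, outdir / "spring.asc")
    if ds.world.range_geojson is not None:
        with open(outdir / "range.geojson", "w") as fh:
            json.dump(ds.world.range_geojson, fh, indent=2)
            fh.write("\n")
    from dataclasses import asdict

    cfg = json.loads(json.dumps(asdict(ds.world.config)))  # tuples -> lists
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_temps_dir(tdir) -> dict:
    """Load per-site temperature CSVs back into a (site, year) -> series map."""
    from pathlib import Path

    temps: dict = {}
    for path in sorted(Path(tdir).glob("*.csv")):
        sid = path.stem
        df = pd.read_csv(path)
        for year, sub in df.groupby("year"):
            sub = sub.sort_values("doy")
            temps[(sid, int(year))] = TemperatureSeries(
                site_id=sid, year=int(year),
                tmin=sub["tmin"].to_numpy(), tmax=sub["tmax"].to_numpy(),
            )
    return temps
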