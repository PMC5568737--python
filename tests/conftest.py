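import numpy as np
import pandas as pd
import pytest

from gddphen import (
    RunConfig,
    SpeciesSpec,
    TemperatureSeries,
    WorldConfig,
    simulate,
)


def make_series(tmean, site_id="s1", year=2015, diurnal=0.0):
    """TemperatureSeries with the given daily means (padded to year length)."""
    tmean = np.asarray(tmean, dtype=float)
    n = 366 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0) else 365
    if len(tmean) < n:
        tmean = np.concatenate([tmean, np.full(n - len(tmean), tmean[-1])])
    return TemperatureSeries(site_id=site_id, year=year,
                             tmin=tmean - diurnal, tmax=tmean + diurnal)


@pytest.fixture
def constant_10c():
    """A year at a constant 10 °C daily mean."""
    return make_series(np.full(365, 10.0))


@pytest.fixture(scope="session")
def small_world_config():
    """A compact noiseless world: 12 sites, one species, daily visits."""
    return WorldConfig(
        n_sites=12,
        species=(SpeciesSpec("synthspecies_mid", "leaves", 700.0),),
        individuals_per_site=2,
        onset_jitter_sd=0.0,
        visit_interval=1,
        noise_sd=0.0,
        make_grids=False,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_world_config):
    return simulate(small_world_config)


@pytest.fixture(scope="session")
def small_run_config():
    return RunConfig(min_sample=10)


@pytest.fixture(scope="session")
def gridded_dataset():
    """A small noisy world including stacks, spring grid and range mask."""
    cfg = WorldConfig(
        n_sites=15,
        individuals_per_site=2,
        visit_interval=3,
        onset_jitter_sd=1.0,
        cellsize=2.0,
        seed=5,
    )
    return simulate(cfg)


def make_phens(rows):
    """Phenometrics DataFrame from (site, species, phenophase, year, fy, pn)."""
    return pd.DataFrame(
        rows,
        columns=["site_id", "species", "phenophase", "year",
                 "first_yes_doy", "prior_no_doy"],
    ).assign(n_individuals=1)
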