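"""Growing-degree-day arithmetic and universal AGDD threshold models.

A thermal-time model predicts the onset DOY of a phenophase as the day the
accumulated growing degree days (AGDD) — daily mean temperature above a
0 °C base, summed from January 1 — first reach a species x phenophase
specific threshold.  The *universal* threshold is the arithmetic mean of the
AGDD observed at onset across all calibration site x years, used as a single
predictor independent of site and year.

Daily GDD uses the simple-average convention, ``max(0, (tmin + tmax)/2 -
base)``: the daily extremes are averaged first and the result truncated at
the base temperature, matching the convention of operational GDD map
products.
"""

from __future__ import annotations

import json
import logging
import math
from calendar import isleap
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataCompletenessError, InputError, InsufficientDataError

logger = logging.getLogger(__name__)

BASE_TEMP_C = 0.0
START_DOY = 1


@dataclass
class TemperatureSeries:
    """Daily tmin/tmax (°C) for one site and calendar year."""

    site_id: str
    year: int
    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        expected = 366 if isleap(self.year) else 365
        if len(self.tmin) != expected or len(self.tmax) != expected:
            raise InputError(
                f"series for {self.site_id}/{self.year} must have {expected} "
                f"days, got {len(self.tmin)}/{len(self.tmax)}"
            )
        if np.any(self.tmax < self.tmin):
            raise InputError(f"tmax < tmin in series {self.site_id}/{self.year}")

    def __len__(self) -> int:
        return len(self.tmin)


def daily_gdd(tmin, tmax, base: float = BASE_TEMP_C):
    """Growing degree days for one day: max(0, (tmin+tmax)/2 - base)."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise InputError("tmax < tmin")
    out = np.maximum(0.0, (tmin + tmax) / 2.0 - base)
    return float(out) if out.ndim == 0 else out


def agdd_series(series: TemperatureSeries, base: float = BASE_TEMP_C) -> np.ndarray:
    """Cumulative GDD from Jan 1; element d-1 is the AGDD through DOY d."""
    return np.cumsum(daily_gdd(series.tmin, series.tmax, base))


def round_half_up(x: float) -> int:
    """Round a fractional DOY to a calendar day, halves away from zero-up."""
    return int(math.floor(x + 0.5))


def agdd_at_onset(series: TemperatureSeries, first_yes_doy: float,
                  base: float = BASE_TEMP_C) -> float:
    """AGDD accumulated through the (rounded) onset day."""
    d = round_half_up(first_yes_doy)
    if not 1 <= d <= len(series):
        raise InputError(f"first_yes_doy {first_yes_doy} outside 1..{len(series)}")
    return float(agdd_series(series, base)[d - 1])


@dataclass
class ThermalTimeModel:
    """A species x phenophase universal AGDD threshold with calibration data."""

    species: str
    phenophase: str
    threshold_agdd: float
    n_calibration: int
    base_temp: float = BASE_TEMP_C
    start_doy: int = START_DOY
    per_record_agdd: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "phenophase": self.phenophase,
            "threshold_agdd": float(self.threshold_agdd),
            "base_temp": float(self.base_temp),
            "start_doy": int(self.start_doy),
            "n_calibration": int(self.n_calibration),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ThermalTimeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            species=d["species"],
            phenophase=d["phenophase"],
            threshold_agdd=d["threshold_agdd"],
            n_calibration=d["n_calibration"],
            base_temp=d.get("base_temp", BASE_TEMP_C),
            start_doy=d.get("start_doy", START_DOY),
        )


def _require_series(phens: pd.DataFrame, temps) -> list:
    missing = sorted(
        {(r.site_id, int(r.year)) for r in phens.itertuples()} - set(temps)
    )
    return missing


def estimate_threshold(
    calibration: pd.DataFrame,
    temps: dict,
    minimum: int = 30,
    base: float = BASE_TEMP_C,
) -> ThermalTimeModel:
    """Fit the universal AGDD threshold for one species x phenophase.

    ``temps`` maps ``(site_id, year)`` to a :class:`TemperatureSeries`.  The
    threshold is the mean AGDD-at-onset over the calibration site x years;
    at least ``minimum`` distinct site x years are required.
    """
    combos = calibration[["species", "phenophase"]].drop_duplicates()
    if len(combos) != 1:
        raise InputError("calibration records must be one species x phenophase")
    species, phenophase = combos.iloc[0]

    n = len(calibration[["site_id", "year"]].drop_duplicates())
    if n < minimum:
        raise InsufficientDataError(
            f"{species}/{phenophase}: {n} site x years < minimum {minimum}"
        )
    missing = _require_series(calibration, temps)
    if missing:
        raise DataCompletenessError(
            f"missing temperature series for {len(missing)} site x year(s)",
            missing=missing,
        )
    agdds = np.array(
        [
            agdd_at_onset(temps[(r.site_id, int(r.year))], r.first_yes_doy, base)
            for r in calibration.itertuples()
        ]
    )
    return ThermalTimeModel(
        species=species,
        phenophase=phenophase,
        threshold_agdd=float(agdds.mean()),
        n_calibration=len(agdds),
        base_temp=base,
        per_record_agdd=agdds,
    )


def doy_threshold_met(series: TemperatureSeries, threshold: float,
                      base: float = BASE_TEMP_C) -> int | None:
    """Smallest DOY whose AGDD reaches the threshold; None if never met."""
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    if threshold <= 0:
        return 1
    agdd = agdd_series(series, base)
    if agdd[-1] < threshold:
        return None
    return int(np.argmax(agdd >= threshold)) + 1


def predict_onsets(model: ThermalTimeModel, phens: pd.DataFrame,
                   temps: dict) -> pd.DataFrame:
    """Invert the threshold to predicted DOYs for each phenometric.

    Returns one row per phenometric with columns ``site_id, year,
    predicted_doy, observed_doy, met``; rows whose threshold is never met in
    the year have ``met == False`` and NaN ``predicted_doy`` (they are
    excluded from metrics downstream, with a logged count).
    """
    if phens.empty:
        return pd.DataFrame(
            columns=["site_id", "year", "predicted_doy", "observed_doy", "met"]
        )
    missing = _require_series(phens, temps)
    if missing:
        raise DataCompletenessError(
            f"missing temperature series for {len(missing)} site x year(s)",
            missing=missing,
        )
    rows = []
    for r in phens.itertuples():
        series = temps[(r.site_id, int(r.year))]
        doy = doy_threshold_met(series, model.threshold_agdd, model.base_temp)
        rows.append(
            {
                "site_id": r.site_id,
                "year": int(r.year),
                "predicted_doy": float(doy) if doy is not None else np.nan,
                "observed_doy": float(r.first_yes_doy),
                "met": doy is not None,
            }
        )
    out = pd.DataFrame(rows)
    n_not_met = int((~out["met"]).sum())
    if n_not_met:
        logger.info("%s/%s: threshold not met for %d site x year(s)",
                    model.species, model.phenophase, n_not_met)
    return out


def read_series_csv(path, site_id: str, year: int) -> TemperatureSeries:
    """Read one site-year series from a CSV with columns doy, tmin, tmax."""
    df = pd.read_csv(path)
    df = df.sort_values("doy")
    return TemperatureSeries(
        site_id=site_id, year=year,
        tmin=df["tmin"].to_numpy(), tmax=df["tmax"].to_numpy(),
    )
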