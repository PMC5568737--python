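"""Status-format phenology observations and site phenometrics.

Observers report, on each visit to an individual plant, whether a phenophase
is occurring ("yes") or not ("no").  The modeling unit derived from those
reports is the *site phenometric*: for one site x species x phenophase x
year, the mean day of year (DOY) of the first "yes" across the monitored
individuals, together with the mean DOY of each individual's last "no"
strictly before its first "yes".  The distance between the two bounds how
imprecisely the true onset date is known, and drives the record filter.

Tabular data is carried in pandas DataFrames:

* status records — columns ``site_id, individual_id, species, phenophase,
  date, status`` (one row per report);
* sites — columns ``site_id, latitude, longitude, region``;
* phenometrics — columns ``site_id, species, phenophase, year,
  first_yes_doy, prior_no_doy, n_individuals`` (``prior_no_doy`` is NaN when
  no individual has a prior "no").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, RowError

logger = logging.getLogger(__name__)

#: The four phenophases modeled: they represent the full expression of a
#: state in a plant and are near-universal in plant monitoring protocols.
PHENOPHASES = ("breaking_leaf_buds", "leaves", "open_flowers", "ripe_fruits")

STATUS_COLUMNS = ("site_id", "individual_id", "species", "phenophase", "date", "status")
SITE_COLUMNS = ("site_id", "latitude", "longitude")

#: Day-of-year cutoffs beyond which a reported onset is treated as an
#: outlier: DOY 172 (June 21, first day of summer) for leaf phenophases,
#: DOY 213 (Aug 1) for flower/fruit phenophases.
DEFAULT_CUTOFFS = {
    "breaking_leaf_buds": 172,
    "leaves": 172,
    "open_flowers": 213,
    "ripe_fruits": 213,
}


@dataclass(frozen=True)
class FilterConfig:
    """Record-retention rules applied to site phenometrics.

    A phenometric is retained iff

    a. it has a prior "no" and ``first_yes_doy - prior_no_doy`` is strictly
       less than ``max_gap_days`` (onset-date imprecision bound);
    b. ``first_yes_doy`` does not exceed the phenophase's DOY cutoff
       (inclusive);
    c. its site's region tag is not excluded (used to drop regions without
       usable climate data, e.g. Alaska).
    """

    max_gap_days: float = 15.0
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    excluded_regions: tuple = ("AK",)


def read_status_csv(path) -> pd.DataFrame:
    """Read status observations; validate columns, dates and enum values.

    Raises :class:`FormatError` for a missing column and :class:`RowError`
    (with 1-based line numbers, header = line 1) for unparseable dates,
    unknown phenophases or status values outside {yes, no}.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in STATUS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"status file is missing required column(s): {missing}")
    if df.empty:
        out = df.loc[:, list(STATUS_COLUMNS)].copy()
        out["date"] = pd.to_datetime(out["date"])
        return out

    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    status = df["status"].str.strip().str.lower()
    pheno = df["phenophase"].str.strip()

    bad = pd.Series(False, index=df.index)
    problems = []
    for mask, what in [
        (dates.isna(), "unparseable date"),
        (~status.isin(["yes", "no"]), "status not yes/no"),
        (~pheno.isin(PHENOPHASES), "unknown phenophase"),
    ]:
        if mask.any():
            lines = (df.index[mask] + 2).tolist()  # +1 header, +1 zero-base
            problems.append(f"{what} at line(s) {lines[:20]}")
            bad |= mask
    if problems:
        raise RowError("; ".join(problems), lines=(df.index[bad] + 2).tolist())

    out = pd.DataFrame(
        {
            "site_id": df["site_id"].str.strip(),
            "individual_id": df["individual_id"].str.strip(),
            "species": df["species"].str.strip(),
            "phenophase": pheno,
            "date": dates,
            "status": status,
        }
    )
    return out


def read_sites_csv(path) -> pd.DataFrame:
    """Read the site table; deduplicate by site_id (first occurrence wins)."""
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sites file is missing required column(s): {missing}")
    if "region" not in df.columns:
        df["region"] = ""
    df = df.copy()
    df["site_id"] = df["site_id"].astype(str).str.strip()
    df["region"] = df["region"].fillna("").astype(str).str.strip()
    lat = df["latitude"].astype(float)
    lon = df["longitude"].astype(float)
    bad = (~lat.between(-90, 90)) | (~lon.between(-180, 180))
    if bad.any():
        raise RowError(
            f"coordinates out of bounds at line(s) {(df.index[bad] + 2).tolist()}",
            lines=(df.index[bad] + 2).tolist(),
        )
    df["latitude"], df["longitude"] = lat, lon
    df = df.drop_duplicates(subset="site_id", keep="first").reset_index(drop=True)
    return df[["site_id", "latitude", "longitude", "region"]]


def read_observations(status_path, sites_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the paired status + site CSVs."""
    return read_status_csv(status_path), read_sites_csv(sites_path)


def compute_site_phenometrics(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce status records to site phenometrics.

    Per individual and year, the first "yes" on/after Jan 1 is found (later
    yeses in the same year are ignored) plus that individual's latest "no"
    strictly before it within the same year — no cross-year lookback, since
    heat accumulation restarts each Jan 1.  Site-level values are the means
    across individuals: the first-yes mean over all individuals with a yes,
    the prior-no mean over the subset that has a prior no.  Conflicting
    same-day yes/no reports for one individual resolve to "yes"
    (yes-precedence); the number of such conflicts is logged.
    """
    cols = ["site_id", "species", "phenophase", "year",
            "first_yes_doy", "prior_no_doy", "n_individuals"]
    if records.empty:
        return pd.DataFrame(columns=cols)

    rec = records.copy()
    rec["year"] = rec["date"].dt.year
    rec["doy"] = rec["date"].dt.dayofyear
    ind_key = ["site_id", "species", "phenophase", "individual_id", "year"]

    # yes-precedence for same-day conflicts: boolean max over the
    # individual-day group is a C-level any()
    rec["is_yes"] = rec["status"].eq("yes")
    day_key = ind_key + ["doy"]
    day_groups = rec.groupby(day_key, sort=False)["is_yes"]
    per_day = day_groups.max()
    n_conflicts = int(day_groups.nunique().gt(1).sum())
    if n_conflicts:
        logger.info("resolved %d same-day yes/no conflicts with yes-precedence",
                    n_conflicts)
    per_day = per_day.reset_index()

    yes = per_day[per_day["is_yes"]]
    first_yes = (
        yes.groupby(ind_key, sort=False)["doy"].min()
        .rename("first_yes").reset_index()
    )

    no = per_day[~per_day["is_yes"]]
    no = no.merge(first_yes, on=ind_key, how="inner")
    no = no[no["doy"] < no["first_yes"]]
    prior_no = (
        no.groupby(ind_key, sort=False)["doy"].max()
        .rename("prior_no").reset_index()
    )

    ind = first_yes.merge(prior_no, on=ind_key, how="left")
    site_key = ["site_id", "species", "phenophase", "year"]
    grouped = ind.groupby(site_key, sort=True)
    phens = grouped.agg(
        first_yes_doy=("first_yes", "mean"),
        prior_no_doy=("prior_no", "mean"),  # NaN-skipping mean
        n_individuals=("first_yes", "size"),
    ).reset_index()
    return phens[cols]


def filter_phenometrics(
    phens: pd.DataFrame,
    sites: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the retention rules; return (retained, audit).

    Rules are applied in order gap -> cutoff -> region and each removed
    record is attributed to the first rule it fails, so the audit counts sum
    to input minus output.  The audit dict reports totals and per
    species x phenophase counts.
    """
    config = config or FilterConfig()
    unknown = set(phens["phenophase"].unique()) - set(config.cutoffs)
    if unknown:
        raise ConfigurationError(f"no DOY cutoff configured for phenophase(s): "
                                 f"{sorted(unknown)}")

    df = phens.merge(sites[["site_id", "region"]], on="site_id", how="left")
    df["region"] = df["region"].fillna("")

    gap = df["first_yes_doy"] - df["prior_no_doy"]
    fail_gap = df["prior_no_doy"].isna() | ~(gap < config.max_gap_days)
    cutoff = df["phenophase"].map(config.cutoffs)
    fail_cut = ~fail_gap & (df["first_yes_doy"] > cutoff)
    fail_region = ~fail_gap & ~fail_cut & df["region"].isin(config.excluded_regions)

    rule = np.select([fail_gap, fail_cut, fail_region],
                     ["gap", "cutoff", "region"], default="retained")
    df = df.drop(columns="region")

    audit: dict = {
        "input": int(len(df)),
        "removed_gap": int(fail_gap.sum()),
        "removed_cutoff": int(fail_cut.sum()),
        "removed_region": int(fail_region.sum()),
        "retained": int((rule == "retained").sum()),
        "by_group": {},
    }
    tag = df["species"].astype(str) + "|" + df["phenophase"].astype(str)
    for name, sub in pd.Series(rule).groupby(tag.values):
        counts = sub.value_counts()
        audit["by_group"][name] = {
            "removed_gap": int(counts.get("gap", 0)),
            "removed_cutoff": int(counts.get("cutoff", 0)),
            "removed_region": int(counts.get("region", 0)),
            "retained": int(counts.get("retained", 0)),
        }
    retained = df[rule == "retained"].reset_index(drop=True)
    return retained, audit


def split_calibration_validation(
    phens: pd.DataFrame, holdout_year: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split by year: validation = holdout year, calibration = earlier years.

    Years after the holdout cannot belong to either pool; they are dropped
    with a logged warning count.
    """
    cal = phens[phens["year"] < holdout_year].reset_index(drop=True)
    val = phens[phens["year"] == holdout_year].reset_index(drop=True)
    n_later = int((phens["year"] > holdout_year).sum())
    if n_later:
        logger.warning("dropped %d phenometric(s) from years after the "
                       "holdout year %d", n_later, holdout_year)
    return cal, val


def check_min_sample(calibration: pd.DataFrame, minimum: int = 30) -> bool:
    """True iff the calibration pool has >= ``minimum`` distinct site x years."""
    if calibration.empty:
        return False
    n = len(calibration[["site_id", "year"]].drop_duplicates())
    return n >= minimum
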