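"""End-to-end orchestration: phenometrics -> filter -> fit -> evaluate ->
extensibility, with a per-combination run report.

`run_all` loops over every species x phenophase present in the observations.
Combinations with at least the minimum calibration sample get a thermal-time
model, a null model, calibration and validation evaluation reports, a
candidate flag (calibration-period criteria only; the holdout year is
reported but never used for selection) and — when a spring grid and range
mask are supplied — the percent of the species range inside the calibration
climate envelope.  Stage errors are captured per combination with a reason
code instead of aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GddphenError, InsufficientDataError, UndefinedMetricError
from .evaluation import (
    CandidateCriteria,
    EvaluationReport,
    NullModel,
    evaluate_model,
    fit_null,
    is_candidate,
)
from .extensibility import (
    clip_range_to_envelope,
    envelope_from_points,
    percent_range_covered,
)
from .observations import (
    FilterConfig,
    check_min_sample,
    compute_site_phenometrics,
    filter_phenometrics,
    split_calibration_validation,
)
from .thermal_time import ThermalTimeModel, estimate_threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    holdout_year: int = 2016
    min_sample: int = 30
    criteria: CandidateCriteria = field(default_factory=CandidateCriteria)
    area_weighted: bool = True


@dataclass
class ComboResult:
    species: str
    phenophase: str
    status: str                       # ok | insufficient_data | <reason code>
    n_calibration: int = 0
    model: ThermalTimeModel | None = None
    null: NullModel | None = None
    calibration: EvaluationReport | None = None
    validation: EvaluationReport | None = None
    candidate: bool = False
    pct_range: float | None = None
    envelope: dict | None = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "phenophase": self.phenophase,
            "status": self.status,
            "n_calibration": int(self.n_calibration),
            "model": self.model.to_dict() if self.model else None,
            "null_mean_doy": self.null.mean_doy if self.null else None,
            "calibration": self.calibration.to_dict() if self.calibration else None,
            "validation": self.validation.to_dict() if self.validation else None,
            "candidate": bool(self.candidate),
            "pct_range": self.pct_range,
            "envelope": self.envelope,
        }


@dataclass
class RunReport:
    combos: list[ComboResult]
    audit: dict

    def to_dict(self) -> dict:
        return {
            "combos": [c.to_dict() for c in self.combos],
            "audit": self.audit,
        }

    def to_table(self) -> pd.DataFrame:
        """Summary table: one row per sufficiently sampled species x phenophase."""
        rows = []
        for c in self.combos:
            if c.model is None:
                continue
            cal, val = c.calibration, c.validation

            def g(rep, attr):
                if rep is None:
                    return np.nan
                v = getattr(rep, attr)
                return np.nan if v is None else v

            rows.append(
                {
                    "species": c.species,
                    "phenophase": c.phenophase,
                    "n_cal": c.n_calibration,
                    "null_mae": self.audit.get("null_errors", {}).get(
                        f"{c.species}|{c.phenophase}", {}).get("mae", np.nan),
                    "null_rmse": self.audit.get("null_errors", {}).get(
                        f"{c.species}|{c.phenophase}", {}).get("rmse", np.nan),
                    "cal_mae": g(cal, "mae"),
                    "cal_rmse": g(cal, "rmse"),
                    "cal_r2": g(cal, "r2"),
                    "nsme": g(cal, "nsme"),
                    "n_val": 0 if val is None else val.n,
                    "val_mae": g(val, "mae"),
                    "val_rmse": g(val, "rmse"),
                    "val_r2": g(val, "r2"),
                    "pct_range": np.nan if c.pct_range is None else c.pct_range,
                    "threshold_agdd": c.model.threshold_agdd,
                    "candidate": c.candidate,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.to_table().to_csv(outdir / "table.csv", index=False)
        with open(outdir / "audit.json", "w") as fh:
            json.dump(self.audit, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_all(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    temps: dict,
    config: RunConfig | None = None,
    spring=None,
    range_masks=None,
) -> RunReport:
    """Run the full analysis over every species x phenophase combination.

    ``range_masks`` may be a single RangeMask applied to all species or a
    dict keyed by species name; extensibility is skipped (pct_range None)
    where no mask or spring grid is available.
    """
    config = config or RunConfig()
    phens = compute_site_phenometrics(records)
    filtered, audit = filter_phenometrics(phens, sites, config.filter)
    audit["null_errors"] = {}
    cal_all, val_all = split_calibration_validation(filtered, config.holdout_year)

    combos = (
        filtered[["species", "phenophase"]]
        .drop_duplicates()
        .sort_values(["species", "phenophase"])
    )
    results = []
    for species, phenophase in combos.itertuples(index=False):
        sel = lambda df: df[
            (df["species"] == species) & (df["phenophase"] == phenophase)
        ].reset_index(drop=True)
        cal, val = sel(cal_all), sel(val_all)
        n_cal = len(cal[["site_id", "year"]].drop_duplicates())
        res = ComboResult(species=species, phenophase=phenophase,
                          status="ok", n_calibration=n_cal)
        if not check_min_sample(cal, config.min_sample):
            res.status = "insufficient_data"
            results.append(res)
            continue
        try:
            res.model = estimate_threshold(cal, temps, minimum=config.min_sample)
            res.null = fit_null(cal)
            res.calibration = evaluate_model(res.model, res.null, cal, temps,
                                             "calibration")
            res.validation = evaluate_model(res.model, res.null, val, temps,
                                            "validation")
            res.candidate = is_candidate(res.calibration, config.criteria)
            null_res = res.null.mean_doy - cal["first_yes_doy"].to_numpy()
            audit["null_errors"][f"{species}|{phenophase}"] = {
                "mae": float(np.mean(np.abs(null_res))),
                "rmse": float(np.sqrt(np.mean(null_res**2))),
            }
        except UndefinedMetricError as exc:
            res.status = f"undefined_metric: {exc}"
            res.candidate = False
            results.append(res)
            continue
        except (InsufficientDataError, GddphenError) as exc:
            res.status = f"error: {exc}"
            results.append(res)
            continue

        if spring is not None and range_masks is not None:
            mask = (range_masks.get(species)
                    if isinstance(range_masks, dict) else range_masks)
            if mask is not None:
                try:
                    cal_sites = sites[sites["site_id"].isin(cal["site_id"])]
                    env, _ = envelope_from_points(spring, cal_sites)
                    clipped = clip_range_to_envelope(mask, spring, env)
                    res.pct_range = percent_range_covered(
                        clipped, mask, area_weighted=config.area_weighted
                    )
                    res.envelope = env.to_dict()
                except GddphenError as exc:
                    res.status = f"extensibility_error: {exc}"
        results.append(res)

    n_insufficient = sum(r.status == "insufficient_data" for r in results)
    if n_insufficient:
        logger.info("%d combination(s) below the minimum calibration sample",
                    n_insufficient)
    return RunReport(combos=results, audit=audit)


def recover_model_from_simulation(ds, species: str, phenophase: str,
                                  config: RunConfig | None = None):
    """Convenience for tests/studies: fit + evaluate one combo of a
    SimulatedDataset; returns (model, null, cal_report, val_report)."""
    config = config or RunConfig()
    phens = compute_site_phenometrics(ds.records)
    filtered, _ = filter_phenometrics(phens, ds.world.sites, config.filter)
    one = filtered[(filtered["species"] == species)
                   & (filtered["phenophase"] == phenophase)].reset_index(drop=True)
    cal, val = split_calibration_validation(one, config.holdout_year)
    model = estimate_threshold(cal, ds.world.temps, minimum=config.min_sample)
    null = fit_null(cal)
    cal_rep = evaluate_model(model, null, cal, ds.world.temps, "calibration")
    val_rep = evaluate_model(model, null, val, ds.world.temps, "validation")
    return model, null, cal_rep, val_rep


def degradation_study(base_config, visit_intervals, seeds,
                      run_config: RunConfig | None = None) -> pd.DataFrame:
    """Calibration MAE of the recovered model per seed x visit interval.

    Re-simulates the world for every (seed, interval) with grids disabled
    (they are irrelevant to this question), fits each species x phenophase
    and records the calibration MAE.  Returns a tidy DataFrame with columns
    ``seed, visit_interval, species, phenophase, mae, nsme, r2,
    threshold_err``.
    """
    from dataclasses import replace

    from .synthetic_data import simulate

    run_config = run_config or RunConfig()
    rows = []
    for seed in seeds:
        for iv in visit_intervals:
            cfg = replace(base_config, seed=int(seed), visit_interval=int(iv),
                          make_grids=False)
            ds = simulate(cfg)
            for spec in cfg.species:
                model, _, cal_rep, _ = recover_model_from_simulation(
                    ds, spec.species, spec.phenophase, run_config
                )
                rows.append(
                    {
                        "seed": int(seed),
                        "visit_interval": int(iv),
                        "species": spec.species,
                        "phenophase": spec.phenophase,
                        "mae": cal_rep.mae,
                        "nsme": cal_rep.nsme,
                        "r2": cal_rep.r2,
                        "threshold_err": model.threshold_agdd
                        - spec.true_threshold_agdd,
                    }
                )
    return pd.DataFrame(rows)
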