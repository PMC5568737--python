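"""Null model, error metrics, Nash-Sutcliffe efficiency, candidate selection.

The null model predicts every onset with one constant: the calibration-period
mean of the site-level mean first-"yes" DOYs.  The Nash-Sutcliffe model
efficiency (NSME) compares the thermal-time model's squared error against the
null's::

    NSME = 1 - sum((pred - obs)^2) / sum((null - obs)^2)

NSME ranges from -inf to 1; 1 is a perfect match and 0 means no better than
the null.  Because the null constant is the calibration mean, NSME on
calibration data coincides with the classic efficiency about the observed
mean.  R^2 is the squared Pearson correlation of predicted vs observed DOY —
direction-blind, which is why candidate selection also requires NSME and MAE.

Residuals follow the convention ``predicted - observed``: negative means the
model predicted the phenophase earlier than observers reported it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError
from .thermal_time import ThermalTimeModel, predict_onsets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModel:
    species: str
    phenophase: str
    mean_doy: float


@dataclass(frozen=True)
class CandidateCriteria:
    """Minimum calibration-period fit for a model to be a candidate."""

    nsme_min: float = 0.4
    r2_min: float = 0.5
    mae_max: float = 10.0


def fit_null(calibration: pd.DataFrame) -> NullModel:
    """Mean of the mean first-yes DOY across calibration site x years."""
    if calibration.empty:
        raise InputError("cannot fit a null model on an empty calibration set")
    combos = calibration[["species", "phenophase"]].drop_duplicates()
    if len(combos) != 1:
        raise InputError("calibration records must be one species x phenophase")
    species, phenophase = combos.iloc[0]
    return NullModel(species=species, phenophase=phenophase,
                     mean_doy=float(calibration["first_yes_doy"].mean()))


def mae(residuals) -> float:
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise InputError("MAE of empty residuals is undefined")
    return float(np.mean(np.abs(residuals)))


def rmse(residuals) -> float:
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise InputError("RMSE of empty residuals is undefined")
    return float(np.sqrt(np.mean(residuals**2)))


def nsme(predicted, observed, null_predicted) -> float:
    """Nash-Sutcliffe efficiency of ``predicted`` relative to the null."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    null_predicted = np.asarray(null_predicted, dtype=float)
    if not (predicted.size == observed.size == null_predicted.size):
        raise InputError("nsme inputs must have equal length")
    if predicted.size == 0:
        raise InputError("nsme of empty inputs is undefined")
    denom = float(np.sum((null_predicted - observed) ** 2))
    if denom == 0.0:
        raise UndefinedMetricError(
            "null sum of squares is zero (all observations equal the null)"
        )
    return float(1.0 - np.sum((predicted - observed) ** 2) / denom)


def r_squared(predicted, observed) -> float:
    """Squared Pearson correlation of predicted vs observed."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size:
        raise InputError("r_squared inputs must have equal length")
    if predicted.size < 2:
        raise InputError("r_squared needs at least two points")
    if np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        raise UndefinedMetricError("zero variance in predicted or observed")
    r = np.corrcoef(predicted, observed)[0, 1]
    return float(r**2)


@dataclass
class EvaluationReport:
    """Fit metrics for one model on one labeled dataset."""

    dataset_label: str  # "calibration" or "validation"
    n: int
    mae: float | None
    rmse: float | None
    r2: float | None
    nsme: float | None
    residuals: np.ndarray = field(repr=False, default=None)
    n_not_met: int = 0

    def to_dict(self) -> dict:
        return {
            "dataset_label": self.dataset_label,
            "n": int(self.n),
            "mae": None if self.mae is None else float(self.mae),
            "rmse": None if self.rmse is None else float(self.rmse),
            "r2": None if self.r2 is None else float(self.r2),
            "nsme": None if self.nsme is None else float(self.nsme),
            "n_not_met": int(self.n_not_met),
        }

    def summary(self) -> str:
        """One-line human-readable summary (days to 0.1, ratios to 0.01)."""
        if self.n == 0:
            return f"{self.dataset_label}: n=0 (no usable records)"
        fmt = lambda v, p: "NA" if v is None else f"{v:.{p}f}"
        return (
            f"{self.dataset_label}: n={self.n} "
            f"MAE={fmt(self.mae, 1)}d RMSE={fmt(self.rmse, 1)}d "
            f"R2={fmt(self.r2, 2)} NSME={fmt(self.nsme, 2)} "
            f"not_met={self.n_not_met}"
        )


def evaluate_model(
    model: ThermalTimeModel,
    null: NullModel,
    phens: pd.DataFrame,
    temps: dict,
    label: str,
) -> EvaluationReport:
    """Predict onsets and compute MAE/RMSE/R^2/NSME on rows with a met threshold.

    The null prediction is the calibration-fit constant even on the
    validation year.  Rows whose threshold is never met are excluded from
    the metrics and counted in ``n_not_met``.  An empty dataset yields a
    report with n = 0 and absent metrics.
    """
    pred = predict_onsets(model, phens, temps)
    met = pred[pred["met"]]
    n_not_met = int(len(pred) - len(met))
    if met.empty:
        return EvaluationReport(dataset_label=label, n=0, mae=None, rmse=None,
                                r2=None, nsme=None,
                                residuals=np.array([]), n_not_met=n_not_met)
    residuals = (met["predicted_doy"] - met["observed_doy"]).to_numpy()
    null_pred = np.full(len(met), null.mean_doy)
    return EvaluationReport(
        dataset_label=label,
        n=int(len(met)),
        mae=mae(residuals),
        rmse=rmse(residuals),
        r2=r_squared(met["predicted_doy"], met["observed_doy"]),
        nsme=nsme(met["predicted_doy"], met["observed_doy"], null_pred),
        residuals=residuals,
        n_not_met=n_not_met,
    )


def is_candidate(report: EvaluationReport,
                 criteria: CandidateCriteria | None = None) -> bool:
    """True iff the calibration report meets all minimum criteria (inclusive)."""
    criteria = criteria or CandidateCriteria()
    if report.mae is None or report.r2 is None or report.nsme is None:
        return False
    return (
        report.nsme >= criteria.nsme_min
        and report.r2 >= criteria.r2_min
        and report.mae <= criteria.mae_max
    )
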