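"""External-validation metrics for a continuous-outcome prediction model.

Given observed and predicted outcomes (here 1-year PDC, a proportion),
this module computes the standard external-validation suite:

* calibration-in-the-large (CITL): mean observed minus mean predicted;
* the calibration model ``observed = a_cal + l_cal * predicted + e``,
  fitted by least squares, with a normal-theory 95% CI for the slope
  (t distribution, n-2 degrees of freedom);
* R²_val = 1 - SSE/SST computed on the raw predictions without refitting
  (negative for a badly miscalibrated model); the squared Pearson
  correlation and the calibration-model R² are reported as secondary
  fields;
* RMSE, MAE, the MAE of a constant mean-outcome baseline, and the
  relative MAE reduction 1 - MAE/baseline_MAE;
* absolute-error quantiles and an equal-count (quantile-binned)
  calibration curve.

When the fitted calibration slope is exactly 1, the calibration intercept
equals CITL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ValidationReport",
    "citl",
    "calibration_fit",
    "r2_val",
    "error_metrics",
    "abs_error_quantile",
    "calibration_bins",
    "validate",
]


class DegenerateFitError(ValueError):
    """Zero variance where the metric needs spread."""


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.ndim != 1 or pred.ndim != 1:
        raise ValueError("observed and predicted must be one-dimensional")
    if obs.size != pred.size:
        raise ValueError(
            f"length mismatch: {obs.size} observed vs {pred.size} predicted"
        )
    if obs.size == 0:
        raise ValueError("empty input")
    return obs, pred


def citl(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Calibration-in-the-large: mean(observed) - mean(predicted)."""
    obs, pred = _check_pair(observed, predicted)
    return float(obs.mean() - pred.mean())


def calibration_fit(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Least-squares calibration model: intercept, slope, slope 95% CI.

    A perfectly calibrated model has intercept 0 and slope 1.  The CI is
    ``slope ± t(0.975, n-2) * SE(slope)``; for an exact fit the residual SE
    is zero and the CI has zero width.
    """
    obs, pred = _check_pair(observed, predicted)
    n = obs.size
    if n < 3:
        raise ValueError(f"calibration fit needs n >= 3, got {n}")
    if np.ptp(pred) == 0:
        raise DegenerateFitError("predicted values have zero variance")
    res = stats.linregress(pred, obs)
    half = stats.t.ppf(0.975, n - 2) * res.stderr
    return (
        float(res.intercept),
        float(res.slope),
        (float(res.slope - half), float(res.slope + half)),
    )


def r2_val(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Proportion of outcome variance explained by the raw predictions.

    ``1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2)``, with no
    refitting; may be negative when the model is worse than predicting the
    mean.
    """
    obs, pred = _check_pair(observed, predicted)
    if obs.size < 2:
        raise ValueError("r2_val needs n >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise DegenerateFitError("observed values have zero variance")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def error_metrics(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float, float | None]:
    """(rmse, mae, baseline_mae, relative_mae_reduction).

    The baseline is the constant predictor equal to ``mean(observed)``; the
    relative reduction is ``1 - mae / baseline_mae`` (None when the observed
    outcome is constant and the baseline MAE is zero).
    """
    obs, pred = _check_pair(observed, predicted)
    err = obs - pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    baseline_mae = float(np.mean(np.abs(obs - obs.mean())))
    reduction = None if baseline_mae == 0 else 1.0 - mae / baseline_mae
    return rmse, mae, baseline_mae, reduction


def abs_error_quantile(
    observed: Sequence[float], predicted: Sequence[float], q
) -> float | np.ndarray:
    """q-quantile of |observed - predicted| (linear interpolation)."""
    obs, pred = _check_pair(observed, predicted)
    out = np.quantile(np.abs(obs - pred), q)
    return float(out) if np.ndim(q) == 0 else out


def calibration_bins(
    observed: Sequence[float],
    predicted: Sequence[float],
    n_bins: int = 10,
) -> list[tuple[float, float, int]]:
    """Equal-count calibration curve: (mean predicted, mean observed, count).

    Predictions are sorted and split into ``n_bins`` near-equal-count bins
    (quantile binning); rows are returned in ascending predicted order.
    """
    obs, pred = _check_pair(observed, predicted)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    order = np.argsort(pred, kind="stable")
    rows = []
    for idx in np.array_split(order, min(n_bins, obs.size)):
        if idx.size:
            rows.append(
                (float(pred[idx].mean()), float(obs[idx].mean()), int(idx.size))
            )
    return rows


@dataclass
class ValidationReport:
    """The full external-validation metric set for one model on one cohort."""

    n: int
    r2_val: float
    r2_pearson: float
    r2_calibration: float
    citl: float
    cal_intercept: float
    cal_slope: float
    cal_slope_ci95: tuple[float, float]
    rmse: float
    mae: float
    baseline_mae: float
    relative_mae_reduction: float | None
    abs_error_quantiles: Mapping[float, float]
    calibration_bins: list[tuple[float, float, int]]
    errors: np.ndarray = field(repr=False)
    abs_errors: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("errors")
        d.pop("abs_errors")
        d["abs_error_quantiles"] = {str(k): v for k, v in d["abs_error_quantiles"].items()}
        d["cal_slope_ci95"] = list(d["cal_slope_ci95"])
        d["calibration_bins"] = [list(b) for b in d["calibration_bins"]]
        return d


def validate(
    observed: Sequence[float],
    predicted: Sequence[float],
    n_bins: int = 10,
    quantiles: Sequence[float] = (0.5, 0.7, 0.9),
) -> ValidationReport:
    """Compute the full metric suite comparing observed and predicted PDC."""
    obs, pred = _check_pair(observed, predicted)
    a_cal, l_cal, ci = calibration_fit(obs, pred)
    rmse, mae, base_mae, reduction = error_metrics(obs, pred)
    err = obs - pred
    pearson = float(stats.pearsonr(obs, pred).statistic) if np.ptp(obs) and np.ptp(pred) else 1.0
    resid = obs - (a_cal + l_cal * pred)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2_cal = 1.0 - float(np.sum(resid**2)) / sst if sst else 1.0
    return ValidationReport(
        n=obs.size,
        r2_val=r2_val(obs, pred),
        r2_pearson=pearson**2,
        r2_calibration=r2_cal,
        citl=citl(obs, pred),
        cal_intercept=a_cal,
        cal_slope=l_cal,
        cal_slope_ci95=ci,
        rmse=rmse,
        mae=mae,
        baseline_mae=base_mae,
        relative_mae_reduction=reduction,
        abs_error_quantiles={float(q): abs_error_quantile(obs, pred, q) for q in quantiles},
        calibration_bins=calibration_bins(obs, pred, n_bins),
        errors=err,
        abs_errors=np.abs(err),
    )
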