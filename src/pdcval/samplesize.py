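"""Minimum sample size for external validation of a continuous-outcome model.

Four criteria, each targeting the precision of one validation metric; the
overall minimum is the largest of the four.

(i)   precise R²_val:        n = 4 R² (1-R²)² / SE(R²)²
(ii)  precise CITL:          n = var(Y) (1-R²) / SE(CITL)²
(iii) precise calibration slope:
                             n = λ² (1-R²) / (SE(λ)² R²) + 1
(iv)  precise residual spread of the calibration model: the smallest n
      such that the 95% chi-square confidence interval for the residual
      standard deviation has multiplicative margin of error at most
      ``moe_resid``, i.e. the smallest n with

          sqrt(m / chi2_quantile(0.025, m)) <= 1 + moe_resid,
          m = n - p_cal - 1

      where p_cal is the number of predictors in the calibration model.
      The margin is defined on the standard-deviation scale.

Criteria (i)-(iii) are closed-form; their integer n is the ceiling of the
raw value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy.stats import chi2

__all__ = [
    "SampleSizeSpec",
    "SampleSizeResult",
    "CriterionResult",
    "n_for_r2",
    "n_for_citl",
    "n_for_slope",
    "n_for_residual_variance",
    "overall_minimum",
]


class CriterionResult(NamedTuple):
    raw: float
    n: int


def _ceil(raw: float) -> int:
    return int(math.ceil(raw))


def n_for_r2(r2_val: float, se_r2: float) -> CriterionResult:
    """Criterion (i): sample size to estimate R²_val with standard error se_r2."""
    if not 0 < r2_val < 1:
        raise ValueError(f"r2_val must be in (0, 1), got {r2_val}")
    if se_r2 <= 0:
        raise ValueError("se_r2 must be positive")
    raw = 4 * r2_val * (1 - r2_val) ** 2 / se_r2**2
    return CriterionResult(raw, _ceil(raw))


def n_for_citl(var_y: float, r2_val: float, se_citl: float) -> CriterionResult:
    """Criterion (ii): sample size to estimate calibration-in-the-large.

    ``var_y`` is the anticipated outcome variance var(Y_i).
    """
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    if not 0 < r2_val < 1:
        raise ValueError(f"r2_val must be in (0, 1), got {r2_val}")
    if se_citl <= 0:
        raise ValueError("se_citl must be positive")
    raw = var_y * (1 - r2_val) / se_citl**2
    return CriterionResult(raw, _ceil(raw))


def n_for_slope(lambda_cal: float, r2_val: float, se_lambda: float) -> CriterionResult:
    """Criterion (iii): sample size to estimate the calibration slope λ."""
    if not 0 < r2_val < 1:
        raise ValueError(f"r2_val must be in (0, 1), got {r2_val}")
    if se_lambda <= 0:
        raise ValueError("se_lambda must be positive")
    raw = lambda_cal**2 * (1 - r2_val) / (se_lambda**2 * r2_val) + 1
    return CriterionResult(raw, _ceil(raw))


def n_for_residual_variance(moe_resid: float = 0.10, p_cal: int = 1) -> int:
    """Criterion (iv): sample size for precise residual-spread estimation.

    Smallest n such that the upper bound of the 95% chi-square confidence
    interval for the residual standard deviation of a calibration model
    with ``p_cal`` predictors is within a factor ``1 + moe_resid`` of the
    estimate: ``sqrt(m / chi2.ppf(0.025, m)) <= 1 + moe_resid`` with
    residual degrees of freedom ``m = n - p_cal - 1``.
    """
    if not 0 < moe_resid < 1:
        raise ValueError("moe_resid must be in (0, 1)")
    if p_cal < 1:
        raise ValueError("p_cal must be >= 1")
    target = 1 + moe_resid
    m = 1
    while math.sqrt(m / chi2.ppf(0.025, m)) > target:
        m += 1
    return m + p_cal + 1


@dataclass(frozen=True)
class SampleSizeSpec:
    """Anticipated performance and precision targets for all four criteria."""

    r2_val: float = 0.5
    se_r2: float = 0.0255
    var_y: float = 0.04
    se_citl: float = 0.0255
    lambda_cal: float = 1.0
    se_lambda: float = 0.051
    moe_resid: float = 0.10
    p_cal: int = 1


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-criterion raw values and integer minima, and their maximum."""

    criteria: dict[str, CriterionResult]
    overall: int

    def to_dict(self) -> dict:
        return {
            "criteria": {
                k: {"raw": v.raw, "n": v.n} for k, v in self.criteria.items()
            },
            "overall": self.overall,
        }


def overall_minimum(spec: SampleSizeSpec = SampleSizeSpec()) -> SampleSizeResult:
    """Evaluate all four criteria; the overall minimum is their maximum."""
    n4 = n_for_residual_variance(spec.moe_resid, spec.p_cal)
    criteria = {
        "r2": n_for_r2(spec.r2_val, spec.se_r2),
        "citl": n_for_citl(spec.var_y, spec.r2_val, spec.se_citl),
        "slope": n_for_slope(spec.lambda_cal, spec.r2_val, spec.se_lambda),
        "residual_variance": CriterionResult(float(n4), n4),
    }
    return SampleSizeResult(
        criteria=criteria, overall=max(c.n for c in criteria.values())
    )
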