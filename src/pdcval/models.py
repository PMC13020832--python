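"""Published beta-regression mean models for 1-year adherence.

Each model is a logit-linear mean equation

    logit(PDC_1yr) = intercept + slope * (days covered at 90 days)

applied through the inverse logit.  The built-in statin and antiplatelet
coefficients live in a plain JSON registry (``models.json``) so that users
can add recalibrated or re-estimated specifications without code changes.

``mean_recalibrate`` implements mean-shift recalibration: adapting a model
to a population whose outcome mean differs by adding the difference in
means to the predictions on the probability scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "builtin_models",
    "load_registry",
    "predict_pdc",
    "mean_recalibrate",
]

PREDICTOR_MIN = 0
PREDICTOR_MAX = 90


class InvalidModelError(ValueError):
    """Model coefficients are not finite."""


class PredictorRangeError(ValueError):
    """Predictor outside the supported [0, 90] day range."""


@dataclass(frozen=True)
class ModelSpec:
    """Logit-scale intercept and slope of a published prediction model."""

    name: str
    intercept: float
    slope: float
    predictor_name: str = "days covered at 90"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise InvalidModelError(
                f"model {self.name!r} has non-finite coefficients"
            )

    def linear_predictor(self, days_covered_90):
        return self.intercept + self.slope * np.asarray(days_covered_90, dtype=float)


def load_registry(path: str | Path | None = None) -> dict[str, ModelSpec]:
    """Load model specs from a JSON registry (the built-in one by default)."""
    if path is None:
        text = resources.files("pdcval").joinpath("models.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return {
        name: ModelSpec(name=name, **entry) for name, entry in raw.items()
    }


def builtin_models() -> tuple[ModelSpec, ModelSpec]:
    """Return the published (statin, antiplatelet) model specifications."""
    reg = load_registry()
    return reg["statin"], reg["antiplatelet"]


def predict_pdc(
    model: ModelSpec,
    days_covered_90,
    on_range_error: str = "raise",
):
    """Predicted 1-year PDC: inverse-logit of the linear predictor.

    Accepts a scalar or array predictor.  Values outside [0, 90] raise
    ``PredictorRangeError`` by default; pass ``on_range_error="warn"`` to
    warn and predict anyway.  Predictions are strictly inside (0, 1).
    """
    x = np.asarray(days_covered_90, dtype=float)
    if np.any(x < PREDICTOR_MIN) or np.any(x > PREDICTOR_MAX):
        msg = (
            f"days_covered_90 outside [{PREDICTOR_MIN}, {PREDICTOR_MAX}]; "
            f"the model was developed on that range"
        )
        if on_range_error == "raise":
            raise PredictorRangeError(msg)
        warnings.warn(msg, stacklevel=2)
    out = expit(model.linear_predictor(x))
    return float(out) if np.isscalar(days_covered_90) else out


def mean_recalibrate(predictions: Sequence[float], delta: float) -> np.ndarray:
    """Shift predictions by ``delta`` on the probability scale, clipped to [0, 1].

    When no clipping occurs, ``mean(out) - mean(in) == delta`` exactly, so a
    model can be adapted to a new population by passing the difference in
    outcome means between the populations.
    """
    preds = np.asarray(predictions, dtype=float)
    return np.clip(preds + delta, 0.0, 1.0)
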