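"""Model evaluation panel: RMSEC/RMSEP, R²cal/R²pre, RPD, and quality bands.

All root-mean-square errors use a plain ``n`` denominator (the common
chemometrics convention).  RPD is the ratio of the validation set's
reference-value standard deviation (n-1 denominator) to RMSEP; larger is
better, and the conventional quality bands are: below 2.5 inadequate,
2.5-3 fair, above 3 good, above 4 excellent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError, ParameterError, ShapeError, UndefinedRPDError

CATEGORIES = ("inadequate", "fair", "good", "excellent")


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean square error, ``sqrt(sum((yhat - y)^2) / n)``."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ShapeError(
            f"predicted length {len(predicted)} != observed length {len(observed)}"
        )
    if len(observed) < 1:
        raise ShapeError("rmse needs at least one observation")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the evaluated set's own observed mean; values
    below zero mean the model predicts worse than that mean.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ShapeError(
            f"predicted length {len(predicted)} != observed length {len(observed)}"
        )
    if len(observed) < 2:
        raise ShapeError("r_squared needs at least two observations")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateModelError("observed values have zero variance; R² undefined")
    return 1.0 - float(np.sum((predicted - observed) ** 2)) / ss_tot


def rpd(observed_validation: np.ndarray, rmsep: float) -> float:
    """Ratio of performance to deviation: ``SD(observed) / RMSEP``.

    SD uses the n-1 denominator.  A value around 2.5-3 marks a model usable
    for screening; above 3 for quality control.
    """
    observed = np.asarray(observed_validation, dtype=float).ravel()
    if len(observed) < 2:
        raise ParameterError("RPD needs at least two validation observations")
    sd = float(observed.std(ddof=1))
    if sd == 0:
        raise DegenerateModelError("validation reference values have zero variance")
    if rmsep <= 0:
        raise UndefinedRPDError("RPD undefined for non-positive RMSEP")
    return sd / rmsep


def categorize_rpd(value: float) -> str:
    """Quality band for an RPD value (inadequate/fair/good/excellent)."""
    if not value > 0:
        raise ParameterError(f"RPD must be positive, got {value}")
    if value < 2.5:
        return "inadequate"
    if value <= 3.0:
        return "fair"
    if value <= 4.0:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ModelMetrics:
    """The full evaluation panel of one calibration model."""

    rmsec: float
    rmsep: float
    r2_cal: float
    r2_pre: float
    rpd: float
    n_cal: int
    n_val: int

    @property
    def category(self) -> str:
        return categorize_rpd(self.rpd)


def evaluate_model(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_val: np.ndarray,
    yhat_val: np.ndarray,
) -> ModelMetrics:
    """Assemble the metric panel from calibration and validation predictions.

    A numerically perfect validation fit (RMSEP exactly 0) gets infinite
    RPD rather than an error, so exhaustive grids over idealized synthetic
    data stay well-defined.
    """
    rmsec = rmse(yhat_cal, y_cal)
    rmsep = rmse(yhat_val, y_val)
    rpd_value = math.inf if rmsep == 0 else rpd(y_val, rmsep)
    return ModelMetrics(
        rmsec=rmsec,
        rmsep=rmsep,
        r2_cal=r_squared(yhat_cal, y_cal),
        r2_pre=r_squared(yhat_val, y_val),
        rpd=rpd_value,
        n_cal=len(np.ravel(y_cal)),
        n_val=len(np.ravel(y_val)),
    )
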