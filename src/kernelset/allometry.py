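"""Non-destructive allometric estimation of maize shoot and ear biomass.

Tagged plants are never cut; their biomass is predicted from morphometrics
through calibration regressions fitted on destructively sampled border
plants:

* preflowering — shoot biomass ~ stem volume (simple OLS);
* postflowering — shoot biomass ~ stem volume + maximum ear diameter
  (multiple OLS, silking ears only);
* ear — ear biomass ~ ear diameter squared (simple OLS).

Stem volume is taken as a cylinder, pi * (d/2)^2 * h, from plant height
(ground to uppermost leaf collar) and basal stalk diameter.  The cylinder
is a modelling choice (the standard one in the allometric literature); swap
in another volume rule upstream if needed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "AllometricModel",
    "stem_volume",
    "fit_preflowering",
    "fit_postflowering",
    "fit_ear_model",
    "predict_biomass",
]

_KINDS = ("preflowering", "postflowering", "ear")
_ARITY = {"preflowering": 1, "postflowering": 2, "ear": 1}


@dataclass(frozen=True)
class AllometricModel:
    """A fitted calibration regression.

    coefficients are [intercept, slopes...] in model order; for the ear
    model the single slope applies to diameter squared.
    """

    kind: str
    coefficients: tuple[float, ...]
    r_squared: float
    n_calibration: int

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_calibration < len(self.coefficients) + 1:
            raise ValueError("too few calibration points for the model order")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "AllometricModel":
        d = json.loads(s)
        d["coefficients"] = tuple(d["coefficients"])
        return cls(**d)


def stem_volume(height: float, diameter: float) -> float:
    """Cylinder stem volume (cm^3) from height and basal diameter (cm)."""
    height = np.asarray(height, dtype=float)
    diameter = np.asarray(diameter, dtype=float)
    if np.any(height < 0) or np.any(diameter < 0):
        raise ValueError("height and diameter must be >= 0")
    v = math.pi * (diameter / 2.0) ** 2 * height
    return float(v) if v.ndim == 0 else v


def _ols(X: np.ndarray, y: np.ndarray, kind: str) -> AllometricModel:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(
            f"{kind} calibration design is rank-deficient "
            "(collinear or constant predictors)")
    fit = sm.OLS(y, Xc).fit()
    r2 = float(min(max(fit.rsquared, 0.0), 1.0))
    return AllometricModel(kind=kind, coefficients=tuple(float(b) for b in fit.params),
                           r_squared=r2, n_calibration=len(y))


def fit_preflowering(calibration) -> AllometricModel:
    """OLS of shoot biomass (g) on stem volume (cm^3).

    ``calibration`` is a sequence of (stem_volume, biomass) pairs; at least
    3 points with non-identical volumes are required.
    """
    arr = np.asarray(calibration, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (stem_volume, biomass) calibration points")
    return _ols(arr[:, :1], arr[:, 1], "preflowering")


def fit_postflowering(calibration) -> AllometricModel:
    """OLS of shoot biomass (g) on stem volume (cm^3) and ear diameter (cm).

    ``calibration`` rows are (stem_volume, ear_diameter, biomass); at least
    4 points, predictors not collinear.  Main effects only.
    """
    arr = np.asarray(calibration, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 4:
        raise ValueError("need >= 4 (stem_volume, ear_diameter, biomass) points")
    return _ols(arr[:, :2], arr[:, 2], "postflowering")


def fit_ear_model(calibration) -> AllometricModel:
    """OLS of ear biomass (g) on ear diameter squared (cm^2)."""
    arr = np.asarray(calibration, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (ear_diameter, ear_biomass) points")
    if np.any(arr[:, 0] < 0):
        raise ValueError("ear diameters must be >= 0")
    return _ols(arr[:, :1] ** 2, arr[:, 1], "ear")


def predict_biomass(model: AllometricModel, predictors):
    """Apply a calibration model; negative predictions floored at 0.

    ``predictors`` is a scalar (simple models), a pair
    (stem_volume, ear_diameter) for the postflowering model, or an array of
    shape (n,) / (n, 2) accordingly.  The ear model squares its diameter
    predictor internally.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and X.shape[1] != _ARITY[model.kind]:
        X = X.T
    if X.shape[1] != _ARITY[model.kind]:
        raise ValueError(
            f"{model.kind} model expects {_ARITY[model.kind]} predictor(s), "
            f"got shape {X.shape}")
    if model.kind == "ear":
        X = X ** 2
    beta = np.asarray(model.coefficients)
    pred = beta[0] + X @ beta[1:]
    if np.any(pred < 0):
        logger.warning("%d negative biomass prediction(s) floored at 0",
                       int(np.sum(pred < 0)))
        pred = np.maximum(pred, 0.0)
    scalar = np.isscalar(predictors) or (
        np.asarray(predictors).ndim == 1 and _ARITY[model.kind] > 1)
    return float(pred[0]) if scalar else pred
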