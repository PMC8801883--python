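"""Piecewise hyperbolic kernel-set model for maize.

Kernel number per plant (KNP) in maize is set by ear biomass (EB)
accumulated during the weeks bracketing flowering, which in turn is driven
by plant growth rate (PGR) over that interval.  Both links are described by
saturating hyperbolae with a base threshold below which the response is
zero:

    EB(PGR)  = 0                                          if PGR <= PGR_b
             = IS_EB (PGR - PGR_b) / (1 + C_EB (PGR - PGR_b))   otherwise

    KNP(EB)  = 0                                          if EB <= EB_b
             = IS_KN (EB - EB_b) / (1 + C_KN (EB - EB_b))       otherwise

The six quantities (PGR_b, IS_EB, C_EB, EB_b, IS_KN, C_KN) are genotypic
coefficients: base growth rate for ear growth, initial slope and curvature
of the EB response, base ear biomass for kernel set, and initial slope and
curvature of the KNP response.  Fitting is two-stage bound-constrained
nonlinear least squares: the EB-vs-PGR curve first, then the KNP-vs-EB
curve, each with a multi-start strategy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCoefficients",
    "FitResult",
    "REFERENCE_HYBRIDS",
    "ear_biomass_forward",
    "kernel_number_forward",
    "fit_kernelset",
    "plateau",
]


@dataclass(frozen=True)
class GenotypeCoefficients:
    """Genotypic coefficients of the two hyperbolic responses.

    Attributes
    ----------
    pgr_b : float
        Base plant growth rate for ear biomass accumulation
        (g plant^-1 d^-1); EB is zero at or below this PGR.
    is_eb : float
        Initial slope of the EB-vs-PGR response (g EB per g plant^-1 d^-1).
    c_eb : float
        Curvature of the EB-vs-PGR hyperbola (g plant^-1 d^-1)^-1;
        0 gives a straight line.
    eb_b : float
        Base ear biomass for initial kernel set (g).
    is_kn : float
        Initial slope of the KNP-vs-EB response (kernels per g EB).
    c_kn : float
        Curvature of the KNP-vs-EB hyperbola (g EB)^-1.
    """

    pgr_b: float
    is_eb: float
    c_eb: float
    eb_b: float
    is_kn: float
    c_kn: float

    def __post_init__(self) -> None:
        if self.pgr_b < 0 or self.eb_b < 0:
            raise ValueError("base thresholds pgr_b and eb_b must be >= 0")
        if self.is_eb <= 0 or self.is_kn <= 0:
            raise ValueError("initial slopes is_eb and is_kn must be > 0")
        if self.c_eb < 0 or self.c_kn < 0:
            raise ValueError("curvatures c_eb and c_kn must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeCoefficients":
        return cls(**{k: float(d[k]) for k in
                      ("pgr_b", "is_eb", "c_eb", "eb_b", "is_kn", "c_kn")})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GenotypeCoefficients":
        return cls.from_dict(json.loads(s))


#: Published coefficients for four commercial maize hybrids (H1-H4), used
#: as generating truth in simulations and parameter-recovery checks.
REFERENCE_HYBRIDS: dict[str, GenotypeCoefficients] = {
    "H1": GenotypeCoefficients(0.13, 14.5, 0.17, 11.2, 40.8, 0.04),
    "H2": GenotypeCoefficients(0.52, 11.9, 0.20, 9.2, 105.0, 0.15),
    "H3": GenotypeCoefficients(1.00, 31.6, 0.52, 16.5, 58.0, 0.06),
    "H4": GenotypeCoefficients(0.24, 13.3, 0.08, 12.2, 56.1, 0.07),
}


def _hyperbola(x: np.ndarray, base: float, slope: float, curv: float) -> np.ndarray:
    """Saturating hyperbola with threshold: slope*(x-b)/(1+curv*(x-b)), 0 below b."""
    dx = np.maximum(0.0, np.asarray(x, dtype=float) - base)
    return slope * dx / (1.0 + curv * dx)


def ear_biomass_forward(pgr, c: GenotypeCoefficients):
    """Ear biomass (g) accumulated by 15 d after anthesis at a given PGR.

    Zero at or below ``c.pgr_b``; continuous at the break.  Accepts scalars
    or arrays.
    """
    out = _hyperbola(pgr, c.pgr_b, c.is_eb, c.c_eb)
    return float(out) if np.isscalar(pgr) else out


def kernel_number_forward(eb, c: GenotypeCoefficients):
    """Kernel number per plant at a given ear biomass (g).

    Zero at or below ``c.eb_b``; continuous at the break.
    """
    eb_arr = np.asarray(eb, dtype=float)
    if np.any(eb_arr < 0):
        raise ValueError("ear biomass must be >= 0")
    out = _hyperbola(eb_arr, c.eb_b, c.is_kn, c.c_kn)
    return float(out) if np.isscalar(eb) else out


def plateau(c: GenotypeCoefficients) -> tuple[float, float]:
    """Asymptotic maxima (eb_max, knp_max) = (is_eb/c_eb, is_kn/c_kn).

    A zero curvature means the curve is linear and unbounded; the
    corresponding plateau is returned as ``inf``.
    """
    eb_max = c.is_eb / c.c_eb if c.c_eb > 0 else float("inf")
    knp_max = c.is_kn / c.c_kn if c.c_kn > 0 else float("inf")
    return eb_max, knp_max


@dataclass
class FitResult:
    """Outcome of a two-stage kernel-set model fit."""

    coefficients: GenotypeCoefficients
    r_squared_eb: float
    r_squared_kn: float
    n_points: int
    converged: bool
    residual_ss: float


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _stage_starts(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                  n_restarts: int) -> list[np.ndarray]:
    """Heuristic start + jittered restarts for one hyperbola stage.

    base <- 0.9 * smallest x with y > 0; slope <- secant slope of the
    lowest-x third of positive-y points; curvature <- slope / plateau guess,
    the plateau guessed from the top decile of y.
    """
    pos = y > 0
    if pos.sum() == 0:
        raise ValueError("all responses are zero: stage not identifiable")
    x_pos, y_pos = x[pos], y[pos]
    order = np.argsort(x_pos)
    x_s, y_s = x_pos[order], y_pos[order]
    base0 = 0.9 * x_s[0]
    k = max(2, len(x_s) // 3)
    dx = x_s[k - 1] - base0
    slope0 = y_s[:k].max() / dx if dx > 0 else 1.0
    slope0 = max(slope0, 1e-3)
    plateau0 = max(np.quantile(y_pos, 0.9), 1e-6)
    curv0 = slope0 / plateau0
    starts = [np.array([base0, slope0, curv0]), np.array([0.0, slope0, 1e-6])]
    for _ in range(n_restarts):
        jit = rng.lognormal(mean=0.0, sigma=0.4, size=3)
        starts.append(np.array([base0 * jit[0], slope0 * jit[1], curv0 * jit[2]]))
    return starts


def _fit_stage(x: np.ndarray, y: np.ndarray, starts: Sequence[np.ndarray],
               upper_base: float) -> tuple[np.ndarray, float, bool]:
    """Bound-constrained least squares on one hyperbola, best of all starts."""

    def resid(theta: np.ndarray) -> np.ndarray:
        return _hyperbola(x, *theta) - y

    lower = np.array([0.0, 1e-8, 0.0])
    upper = np.array([upper_base, 1e5, 1e3])
    best_theta, best_ss, ok = None, np.inf, False
    for t0 in starts:
        t0 = np.clip(t0, lower + 1e-12, upper - 1e-12)
        try:
            sol = least_squares(resid, t0, bounds=(lower, upper),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # numerical failure on one start is not fatal
            continue
        ss = float(2.0 * sol.cost)
        if ss < best_ss:
            best_theta, best_ss, ok = sol.x, ss, bool(sol.success)
    if best_theta is None:
        raise RuntimeError("optimizer failed from every start")
    return best_theta, best_ss, ok


def fit_kernelset(pgr, eb, knp, init: GenotypeCoefficients | None = None,
                  n_restarts: int = 5, restart_seed: int = 1234) -> FitResult:
    """Two-stage fit of the kernel-set model to per-plant observations.

    Stage 1 fits the EB-vs-PGR hyperbola, stage 2 the KNP-vs-EB hyperbola,
    each by bound-constrained least squares (bounds given by the coefficient
    invariants) from a heuristic start plus ``n_restarts`` jittered
    restarts; the lowest residual sum of squares wins.

    Parameters
    ----------
    pgr, eb, knp : array-like
        Matched per-plant plant growth rate (g plant^-1 d^-1), ear biomass
        (g) and kernel number observations.
    init : GenotypeCoefficients, optional
        An extra user-supplied starting point.

    Raises
    ------
    ValueError
        Fewer than 8 points, or all ear-biomass values zero
        (non-identifiable).
    """
    pgr = np.asarray(pgr, dtype=float)
    eb = np.asarray(eb, dtype=float)
    knp = np.asarray(knp, dtype=float)
    if not (len(pgr) == len(eb) == len(knp)):
        raise ValueError("pgr, eb and knp must have equal length")
    if len(pgr) < 8:
        raise ValueError("at least 8 points are required for identifiability")
    if np.all(eb <= 0):
        raise ValueError("all ear-biomass values are zero: model not identifiable")

    rng = np.random.default_rng(restart_seed)

    starts1 = _stage_starts(pgr, eb, rng, n_restarts)
    if init is not None:
        starts1.append(np.array([init.pgr_b, init.is_eb, init.c_eb]))
    theta1, ss1, ok1 = _fit_stage(pgr, eb, starts1, upper_base=float(pgr.max()))

    starts2 = _stage_starts(eb, knp, rng, n_restarts)
    if init is not None:
        starts2.append(np.array([init.eb_b, init.is_kn, init.c_kn]))
    theta2, ss2, ok2 = _fit_stage(eb, knp, starts2, upper_base=float(eb.max()))

    coefs = GenotypeCoefficients(
        pgr_b=float(theta1[0]), is_eb=float(theta1[1]), c_eb=float(theta1[2]),
        eb_b=float(theta2[0]), is_kn=float(theta2[1]), c_kn=float(theta2[2]))
    r2_eb = _r_squared(eb, _hyperbola(pgr, *theta1))
    r2_kn = _r_squared(knp, _hyperbola(eb, *theta2))
    converged = bool(ok1 and ok2)
    if not converged:
        logger.warning("kernel-set fit did not fully converge "
                       "(stage1=%s stage2=%s)", ok1, ok2)
    return FitResult(coefficients=coefs, r_squared_eb=r2_eb,
                     r_squared_kn=r2_kn, n_points=len(pgr),
                     converged=converged, residual_ss=float(ss1 + ss2))
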