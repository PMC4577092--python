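"""Saturation and log-logistic dose-response fits of FP titration data.

Two fit equations, applied to polarization changes ΔP = FP − FP(free probe):

* hyperbolic saturation   ΔP = ΔPmax · x / (Kd + x)          (protein titration)
* log-logistic            ΔP = ΔPmax / (1 + 10^((logx0 − X)·p)),  X = log10 x
                          (competitor/compound dose series; IC50 = 10^logx0)

The saturation form ignores probe depletion, so on data where probe
concentration is comparable to Kd it returns an *apparent* Kd biased high
relative to the exact mass-balance equilibrium; that is deliberate — it is the
standard simplified analysis — and the bias is characterized in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationPoint",
    "SaturationFit",
    "LogisticFit",
    "fit_saturation",
    "fit_logistic",
    "delta_p",
    "logistic_model",
    "saturation_model",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: titrant concentration (nM or µM) and ΔP (mP)."""

    x: float
    delta_p: float

    def __post_init__(self) -> None:
        if self.x < 0 or not math.isfinite(self.x):
            raise ValueError(f"x must be finite and >= 0, got {self.x}")
        if not math.isfinite(self.delta_p):
            raise ValueError("delta_p must be finite")


@dataclass(frozen=True)
class SaturationFit:
    kd: float
    delta_p_max: float
    kd_se: float
    delta_p_max_se: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class LogisticFit:
    delta_p_max: float
    log_x0: float
    p: float
    delta_p_max_se: float
    log_x0_se: float
    p_se: float
    rss: float
    converged: bool
    x_unit: str = "nM"

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_x0


def saturation_model(x, kd, delta_p_max):
    x = np.asarray(x, dtype=float)
    return delta_p_max * x / (kd + x)


def logistic_model(x, delta_p_max, log_x0, p):
    x = np.asarray(x, dtype=float)
    X = np.log10(x)
    return delta_p_max / (1.0 + 10.0 ** ((log_x0 - X) * p))


def delta_p(fp_well: float, fp_free_reference: float) -> float:
    """ΔP of a well relative to the free-probe reference polarization."""
    if not (math.isfinite(fp_well) and math.isfinite(fp_free_reference)):
        raise ValueError("FP values must be finite")
    return fp_well - fp_free_reference


def _standard_errors(res, n_obs: int) -> np.ndarray:
    """Asymptotic parameter SEs from the least-squares Jacobian."""
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        JTJ = res.jac.T @ res.jac
        cov = np.linalg.inv(JTJ) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)


def _as_arrays(points: Sequence[TitrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.delta_p for p in points], dtype=float)
    return x, y


def fit_saturation(points: Sequence[TitrationPoint]) -> SaturationFit:
    """Least-squares fit of ΔP = ΔPmax·x/(Kd+x).

    Requires >= 4 points with >= 2 distinct nonzero concentrations.  Analytic
    starting values: ΔPmax from the largest ΔP, Kd from the concentration
    nearest half-max.  A degenerate signal (all ΔP ~ 0) or optimizer failure is
    returned flagged ``converged=False``, never silently.
    """
    x, y = _as_arrays(points)
    if len(points) < 4 or len(set(x[x > 0])) < 2:
        raise ValueError(
            "fit_saturation needs >= 4 points with >= 2 distinct nonzero x"
        )
    ymax = float(np.max(y))
    yspan = float(np.max(y) - np.min(y))
    if yspan <= 1e-12 or ymax <= 0:
        return SaturationFit(np.nan, np.nan, np.nan, np.nan, float(np.sum(y**2)), False)

    half = ymax / 2.0
    kd0 = float(np.interp(half, np.sort(y), x[np.argsort(y)]))
    kd0 = kd0 if kd0 > 0 else float(np.median(x[x > 0]))

    def resid(theta):
        return saturation_model(x, *theta) - y

    res = least_squares(
        resid,
        x0=[kd0, ymax],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    se = _standard_errors(res, len(points))
    kd, dpmax = res.x
    ok = bool(res.success and kd > 0 and dpmax > 0 and np.isfinite(se).all())
    return SaturationFit(
        kd=float(kd),
        delta_p_max=float(dpmax),
        kd_se=float(se[0]),
        delta_p_max_se=float(se[1]),
        rss=float(2.0 * res.cost),
        converged=ok,
    )


def fit_logistic(points: Sequence[TitrationPoint], x_unit: str = "nM") -> LogisticFit:
    """Least-squares fit of ΔP = ΔPmax/(1 + 10^((logx0 − X)·p)), X = log10(x).

    Requires >= 5 points with positive concentrations spanning >= 2 decades
    (zero-concentration points are excluded: X is undefined there).  The Hill
    slope ``p`` may take either sign: positive for a response that grows with
    dose, negative for displacement read as a falling ΔP.  IC50 is exposed as
    ``10**log_x0`` in the unit the concentrations were supplied in.
    """
    x, y = _as_arrays(points)
    pos = x > 0
    x, y = x[pos], y[pos]
    if len(x) < 5:
        raise ValueError("fit_logistic needs >= 5 points with x > 0")
    X = np.log10(x)
    if X.max() - X.min() < 2.0:
        raise ValueError("fit_logistic needs doses spanning >= 2 log-decades")
    yspan = float(np.max(y) - np.min(y))
    if yspan <= 1e-12:
        return LogisticFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            float(np.sum((y - y.mean()) ** 2)), False, x_unit,
        )

    # direction of response fixes the sign of the starting Hill slope
    rising = np.corrcoef(X, y)[0, 1] >= 0
    dpmax0 = float(np.max(np.abs(y))) or 1.0
    half = 0.5 * (np.max(y) + np.min(y))
    order = np.argsort(y)
    logx0_0 = float(np.interp(half, y[order], X[order]))
    p0 = 1.0 if rising else -1.0

    def resid(theta):
        return logistic_model(x, *theta) - y

    res = least_squares(
        resid,
        x0=[dpmax0, logx0_0, p0],
        bounds=([-np.inf, X.min() - 3, -50.0], [np.inf, X.max() + 3, 50.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    se = _standard_errors(res, len(x))
    dpmax, logx0, slope = res.x
    ok = bool(
        res.success
        and abs(slope) > 1e-6
        and np.isfinite(se).all()
        # half-max dose inside (or near) the tested range, else unidentified
        and (X.min() - 2.0) <= logx0 <= (X.max() + 2.0)
    )
    return LogisticFit(
        delta_p_max=float(dpmax),
        log_x0=float(logx0),
        p=float(slope),
        delta_p_max_se=float(se[0]),
        log_x0_se=float(se[1]),
        p_se=float(se[2]),
        rss=float(2.0 * res.cost),
        converged=ok,
        x_unit=x_unit,
    )
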