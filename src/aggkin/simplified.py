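"""Simplified pseudo-first-order protocol.

At a single concentration the branched mechanism reduces to effective
first-order loss of monomer, observed as a saturating-exponential growth
of the total aggregate fraction:

    f_agg(t) = f0 + (1 - f0) * (1 - exp(-k_app * t))

(with the linear small-extent form ``f0 + k_app * t`` as its limit).  The
shortcut protocol fits this form per temperature at a few low temperatures
(e.g. 25/35/40/45 degC) where only the chemical-modification (LT) branch
is active, places the apparent rates on an Arrhenius line, and
extrapolates to the storage temperature.  A curvature diagnostic warns
when the included temperatures reach into the unfolding-driven (HT)
regime, where a single Arrhenius line no longer holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .fitting import DegenerateFitWarning
from .mechanism import GAS_CONSTANT_KCAL, T_REF_K, InvalidParameterError

__all__ = [
    "ApparentRateSeries",
    "ArrheniusLine",
    "fit_pseudo_first_order",
    "arrhenius_regress",
    "predict_simplified",
]

_KELVIN = 273.15


@dataclass
class ApparentRateSeries:
    """Per-temperature apparent rates with LT-only inclusion flags."""

    temperatures: tuple[float, ...]          # degC
    k_app: tuple[float, ...]                 # h^-1
    stderr: tuple[float, ...] | None = None
    lt_only: tuple[bool, ...] | None = None  # default: include all

    def __post_init__(self) -> None:
        if len(self.k_app) != len(self.temperatures):
            raise InvalidParameterError("k_app and temperatures differ in length")
        if any(k < 0 for k in self.k_app):
            raise InvalidParameterError("k_app must be >= 0")
        if self.lt_only is None:
            self.lt_only = tuple(True for _ in self.temperatures)


@dataclass
class ArrheniusLine:
    """OLS line of ln k_app on 1/T_K, reported at the 5 degC reference."""

    ln_k_ref: float              # ln k_app at 278.15 K
    E_a_app: float               # kcal/mol
    residuals: np.ndarray
    curvature_flag: bool
    curvature_stat: float        # quadratic coefficient in 1/T (convex > 0)

    def k_app(self, T: float) -> float:
        """Extrapolated apparent rate at temperature T (degC)."""
        t_k = T + _KELVIN
        return math.exp(
            self.ln_k_ref
            - (self.E_a_app / GAS_CONSTANT_KCAL) * (1.0 / t_k - 1.0 / T_REF_K)
        )


def fit_pseudo_first_order(
    times: Sequence[float],
    f_agg: Sequence[float],
    fit_f0: bool = True,
) -> tuple[float, float]:
    """Fit the saturating-exponential model to an aggregate time series.

    ``f_agg`` are proportions in [0, 1).  Returns ``(k_app, stderr)``.
    When ``fit_f0`` is False the baseline is fixed at the first point.
    Decreasing or flat series return ``(0, nan)`` with a warning.
    """
    t = np.asarray(times, float)
    f = np.asarray(f_agg, float)
    if len(t) < 3:
        raise InvalidParameterError("need >= 3 points")
    if np.any((f < 0) | (f >= 1)):
        raise InvalidParameterError("f_agg must be proportions in [0, 1)")
    if f[-1] <= f[0] or f.max() - f[0] <= 0:
        warnings.warn("flat or decreasing aggregate series; k_app set to 0",
                      DegenerateFitWarning, stacklevel=2)
        return 0.0, float("nan")

    span = f.max() - f[0]
    dt = t[-1] - t[0] if t[-1] > t[0] else 1.0
    k0 = max(span / dt / max(1.0 - f[0], 1e-9), 1e-12)

    if fit_f0:
        def model(tt, k, f0):
            return f0 + (1.0 - f0) * (-np.expm1(-k * tt))
        p0, lo, hi = [k0, max(f[0], 0.0)], [0.0, 0.0], [np.inf, 1.0 - 1e-12]
    else:
        f0_fixed = f[0]

        def model(tt, k):
            return f0_fixed + (1.0 - f0_fixed) * (-np.expm1(-k * tt))
        p0, lo, hi = [k0], [0.0], [np.inf]

    try:
        popt, pcov = curve_fit(model, t, f, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError:
        warnings.warn("pseudo-first-order fit did not converge; k_app set to 0",
                      DegenerateFitWarning, stacklevel=2)
        return 0.0, float("nan")
    k = float(popt[0])
    var = float(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else float("nan")
    return k, math.sqrt(var) if var >= 0 else float("nan")


def arrhenius_regress(series: ApparentRateSeries) -> ArrheniusLine:
    """OLS of ln k_app on 1/T_K over the LT-only temperatures.

    With three or more points a convexity diagnostic is computed: positive
    residuals at both temperature extremes with a negative interior
    residual (equivalently a positive quadratic coefficient in 1/T) mark
    the biphasic signature of HT-pathway contamination.
    """
    mask = [bool(m) and k > 0
            for m, k in zip(series.lt_only, series.k_app)]
    temps = [T for T, m in zip(series.temperatures, mask) if m]
    ks = [k for k, m in zip(series.k_app, mask) if m]
    if len(temps) < 2:
        raise InvalidParameterError(
            "need >= 2 usable (LT-only, k_app > 0) temperatures"
        )
    inv_t = np.array([1.0 / (T + _KELVIN) for T in temps])
    ln_k = np.log(ks)
    order = np.argsort(inv_t)
    inv_t, ln_k = inv_t[order], ln_k[order]

    slope, intercept = np.polyfit(inv_t, ln_k, 1)
    resid = ln_k - (intercept + slope * inv_t)
    e_a = -slope * GAS_CONSTANT_KCAL
    ln_k_ref = intercept + slope / T_REF_K

    curv_stat = 0.0
    flag = False
    if len(temps) >= 3:
        curv_stat = float(np.polyfit(inv_t, ln_k, 2)[0])
        interior = resid[1:-1]
        flag = bool(resid[0] > 0 and resid[-1] > 0 and interior.min() < 0
                    and curv_stat > 0)
        if flag:
            warnings.warn(
                "convex residual pattern in the Arrhenius regression: the "
                "included temperatures likely reach into the HT regime",
                UserWarning, stacklevel=2,
            )
    return ArrheniusLine(float(ln_k_ref), float(e_a), resid, flag, curv_stat)


def predict_simplified(
    line: ArrheniusLine,
    T_storage: float,
    f0: float,
    eval_times: Sequence[float],
) -> np.ndarray:
    """Aggregate proportions at the storage temperature from the line."""
    if not (math.isfinite(line.ln_k_ref) and math.isfinite(line.E_a_app)):
        raise InvalidParameterError("Arrhenius line has nonfinite coefficients")
    k = line.k_app(T_storage)
    t = np.asarray(eval_times, float)
    return f0 + (1.0 - f0) * (-np.expm1(-k * t))
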