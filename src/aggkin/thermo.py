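"""Thermodynamic stability: urea denaturation, Gibbs-Helmholtz curves,
stability-kinetics linkage, and the aggregation phase space.

The apparent free energy of denaturation ``dG_d`` is obtained from urea
unfolding curves by the linear-extrapolation model (2- or 3-state, first
transition).  Stability enters the aggregation kinetics twice:

* it sets the initial native / non-native split through
  ``K = exp(-dG_d(T) / RT)`` (the non-native mass seeds the HT
  intermediate D), the dominant effect for marginally stable molecules
  (dG_d below ~3 kcal/mol);
* it modulates the LT initiation rate constant through a log-linear
  linkage ``ln k_I = a + b * dG_d`` (b < 0), the residual effect for
  stable molecules.

The phase space maps, over a (temperature x stability) lattice, which
pathway dominates when total dimers first reach 1 %, the apparent rate,
and the time-to-1 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .mechanism import (
    GAS_CONSTANT_KCAL,
    ArrheniusParam,
    Condition,
    InvalidParameterError,
    KineticScheme,
    ParameterSet,
    StiffnessError,
    build_scheme,
    initial_state,
    simulate_fractions,
)

__all__ = [
    "DenaturationCurve",
    "DenaturationFit",
    "GibbsHelmholtzParams",
    "LinkageModel",
    "PhaseSpaceGrid",
    "fit_denaturation",
    "simulate_denaturation",
    "dg_of_temperature",
    "anchored_gibbs_helmholtz",
    "nonnative_fraction",
    "fit_linkage",
    "default_linkage",
    "phase_space",
]

_KELVIN = 273.15
_T25_K = 298.15


# ---------------------------------------------------------------------------
# Urea denaturation (linear extrapolation model)
# ---------------------------------------------------------------------------

@dataclass
class DenaturationCurve:
    """Urea unfolding curve: concentrations (M) vs fluorescence signal."""

    urea: np.ndarray              # M, within [0, 9.5]
    signal: np.ndarray            # arbitrary units
    temperature: float = 25.0     # degC

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, float)
        self.signal = np.asarray(self.signal, float)
        if len(self.urea) < 8:
            raise InvalidParameterError("need >= 8 points spanning both baselines")
        if np.any((self.urea < 0) | (self.urea > 9.5)):
            raise InvalidParameterError("urea concentrations must lie in [0, 9.5] M")


@dataclass
class DenaturationFit:
    model: str                    # "2state" | "3state"
    dG_d: float                   # kcal/mol, first transition
    m_value: float                # kcal/mol/M
    baselines: dict
    midpoints: tuple[float, ...]  # M
    resid_sd: float

    def __post_init__(self) -> None:
        if self.m_value <= 0:
            raise InvalidParameterError("m_value must be positive")


def _rt(temperature: float) -> float:
    return GAS_CONSTANT_KCAL * (temperature + _KELVIN)


def _two_state_signal(u, dG, m, bN, sN, bD, sD, rt):
    k = np.exp(-(dG - m * u) / rt)
    fD = k / (1.0 + k)
    return (bN + sN * u) * (1.0 - fD) + (bD + sD * u) * fD


def _three_state_signal(u, dG1, m1, dG2, m2, bN, sN, bI, bD, sD, rt):
    k1 = np.exp(-(dG1 - m1 * u) / rt)
    k2 = np.exp(-(dG2 - m2 * u) / rt)
    z = 1.0 + k1 + k1 * k2
    pN, pI, pD = 1.0 / z, k1 / z, k1 * k2 / z
    return (bN + sN * u) * pN + bI * pI + (bD + sD * u) * pD


def simulate_denaturation(
    urea: Sequence[float],
    dG_d: float,
    m_value: float,
    baselines: dict | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    temperature: float = 25.0,
    second_transition: tuple[float, float] | None = None,
) -> DenaturationCurve:
    """Synthetic urea curve for testing and calibration (no real data).

    ``second_transition=(dG2, m2)`` switches to the 3-state signal.
    """
    u = np.asarray(urea, float)
    b = {"bN": 1.0, "sN": 0.0, "bD": 0.0, "sD": 0.0, "bI": 0.5}
    if baselines:
        b.update(baselines)
    rt = _rt(temperature)
    if second_transition is None:
        sig = _two_state_signal(u, dG_d, m_value, b["bN"], b["sN"],
                                b["bD"], b["sD"], rt)
    else:
        dG2, m2 = second_transition
        sig = _three_state_signal(u, dG_d, m_value, dG2, m2, b["bN"], b["sN"],
                                  b["bI"], b["bD"], b["sD"], rt)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    return DenaturationCurve(u, sig, temperature)


def fit_denaturation(curve: DenaturationCurve, model: str = "2state") -> DenaturationFit:
    """Least-squares linear-extrapolation fit; returns the first transition.

    Raises when the data contain no resolvable transition (baseline-only,
    monotone-linear signal).
    """
    u, y = curve.urea, curve.signal
    rt = _rt(curve.temperature)
    span = float(y.max() - y.min())
    # linear-only comparison fit for transition detection
    line = np.polyfit(u, y, 1)
    line_sd = float(np.std(y - np.polyval(line, u)))
    if span <= 0:
        raise InvalidParameterError("flat signal: no resolvable transition")

    # crude midpoint guess: crossing of the half-amplitude level
    y_mid = 0.5 * (y[np.argsort(u)[:2]].mean() + y[np.argsort(u)[-2:]].mean())
    mid_guess = float(u[np.argmin(np.abs(y - y_mid))])
    mid_guess = min(max(mid_guess, 0.5), 9.0)

    if model == "2state":
        def f(uu, dG, m, bN, sN, bD, sD):
            return _two_state_signal(uu, dG, m, bN, sN, bD, sD, rt)
        p0 = [2.0 * mid_guess, 2.0, y[np.argmin(u)], 0.0, y[np.argmax(u)], 0.0]
        lo = [0.01, 0.01, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [50.0, 20.0, np.inf, np.inf, np.inf, np.inf]
    elif model == "3state":
        def f(uu, dG1, m1, dG2, m2, bN, sN, bI, bD, sD):
            return _three_state_signal(uu, dG1, m1, dG2, m2, bN, sN, bI, bD, sD, rt)
        p0 = [1.5 * mid_guess, 2.0, 2.0 * mid_guess, 2.0,
              y[np.argmin(u)], 0.0, 0.5 * (y.min() + y.max()),
              y[np.argmax(u)], 0.0]
        lo = [0.01, 0.01, 0.01, 0.01] + [-np.inf] * 5
        hi = [50.0, 20.0, 50.0, 20.0] + [np.inf] * 5
    else:
        raise InvalidParameterError("model must be '2state' or '3state'")

    try:
        popt, _ = curve_fit(f, u, y, p0=p0, bounds=(lo, hi), maxfev=50000)
    except RuntimeError as exc:
        raise InvalidParameterError(f"denaturation fit failed: {exc}") from exc

    resid_sd = float(np.std(y - f(u, *popt)))
    dG, m = float(popt[0]), float(popt[1])
    mid = dG / m
    if not (u.min() < mid < u.max()):
        raise InvalidParameterError(
            "no resolvable transition: fitted midpoint outside the urea range"
        )
    if line_sd > 0 and resid_sd > 0.75 * line_sd and span < 10 * resid_sd:
        raise InvalidParameterError(
            "no resolvable transition: model does not improve on a straight line"
        )

    if model == "2state":
        baselines = dict(zip(("bN", "sN", "bD", "sD"), map(float, popt[2:])))
        mids: tuple[float, ...] = (mid,)
    else:
        baselines = dict(zip(("bN", "sN", "bI", "bD", "sD"), map(float, popt[4:])))
        mids = (mid, float(popt[2] / popt[3]))
    return DenaturationFit(model, dG, m, baselines, mids, resid_sd)


# ---------------------------------------------------------------------------
# Gibbs-Helmholtz stability curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GibbsHelmholtzParams:
    """Protein stability-curve parameters.  Defaults are synthetic values
    typical of an IgG first transition, not measurements."""

    T_m: float = 70.0             # degC
    dH_m: float = 150.0           # kcal/mol
    dC_p: float = 2.0             # kcal/mol/K

    def __post_init__(self) -> None:
        if self.dH_m <= 0:
            raise InvalidParameterError("dH_m must be positive")
        if self.dC_p < 0:
            raise InvalidParameterError("dC_p must be >= 0")


def dg_of_temperature(gh: GibbsHelmholtzParams, T: float) -> float:
    """Gibbs-Helmholtz free energy of denaturation at T (degC), kcal/mol.

    ``dG(T) = dH_m (1 - T/T_m) - dC_p [(T_m - T) + T ln(T/T_m)]`` with
    absolute temperatures; exactly zero at ``T = T_m``, concave with a
    maximum below ``T_m`` when ``dC_p > 0`` (cold denaturation).
    """
    if not (-_KELVIN < T <= 150.0):
        raise InvalidParameterError("temperature out of supported range")
    t_k = T + _KELVIN
    tm_k = gh.T_m + _KELVIN
    return (gh.dH_m * (1.0 - t_k / tm_k)
            - gh.dC_p * ((tm_k - t_k) + t_k * math.log(t_k / tm_k)))


def anchored_gibbs_helmholtz(
    gh: GibbsHelmholtzParams, dG_25: float
) -> GibbsHelmholtzParams:
    """Stability curve anchored so that ``dG(25 degC) = dG_25``.

    ``dH_m`` and ``dC_p`` are kept and the melting temperature is solved
    for: stability differences between formulations track their melting
    temperatures, so lowering the 25 degC stability lowers ``T_m`` and the
    unfolding onset together (the basis of the LT/HT switch moving with
    stability).  ``dG_25 = 0`` maps to ``T_m = 25 degC``.
    """
    from scipy.optimize import brentq

    if dG_25 < 0:
        raise InvalidParameterError("dG_25 must be >= 0")
    if dG_25 == 0:
        return GibbsHelmholtzParams(25.0, gh.dH_m, gh.dC_p)

    def resid(tm_c: float) -> float:
        return dg_of_temperature(
            GibbsHelmholtzParams(tm_c, gh.dH_m, gh.dC_p), 25.0
        ) - dG_25

    # dG(25) rises with T_m, peaks, then falls (dC_p penalty); use the
    # ascending branch so stability and melting temperature move together.
    scan = np.linspace(25.0 + 1e-6, 149.0, 300)
    vals = np.array([resid(t) for t in scan])
    peak = int(np.argmax(vals))
    if vals[peak] < 0:
        raise InvalidParameterError(
            f"dG(25 degC) = {dG_25} not reachable with dH_m = {gh.dH_m}, "
            f"dC_p = {gh.dC_p}"
        )
    tm = brentq(resid, scan[0], scan[peak], xtol=1e-10)
    return GibbsHelmholtzParams(float(tm), gh.dH_m, gh.dC_p)


def nonnative_fraction(dG_d: float, T: float) -> float:
    """Equilibrium non-native population ``K/(1+K)``, ``K = exp(-dG/RT)``."""
    if not math.isfinite(dG_d):
        raise InvalidParameterError("dG_d must be finite")
    k = math.exp(-dG_d / _rt(T))
    return k / (1.0 + k)


# ---------------------------------------------------------------------------
# Stability-kinetics linkage
# ---------------------------------------------------------------------------

@dataclass
class LinkageModel:
    """Log-linear link ``ln k_I(5 degC) = intercept + slope * dG_d``."""

    intercept: float
    slope: float
    r_squared: float = float("nan")
    stderr_slope: float = float("nan")

    def k_I(self, dG_d: float) -> float:
        return math.exp(self.intercept + self.slope * dG_d)


def fit_linkage(pairs: Sequence[tuple[float, float]]) -> LinkageModel:
    """OLS of ln k_I on dG_d across formulations; slope expected negative."""
    if len(pairs) < 3:
        raise InvalidParameterError("need >= 3 (dG_d, k_I) pairs")
    dg = np.array([p[0] for p in pairs], float)
    ln_k = np.log([p[1] for p in pairs])
    slope, intercept = np.polyfit(dg, ln_k, 1)
    pred = intercept + slope * dg
    ss_res = float(np.sum((ln_k - pred) ** 2))
    ss_tot = float(np.sum((ln_k - ln_k.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    n = len(pairs)
    sxx = float(np.sum((dg - dg.mean()) ** 2))
    se = math.sqrt(ss_res / max(n - 2, 1) / sxx) if sxx > 0 else float("nan")
    return LinkageModel(float(intercept), float(slope), r2, se)


def default_linkage() -> LinkageModel:
    """Synthetic linkage calibrated to the mab1like preset: a stable
    molecule (dG_25 = 6 kcal/mol) has the mab1like LT initiation rate and
    every kcal/mol of stability slows LT initiation by exp(0.35)."""
    slope = -0.35
    k_anchor = 2.5e-7
    return LinkageModel(math.log(k_anchor) - slope * 6.0, slope)


# ---------------------------------------------------------------------------
# Aggregation phase space
# ---------------------------------------------------------------------------

@dataclass
class PhaseSpaceGrid:
    """LT/HT dominance and apparent rate over (temperature x stability)."""

    temperatures: np.ndarray      # degC
    dG_25: np.ndarray             # kcal/mol, stability axis at 25 degC
    lt_share: np.ndarray          # (nT, ndG) in [0, 1]; NaN where undefined
    k_app: np.ndarray             # h^-1; NaN where undefined
    t_1pct: np.ndarray            # h to 1 % total dimers; NaN where undefined

    def to_frame(self):
        import pandas as pd

        tt, gg = np.meshgrid(self.temperatures, self.dG_25, indexing="ij")
        return pd.DataFrame({
            "T_C": tt.ravel(), "dG_kcal": gg.ravel(),
            "lt_share": self.lt_share.ravel(),
            "k_app_per_h": self.k_app.ravel(),
            "t1pct_h": self.t_1pct.ravel(),
        })


#: Cap on the time-to-1 %-dimers search: ten years of simulated time.
T1PCT_CAP_H = 87_600.0


def _cell_kinetics(
    scheme: KineticScheme,
    params: ParameterSet,
    cond: Condition,
    n_steps: int = 2000,
) -> tuple[float, float, float] | None:
    """(t at 1 % total dimers, LT share, k_app) for one cell, or None."""
    rates = scheme.rates_at(params, cond.temperature)
    y0 = initial_state(scheme, cond)
    sizes = scheme.sizes
    i_ni, i_d2 = scheme.index("NI"), scheme.index("D2")
    i_n = scheme.index("N")
    t_end = 0.01
    while True:
        eval_t = np.linspace(0.0, t_end, 241)
        steps = n_steps
        while True:
            try:
                frac = simulate_fractions(scheme, rates, cond.m_total, eval_t,
                                          steps, y0=y0.copy())
                break
            except StiffnessError:
                steps *= 4
                if steps > 64 * n_steps:
                    return None
        # fraction columns: [monomer, dimer, trimer, hmw]; f_dimer = NI + D2
        f_dimer = frac[:, 1]
        if f_dimer[-1] >= 1.0:
            j = int(np.argmax(f_dimer >= 1.0))
            t_lo, t_hi = eval_t[j - 1], eval_t[j]
            f_lo, f_hi = f_dimer[j - 1], f_dimer[j]
            t1 = t_lo + (1.0 - f_lo) / (f_hi - f_lo) * (t_hi - t_lo)
            frac_t1 = np.array([np.interp(t1, eval_t, frac[:, c])
                                for c in range(4)])
            # LT share needs species masses, not SEC peaks
            grid_state = _states_at(scheme, rates, y0, t1, steps)
            mass = grid_state * sizes
            agg_mask = np.array([s.name not in ("N", "I", "D")
                                 for s in scheme.species])
            agg_mass = float(mass[agg_mask].sum())
            lt_share = float(mass[i_ni] / agg_mass) if agg_mass > 0 else np.nan
            f_mon = frac_t1[0]
            k_app = -math.log(max(f_mon, 1e-12) / 100.0) / t1 if t1 > 0 else np.nan
            return t1, lt_share, k_app
        if t_end >= T1PCT_CAP_H:
            return None
        t_end = min(t_end * 6.0, T1PCT_CAP_H)


def _states_at(scheme, rates, y0, t1, n_steps) -> np.ndarray:
    """Species molar state at time t1 (Euler, interpolated)."""
    from .mechanism import _propagate_euler

    grid, traj, _ = _propagate_euler(scheme, rates, y0, t1, n_steps)
    return np.array([np.interp(t1, grid, traj[:, s])
                     for s in range(traj.shape[1])])


def phase_space(
    T_axis: Sequence[float],
    dG_axis: Sequence[float],
    ht_params: ParameterSet,
    linkage: LinkageModel | None = None,
    gh: GibbsHelmholtzParams | None = None,
    c_total: float = 50.0,
    scheme: KineticScheme | None = None,
    seed_nonnative: bool = True,
    use_linkage: bool = True,
    molecular_weight: float = 150_000.0,
) -> PhaseSpaceGrid:
    """Aggregation phase space over (temperature x stability-at-25-degC).

    Per cell: the stability curve is anchored so dG(25 degC) equals the
    axis value; the LT initiation rate comes from the linkage (unless
    ``use_linkage`` is off, which freezes it at ``ht_params``); the
    non-native equilibrium population seeds the HT intermediate D (unless
    ``seed_nonnative`` is off); the cell is simulated until total dimers
    reach 1 % (cap ten years).  Cells that never reach 1 % are NaN.
    """
    T_axis = np.asarray(T_axis, float)
    dG_axis = np.asarray(dG_axis, float)
    if np.any((T_axis < 0) | (T_axis > 90)):
        raise InvalidParameterError("temperature axis must lie within [0, 90] degC")
    if np.any((dG_axis < 0) | (dG_axis > 10)):
        raise InvalidParameterError("stability axis must lie within [0, 10] kcal/mol")
    if linkage is None:
        linkage = default_linkage()
    if gh is None:
        gh = GibbsHelmholtzParams()
    if scheme is None:
        scheme = build_scheme(4)

    lt = np.full((len(T_axis), len(dG_axis)), np.nan)
    ka = np.full_like(lt, np.nan)
    t1 = np.full_like(lt, np.nan)
    for jg, dg25 in enumerate(dG_axis):
        gh_j = anchored_gibbs_helmholtz(gh, float(dg25))
        params = ParameterSet(ht_params)
        if use_linkage:
            params["r_I"] = ArrheniusParam(linkage.k_I(float(dg25)),
                                           ht_params["r_I"].E_a)
        for it, temp in enumerate(T_axis):
            dg_t = dg_of_temperature(gh_j, float(temp))
            f_d0 = nonnative_fraction(dg_t, float(temp)) if seed_nonnative else 0.0
            f_d0 = min(f_d0, 1.0 - 1e-12)
            cond = Condition(float(temp), c_total, molecular_weight,
                             {"N": 1.0 - f_d0, "D": f_d0})
            cell = _cell_kinetics(scheme, params, cond)
            if cell is not None:
                t1[it, jg], lt[it, jg], ka[it, jg] = cell
    return PhaseSpaceGrid(T_axis, dG_axis, lt, ka, t1)
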