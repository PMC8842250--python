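"""Global fitting of the branched mechanism to multi-condition SEC studies.

One Arrhenius parameter set is fitted jointly to every (temperature,
concentration) subset of a stability study.  The objective is the
unweighted mean over subsets of the per-subset root-mean-square residual
(in % points) across the fitted observables (monomer, dimer, trimer by
default; the HMW remainder is excluded).  Averaging per subset equalises
sparse low-temperature and dense high-temperature series.

Parameters are optimised as (log10 k_ref, E_a) per reaction under box
bounds by a bound-constrained trust-region least-squares pass (optionally
followed by a quasi-Newton polish of the exact objective), with seeded
multi-start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares, minimize

from .mechanism import (
    ArrheniusParam,
    InvalidParameterError,
    KineticScheme,
    KineticsError,
    ParameterSet,
    simulate_fractions,
)

__all__ = [
    "Subset",
    "StudyDataset",
    "FitResult",
    "FitOptions",
    "DEFAULT_BOUNDS",
    "objective",
    "fit_global",
    "refit",
    "apparent_rate",
    "DegenerateFitWarning",
]

#: Default box bounds: log10 k_ref in [-12, 3], E_a in [0, 200] kcal/mol.
DEFAULT_BOUNDS = {"log10_k": (-12.0, 3.0), "E_a": (0.0, 200.0)}

OBSERVABLE_COLUMNS = {"monomer": 0, "dimer": 1, "trimer": 2, "hmw": 3}


class DegenerateFitWarning(UserWarning):
    """Raised when an apparent-rate fit has no usable signal."""


class FitError(KineticsError):
    """No optimisation start converged."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class Subset:
    """One (temperature, concentration) time series of SEC fractions."""

    temperature: float            # degC
    c_total: float                # mg/mL
    times: np.ndarray             # h, nonnegative
    fractions: np.ndarray         # (n, 4) % [monomer, dimer, trimer, hmw]
    stderr: np.ndarray | None = None   # optional per-point SE, % points
    formulation: str = "default"
    molecular_weight: float = 150_000.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.fractions = np.asarray(self.fractions, float)
        if self.times.ndim != 1 or len(self.times) < 3:
            raise InvalidParameterError("each subset needs >= 3 time points")
        if np.any(self.times < 0):
            raise InvalidParameterError("times must be nonnegative")
        if self.fractions.shape != (len(self.times), 4):
            raise InvalidParameterError("fractions must be (n_times, 4)")

    @property
    def key(self) -> str:
        return f"{self.temperature:g}C_{self.c_total:g}mgml"

    @property
    def m_total(self) -> float:
        return self.c_total / self.molecular_weight

    def total_aggregate(self) -> np.ndarray:
        """Total aggregate fraction (%) = 100 - monomer peak."""
        return 100.0 - self.fractions[:, 0]


@dataclass
class StudyDataset:
    """A stability study: a collection of (T, c) subsets."""

    subsets: list[Subset]

    def __post_init__(self) -> None:
        if not self.subsets:
            raise InvalidParameterError("dataset has no subsets")

    def __len__(self) -> int:
        return len(self.subsets)

    def get(self, temperature: float, c_total: float) -> Subset:
        for s in self.subsets:
            if s.temperature == temperature and s.c_total == c_total:
                return s
        raise KeyError((temperature, c_total))

    def perturbed(self, sigma, rng: np.random.Generator) -> "StudyDataset":
        """Copy with Gaussian noise added to every fraction, rows clipped at
        zero and renormalised to 100 % (SEC closure)."""
        out = []
        for s in self.subsets:
            if sigma is None:
                sd = s.stderr if s.stderr is not None else 0.1
            else:
                sd = sigma
            frac = s.fractions + rng.normal(0.0, 1.0, s.fractions.shape) * sd
            frac = np.clip(frac, 0.0, None)
            frac = 100.0 * frac / frac.sum(axis=1, keepdims=True)
            out.append(Subset(s.temperature, s.c_total, s.times.copy(), frac,
                              s.stderr, s.formulation, s.molecular_weight))
        return StudyDataset(out)


@dataclass
class FitResult:
    """Optimised parameters plus diagnostics."""

    params: ParameterSet
    objective: float
    per_subset_rms: dict[str, float]
    converged: bool
    n_evaluations: int
    free_labels: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        mean_rms = float(np.mean(list(self.per_subset_rms.values())))
        if abs(self.objective - mean_rms) > 1e-12 * max(1.0, mean_rms):
            raise InvalidParameterError(
                "objective must equal the mean of per-subset RMS values"
            )

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "per_subset_rms": self.per_subset_rms,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "free_labels": list(self.free_labels),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 8
    seed: int = 0
    n_steps: int = 3000
    observables: tuple[str, ...] = ("monomer", "dimer", "trimer")
    max_nfev: int | None = None
    polish: bool = False


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _subset_prediction(
    scheme: KineticScheme, params: ParameterSet, subset: Subset, n_steps: int
) -> np.ndarray:
    rates = scheme.rates_at(params, subset.temperature)
    t = subset.times
    if t[0] != 0.0:
        t = np.insert(t, 0, 0.0)
        return simulate_fractions(scheme, rates, subset.m_total, t, n_steps)[1:]
    return simulate_fractions(scheme, rates, subset.m_total, t, n_steps)


def subset_rms(
    scheme: KineticScheme,
    params: ParameterSet,
    subset: Subset,
    n_steps: int = 3000,
    observables: Sequence[str] = ("monomer", "dimer", "trimer"),
) -> float:
    """RMS residual (% points) of one subset over the fitted observables."""
    cols = [OBSERVABLE_COLUMNS[o] for o in observables]
    pred = _subset_prediction(scheme, params, subset, n_steps)
    res = (pred - subset.fractions)[:, cols]
    return float(np.sqrt(np.mean(res ** 2)))


def objective(
    params: ParameterSet,
    dataset: StudyDataset,
    scheme: KineticScheme,
    n_steps: int = 3000,
    observables: Sequence[str] = ("monomer", "dimer", "trimer"),
) -> float:
    """Mean over (T, c) subsets of the per-subset RMS residual (% points)."""
    rms = []
    for s in dataset.subsets:
        try:
            rms.append(subset_rms(scheme, params, s, n_steps, observables))
        except KineticsError as exc:
            raise type(exc)(f"subset {s.key}: {exc}") from exc
    return float(np.mean(rms))


# ---------------------------------------------------------------------------
# Parameter vector mapping
# ---------------------------------------------------------------------------

def _x_to_params(
    x: np.ndarray, base: ParameterSet, free: Sequence[str]
) -> ParameterSet:
    out = ParameterSet(base)
    for j, lbl in enumerate(free):
        out[lbl] = ArrheniusParam(10.0 ** x[2 * j], x[2 * j + 1])
    return out


def _params_to_x(params: ParameterSet, free: Sequence[str]) -> np.ndarray:
    x = np.empty(2 * len(free))
    for j, lbl in enumerate(free):
        k = params[lbl].k_ref
        if k <= 0:
            raise InvalidParameterError(
                f"free parameter {lbl} needs k_ref > 0 to fit in log space"
            )
        x[2 * j] = math.log10(k)
        x[2 * j + 1] = params[lbl].E_a
    return x


def _bounds_arrays(bounds: Mapping, n_free: int) -> tuple[np.ndarray, np.ndarray]:
    lk, uk = bounds["log10_k"]
    le, ue = bounds["E_a"]
    lo = np.tile([lk, le], n_free).astype(float)
    hi = np.tile([uk, ue], n_free).astype(float)
    return lo, hi


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class _ResidualModel:
    """Weighted residual vector whose squared norm is the quadratic mean of
    per-subset RMS values; shares the exact objective's minimiser on clean
    data and is used for the fast trust-region pass."""

    def __init__(self, dataset, scheme, base, free, n_steps, observables):
        self.dataset = dataset
        self.scheme = scheme
        self.base = base
        self.free = free
        self.n_steps = n_steps
        self.cols = [OBSERVABLE_COLUMNS[o] for o in observables]
        self.sizes = [len(s.times) * len(self.cols) for s in dataset.subsets]
        self.n_total = sum(self.sizes)
        self.n_eval = 0
        # precomputed Arrhenius machinery: per-label base values, the
        # label index feeding each reaction, per-subset 1/T offsets
        from .mechanism import GAS_CONSTANT_KCAL, T_REF_K

        self.labels = list(scheme.param_labels)
        self.free_idx = [self.labels.index(lbl) for lbl in free]
        self.base_k = np.array([base[lbl].k_ref for lbl in self.labels])
        self.base_ea = np.array([base[lbl].E_a for lbl in self.labels])
        self.rxn_label = np.array(
            [self.labels.index(r.param_label) for r in scheme.reactions]
        )
        self.deltas = np.array([
            (1.0 / (s.temperature + 273.15) - 1.0 / T_REF_K) / GAS_CONSTANT_KCAL
            for s in dataset.subsets
        ])
        self.eval_times = []
        for s in dataset.subsets:
            t = s.times
            self.eval_times.append(np.asarray(t, float))

    def _label_arrays(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = self.base_k.copy()
        ea = self.base_ea.copy()
        for j, li in enumerate(self.free_idx):
            k[li] = 10.0 ** x[2 * j]
            ea[li] = x[2 * j + 1]
        return k, ea

    def residuals(self, x: np.ndarray) -> np.ndarray:
        self.n_eval += 1
        k_lab, ea_lab = self._label_arrays(x)
        chunks = []
        for i, (s, n_s) in enumerate(zip(self.dataset.subsets, self.sizes)):
            rates = (k_lab * np.exp(-ea_lab * self.deltas[i]))[self.rxn_label]
            try:
                pred = simulate_fractions(self.scheme, rates, s.m_total,
                                          self.eval_times[i], self.n_steps)
                res = (pred - s.fractions)[:, self.cols].ravel()
            except KineticsError:
                res = np.full(n_s, 1e3)
            chunks.append(res / math.sqrt(n_s * len(self.sizes)))
        return np.concatenate(chunks)

    def exact_objective(self, x: np.ndarray) -> float:
        self.n_eval += 1
        params = _x_to_params(x, self.base, self.free)
        try:
            return objective(params, self.dataset, self.scheme, self.n_steps,
                             [o for o in OBSERVABLE_COLUMNS
                              if OBSERVABLE_COLUMNS[o] in self.cols])
        except KineticsError:
            return 1e6


def _finish(model, x, dataset, scheme, n_steps, observables, free,
            converged, seed) -> FitResult:
    params = _x_to_params(x, model.base, free)
    rms = {s.key: subset_rms(scheme, params, s, n_steps, observables)
           for s in dataset.subsets}
    return FitResult(
        params=params,
        objective=float(np.mean(list(rms.values()))),
        per_subset_rms=rms,
        converged=converged,
        n_evaluations=model.n_eval,
        free_labels=tuple(free),
        seed=seed,
    )


def refit(
    dataset: StudyDataset,
    scheme: KineticScheme,
    start: ParameterSet,
    free_labels: Sequence[str] | None = None,
    bounds: Mapping | None = None,
    n_steps: int = 3000,
    observables: Sequence[str] = ("monomer", "dimer", "trimer"),
    max_nfev: int | None = None,
) -> FitResult:
    """Single warm-started trust-region refit (no multi-start, no polish).

    Used for the Monte Carlo replicas, which start at the original optimum.
    """
    bounds = bounds or DEFAULT_BOUNDS
    free = tuple(free_labels) if free_labels is not None else tuple(
        lbl for lbl in scheme.param_labels if start[lbl].k_ref > 0
    )
    model = _ResidualModel(dataset, scheme, start, free, n_steps, observables)
    x0 = _params_to_x(start, free)
    lo, hi = _bounds_arrays(bounds, len(free))
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(
        model.residuals, x0, bounds=(lo, hi), method="trf",
        x_scale=np.tile([1.0, 20.0], len(free)),
        ftol=1e-8, xtol=1e-8, gtol=1e-8,
        max_nfev=max_nfev,
    )
    return _finish(model, sol.x, dataset, scheme, n_steps, observables, free,
                   bool(sol.success), None)


def fit_global(
    dataset: StudyDataset,
    scheme: KineticScheme,
    init: ParameterSet,
    bounds: Mapping | None = None,
    options: FitOptions | None = None,
    free_labels: Sequence[str] | None = None,
) -> FitResult:
    """Globally fit one Arrhenius parameter set to all subsets.

    ``init`` provides the first start (and fixed values for any reaction not
    in ``free_labels``); additional starts are drawn log-uniformly within
    bounds under the options seed.  The best start's solution is polished
    with a bound-constrained quasi-Newton pass on the exact mean-RMS
    objective.  Deterministic for a given seed.
    """
    bounds = bounds or DEFAULT_BOUNDS
    opts = options or FitOptions()
    free = tuple(free_labels) if free_labels is not None else tuple(
        lbl for lbl in scheme.param_labels if init[lbl].k_ref > 0
    )
    if not free:
        raise InvalidParameterError("no free parameters to fit")
    model = _ResidualModel(dataset, scheme, init, free, opts.n_steps,
                           opts.observables)
    lo, hi = _bounds_arrays(bounds, len(free))
    x0 = np.clip(_params_to_x(init, free), lo, hi)
    rng = np.random.default_rng(opts.seed)
    starts = [x0]
    for _ in range(max(0, opts.n_starts - 1)):
        starts.append(lo + (hi - lo) * rng.random(len(lo)))

    best_x, best_obj, any_ok = None, np.inf, False
    for x_start in starts:
        try:
            sol = least_squares(
                model.residuals, x_start, bounds=(lo, hi), method="trf",
                x_scale=np.tile([1.0, 20.0], len(free)),
                ftol=1e-12, xtol=1e-12, gtol=1e-12,
                max_nfev=opts.max_nfev,
            )
        except Exception:
            continue
        obj = model.exact_objective(sol.x)
        if math.isfinite(obj) and obj < best_obj:
            best_x, best_obj = sol.x, obj
            any_ok = any_ok or bool(sol.success)

    if best_x is None:
        raise FitError("no optimisation start converged")

    if opts.polish:
        pol = minimize(
            model.exact_objective, best_x, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-12},
        )
        if math.isfinite(pol.fun) and pol.fun <= best_obj:
            best_x, best_obj = pol.x, float(pol.fun)

    return _finish(model, best_x, dataset, scheme, opts.n_steps,
                   opts.observables, free, any_ok, opts.seed)


# ---------------------------------------------------------------------------
# Apparent (pseudo-first-order) aggregation rate
# ---------------------------------------------------------------------------

def apparent_rate(subset: Subset) -> float:
    """Apparent first-order rate of total monomer loss, k_app (h^-1).

    Least-squares fit of ``f_agg(t) = f0 + (1 - f0) * (1 - exp(-k t))``
    (fractions as proportions) to the subset's total aggregate series.
    Flat or decreasing series return 0 with a :class:`DegenerateFitWarning`.
    """
    t = subset.times
    f = subset.total_aggregate() / 100.0
    if len(t) < 3:
        raise InvalidParameterError("apparent_rate needs >= 3 points")
    span = float(f.max() - f[0])
    if span <= 0 or f[-1] <= f[0]:
        warnings.warn("flat or decreasing aggregate series; k_app set to 0",
                      DegenerateFitWarning, stacklevel=2)
        return 0.0

    def model(tt, k, f0):
        return f0 + (1.0 - f0) * (-np.expm1(-k * tt))

    # initial guess: small-extent slope
    dt = t[-1] - t[0] if t[-1] > t[0] else 1.0
    k0 = max(span / dt / max(1.0 - f[0], 1e-9), 1e-12)
    try:
        popt, _ = curve_fit(
            model, t, f, p0=[k0, max(f[0], 0.0)],
            bounds=([0.0, 0.0], [np.inf, 1.0 - 1e-12]), maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("apparent-rate fit did not converge; k_app set to 0",
                      DegenerateFitWarning, stacklevel=2)
        return 0.0
    return float(popt[0])
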