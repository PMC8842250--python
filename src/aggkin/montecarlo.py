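"""Long-term prediction and Monte Carlo prediction intervals.

Long-term aggregate fractions at the storage temperature follow directly
from forward simulation with the fitted Arrhenius parameters.  Prediction
uncertainty is quantified by parametric resampling of the measurements:
every observed fraction is perturbed with Gaussian noise of the SEC
measurement standard error, the model is refitted to each perturbed study
(warm-started at the original optimum), and the envelope of the retained
fraction of replica prediction curves closest to the central curve forms
the prediction band (95 % coverage by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitResult, StudyDataset, refit
from .mechanism import (
    Condition,
    InvalidParameterError,
    IntegrationError,
    KineticScheme,
    KineticsError,
    ObservedFractions,
    ParameterSet,
    simulate,
    simulate_fractions,
)

__all__ = [
    "PredictionCurve",
    "ParameterEnsemble",
    "PredictionBand",
    "predict_longterm",
    "monte_carlo",
    "prediction_band",
]


@dataclass
class PredictionCurve:
    """Predicted SEC fractions at a storage condition over time."""

    condition: Condition
    times: np.ndarray
    observed: list[ObservedFractions]

    def observed_array(self) -> np.ndarray:
        return np.array([o.as_array() for o in self.observed])

    def total_aggregate(self) -> np.ndarray:
        return 100.0 - self.observed_array()[:, 0]


@dataclass
class ParameterEnsemble:
    """Replica parameter sets from the Monte Carlo resampling protocol."""

    replicas: list[ParameterSet]
    objectives: list[float]
    origin: ParameterSet
    seed: int
    sigma: float | None
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.replicas)


@dataclass
class PredictionBand:
    """Central prediction with a lower/upper envelope at stated coverage."""

    times: np.ndarray
    central: np.ndarray          # total aggregate, %
    lower: np.ndarray
    upper: np.ndarray
    coverage: float
    condition: Condition

    def __post_init__(self) -> None:
        if np.any(self.lower > self.central + 1e-9) or np.any(
            self.central > self.upper + 1e-9
        ):
            raise InvalidParameterError("band must satisfy lower <= central <= upper")


def predict_longterm(
    fit: FitResult,
    scheme: KineticScheme,
    T_storage: float,
    c_total: float,
    horizon: float,
    eval_times: Sequence[float] | None = None,
    molecular_weight: float = 150_000.0,
    n_steps: int = 3000,
) -> PredictionCurve:
    """Forward-simulate the fitted model at the storage condition."""
    if not horizon > 0:
        raise InvalidParameterError("horizon must be positive")
    cond = Condition(T_storage, c_total, molecular_weight)
    if eval_times is None:
        eval_times = np.linspace(0.0, horizon, 121)
    eval_times = np.asarray(eval_times, float)
    if eval_times[-1] > horizon * (1 + 1e-12):
        raise InvalidParameterError("eval_times must lie within [0, horizon]")
    try:
        tc = simulate(scheme, fit.params, cond, horizon, n_steps=n_steps,
                      eval_times=eval_times)
    except KineticsError as exc:
        raise IntegrationError(f"long-term prediction failed: {exc}") from exc
    return PredictionCurve(cond, tc.times, tc.observed)


def monte_carlo(
    dataset: StudyDataset,
    fit: FitResult,
    scheme: KineticScheme,
    n_rep: int = 2000,
    sigma: float | None = None,
    seed: int = 0,
    n_steps: int = 3000,
    max_nfev: int | None = 60,
    max_failure_fraction: float = 0.1,
) -> ParameterEnsemble:
    """Resample the study and refit once per replica.

    ``sigma`` is the Gaussian SD added to every observed fraction
    (% points); when None, per-point standard errors stored in the dataset
    are used, falling back to 0.1 % points.  Rows are renormalised to
    100 % after perturbation.  Each replica refit starts at the original
    optimum.  Replicas whose refit raises are excluded; more than
    ``max_failure_fraction`` failures is an error.
    """
    if sigma is not None and not sigma > 0:
        raise InvalidParameterError("sigma must be positive")
    rng = np.random.default_rng(seed)
    replicas: list[ParameterSet] = []
    objectives: list[float] = []
    n_failed = 0
    for _ in range(n_rep):
        perturbed = dataset.perturbed(sigma, rng)
        try:
            res = refit(perturbed, scheme, fit.params,
                        free_labels=fit.free_labels or None,
                        n_steps=n_steps, max_nfev=max_nfev)
            replicas.append(res.params)
            objectives.append(res.objective)
        except KineticsError:
            n_failed += 1
    if n_failed > max_failure_fraction * n_rep:
        raise IntegrationError(
            f"{n_failed}/{n_rep} Monte Carlo replicas failed to refit"
        )
    return ParameterEnsemble(replicas, objectives, ParameterSet(fit.params),
                             seed, sigma, n_failed)


def prediction_band(
    ensemble: ParameterEnsemble,
    scheme: KineticScheme,
    condition: Condition,
    horizon: float,
    coverage: float = 0.95,
    eval_times: Sequence[float] | None = None,
    n_steps: int = 3000,
) -> PredictionBand:
    """Envelope of the replica curves closest to the central prediction.

    Each replica parameter set is simulated at ``condition``; curves are
    ranked by mean absolute deviation of the total aggregate fraction from
    the central (original-fit) curve, the closest ``ceil(coverage * n)``
    curves are retained, and the band is their pointwise min/max.
    """
    if not 0.0 < coverage <= 1.0:
        raise InvalidParameterError("coverage must lie in (0, 1]")
    if not len(ensemble):
        raise InvalidParameterError("empty parameter ensemble")
    if eval_times is None:
        eval_times = np.linspace(0.0, horizon, 61)
    eval_times = np.asarray(eval_times, float)
    m_total = condition.m_total

    def agg_curve(params: ParameterSet) -> np.ndarray:
        rates = scheme.rates_at(params, condition.temperature)
        frac = simulate_fractions(scheme, rates, m_total, eval_times, n_steps)
        return 100.0 - frac[:, 0]

    central = agg_curve(ensemble.origin)
    curves = np.array([agg_curve(p) for p in ensemble.replicas])
    dist = np.mean(np.abs(curves - central), axis=1)
    n_keep = int(np.ceil(coverage * len(ensemble)))
    keep = np.argsort(dist, kind="stable")[:n_keep]
    kept = curves[keep]
    lower = np.minimum(kept.min(axis=0), central)
    upper = np.maximum(kept.max(axis=0), central)
    return PredictionBand(eval_times, central, lower, upper, coverage, condition)
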