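"""Synthetic ground-truth presets and noisy stability-study generation.

No public mAb stability datasets exist, so every other module is exercised
against synthetic studies generated here.  The preset rate constants are
invented but pinned to printed qualitative anchors of real mAb behaviour:

* LT initiation activation energy around 18 kcal/mol (chemical
  modification), HT dimerisation in the 55-130 kcal/mol range (partial
  unfolding);
* visible aggregation within a couple of hours at 75 degC versus one to
  six months at 40 degC at 50 mg/mL;
* a few tenths of a percent to a few percent total aggregate after
  36 months at the 5 degC storage temperature.

The generator simulates each (temperature, concentration) condition with
the adaptive reference integrator, samples at the design's schedule, adds
i.i.d. Gaussian noise to each SEC fraction, renormalises rows to 100 %
(the SEC closure the model assumes) and clips at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mechanism import (
    GAS_CONSTANT_KCAL,
    T_REF_K,
    ArrheniusParam,
    Condition,
    InvalidParameterError,
    KineticScheme,
    ParameterSet,
    build_scheme,
    simulate,
)
from .fitting import StudyDataset, Subset

__all__ = [
    "TruthPreset",
    "StudyDesign",
    "PRESET_NAMES",
    "preset_truth",
    "default_design",
    "generate_study",
]


@dataclass(frozen=True)
class TruthPreset:
    """Named ground-truth parameter set with its qualitative anchors."""

    name: str
    params: ParameterSet
    anchors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ea_i = self.params["r_I"].E_a
        ea_d2 = self.params["r_D2"].E_a
        if self.params["r_I"].k_ref > 0 and not (10.0 <= ea_i <= 25.0):
            raise InvalidParameterError(
                f"preset {self.name}: E_a(r_I)={ea_i} outside [10, 25] kcal/mol"
            )
        if self.params["r_D2"].k_ref > 0 and not (55.0 <= ea_d2 <= 130.0):
            raise InvalidParameterError(
                f"preset {self.name}: E_a(r_D2)={ea_d2} outside [55, 130] kcal/mol"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a synthetic stability study."""

    temperatures: tuple[float, ...]
    concentrations: tuple[float, ...]
    #: temperature (degC) -> sampling times (h); every schedule starts at 0.
    times: Mapping[float, tuple[float, ...]]
    noise_sd: float = 0.1        # Gaussian SD on each fraction, % points
    seed: int = 0
    molecular_weight: float = 150_000.0
    n_replicates: int = 1        # independent SEC injections per time point

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        for T in self.temperatures:
            ts = self.times.get(T)
            if ts is None:
                raise InvalidParameterError(f"no sampling times for {T} degC")
            if any(t < 0 for t in ts):
                raise InvalidParameterError("sampling times must be >= 0")


def _scale(E_a: float, T_c: float) -> float:
    """Arrhenius factor from the 5 degC reference to T_c."""
    return math.exp(-(E_a / GAS_CONSTANT_KCAL) * (1.0 / (T_c + 273.15) - 1.0 / T_REF_K))


def _mab1like() -> ParameterSet:
    # LT initiation slow with a low (chemical-modification-like) barrier;
    # HT initiation (partial unfolding) rate-limiting with a high barrier;
    # HT growth steps fast once D exists, so seeded non-native material
    # aggregates readily at moderate temperatures.
    return ParameterSet({
        "r_I": ArrheniusParam(2.5e-7, 18.0),
        "r_NI": ArrheniusParam(0.05, 20.0),
        "r_D": ArrheniusParam(1.6e-11, 55.0),
        "r_D2": ArrheniusParam(8.0e-4, 55.0),
        "r_Dn": ArrheniusParam(2.0e-4, 55.0),
    })


def _presets() -> dict[str, TruthPreset]:
    mab1 = _mab1like()
    presets: dict[str, TruthPreset] = {}
    presets["mab1like"] = TruthPreset(
        "mab1like", mab1,
        {"story": "baseline oncology-like IgG1; LT-dominant below ~50 degC"},
    )
    presets["mab3like"] = TruthPreset(
        "mab3like",
        ParameterSet({
            "r_I": ArrheniusParam(1.2e-7, 16.0),
            "r_NI": ArrheniusParam(2.0, 22.0),
            "r_D": ArrheniusParam(1.2e-12, 60.0),
            "r_D2": ArrheniusParam(2.0e-4, 62.0),
            "r_Dn": ArrheniusParam(5.0e-5, 62.0),
        }),
        {"story": "more stable IgG2-like molecule, steeper HT onset"},
    )
    presets["lowstab"] = TruthPreset(
        "lowstab",
        ParameterSet({
            "r_I": ArrheniusParam(1.0e-6, 18.0),
            "r_NI": ArrheniusParam(0.05, 20.0),
            "r_D": ArrheniusParam(6.4e-11, 55.0),
            "r_D2": ArrheniusParam(8.0e-4, 55.0),
            "r_Dn": ArrheniusParam(2.0e-4, 55.0),
        }),
        {"story": "destabilised formulation: both initiation steps faster"},
    )
    # ltonly lives in the fast-dimerisation (pseudo-first-order) regime
    # where the LT pathway reduces exactly to first-order monomer loss.
    presets["ltonly"] = TruthPreset(
        "ltonly",
        ParameterSet({
            "r_I": ArrheniusParam(1.7e-7, 18.0),
            "r_NI": ArrheniusParam(2.0, 20.0),
            "r_D": ArrheniusParam(0.0, 55.0),
            "r_D2": ArrheniusParam(0.0, 80.0),
            "r_Dn": ArrheniusParam(0.0, 80.0),
        }),
        {"story": "chemical-modification pathway only"},
    )
    presets["htonly"] = TruthPreset(
        "htonly",
        ParameterSet({
            "r_I": ArrheniusParam(0.0, 18.0),
            "r_NI": ArrheniusParam(0.0, 20.0),
            "r_D": mab1["r_D"],
            "r_D2": mab1["r_D2"],
            "r_Dn": mab1["r_Dn"],
        }),
        {"story": "partial-unfolding pathway only"},
    )
    # "Forty-degree-blind" partner of mab1like: identical LT rate constant
    # at 40 degC but a higher LT activation energy, so the two presets give
    # the same 40 degC time courses yet several-fold different aggregation
    # at the 5 degC storage temperature.
    ea_b = 25.0
    k_i_b = mab1["r_I"].k_ref * _scale(18.0, 40.0) / _scale(ea_b, 40.0)
    presets["blind40"] = TruthPreset(
        "blind40",
        ParameterSet({
            "r_I": ArrheniusParam(k_i_b, ea_b),
            "r_NI": mab1["r_NI"],
            "r_D": mab1["r_D"],
            "r_D2": mab1["r_D2"],
            "r_Dn": mab1["r_Dn"],
        }),
        {"story": "matches mab1like at 40 degC, diverges at 5 degC"},
    )
    return presets


PRESET_NAMES: tuple[str, ...] = tuple(_presets())


def preset_truth(name: str) -> TruthPreset:
    """Deterministic ground-truth preset by name."""
    presets = _presets()
    if name not in presets:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {', '.join(presets)}"
        )
    return presets[name]


#: Default multi-temperature schedules: dense at high temperature where
#: aggregation completes in hours, sparse at low temperature (h).
DEFAULT_TIMES: dict[float, tuple[float, ...]] = {
    75.0: (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0),
    65.0: (0.0, 3.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0),
    55.0: (0.0, 48.0, 96.0, 168.0, 336.0, 504.0, 672.0, 840.0),
    45.0: (0.0, 168.0, 336.0, 730.0, 1095.0, 1460.0, 2190.0),
    40.0: (0.0, 168.0, 336.0, 730.0, 1460.0, 2190.0, 2920.0, 4380.0),
    35.0: (0.0, 336.0, 730.0, 1460.0, 2920.0, 4380.0, 5840.0),
    25.0: (0.0, 730.0, 1460.0, 2920.0, 4380.0, 5840.0, 8760.0),
}


#: Dense schedules with duplicate-injection-friendly coverage of the LT
#: transient: 12-month series at 40/45 degC, full curvature at 55-75 degC.
DENSE_TIMES: dict[float, tuple[float, ...]] = {
    75.0: (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0),
    65.0: (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 36.0, 48.0, 60.0,
           72.0),
    55.0: (0.0, 12.0, 24.0, 48.0, 72.0, 96.0, 132.0, 168.0, 252.0, 336.0,
           420.0, 504.0, 672.0, 840.0, 1008.0, 1260.0),
    45.0: (0.0, 168.0, 336.0, 730.0, 1095.0, 1460.0, 2190.0, 2920.0, 3650.0,
           4380.0, 5840.0, 7300.0, 8760.0),
    40.0: (0.0, 84.0, 168.0, 336.0, 504.0, 730.0, 1095.0, 1460.0, 2190.0,
           2920.0, 3650.0, 4380.0, 5840.0, 7300.0, 8760.0),
    35.0: (0.0, 336.0, 730.0, 1460.0, 2190.0, 2920.0, 4380.0, 5840.0, 8760.0),
    25.0: (0.0, 730.0, 1460.0, 2920.0, 4380.0, 5840.0, 8760.0, 11680.0),
}


def default_design(
    temperatures: Sequence[float] = (40.0, 55.0, 65.0, 75.0),
    concentrations: Sequence[float] = (25.0, 50.0, 100.0),
    noise_sd: float = 0.1,
    seed: int = 0,
    schedule: str = "standard",
    n_replicates: int = 1,
) -> StudyDesign:
    """Accelerated-study design with per-temperature sampling schedules.

    ``schedule="standard"`` uses the sparse screening schedules;
    ``"dense"`` uses the 12-month parameter-estimation schedules.
    """
    table = {"standard": DEFAULT_TIMES, "dense": DENSE_TIMES}.get(schedule)
    if table is None:
        raise InvalidParameterError("schedule must be 'standard' or 'dense'")
    times = {}
    for T in temperatures:
        if T in table:
            times[T] = table[T]
        else:
            times[T] = tuple(np.linspace(0.0, 4380.0, 8))
    return StudyDesign(tuple(temperatures), tuple(concentrations), times,
                       noise_sd, seed, n_replicates=n_replicates)


def estimation_design(seed: int = 0, noise_sd: float = 0.1) -> StudyDesign:
    """The dense five-temperature design used for parameter estimation:
    40-75 degC, three concentrations, triplicate injections."""
    return default_design(
        temperatures=(40.0, 45.0, 55.0, 65.0, 75.0),
        concentrations=(25.0, 50.0, 100.0),
        noise_sd=noise_sd, seed=seed, schedule="dense", n_replicates=3,
    )


def generate_study(
    truth: TruthPreset,
    design: StudyDesign,
    scheme: KineticScheme | None = None,
    formulation: str = "synthetic",
) -> StudyDataset:
    """Simulate a noisy SEC stability study under ``design``.

    Each (temperature, concentration) condition is integrated with the
    reference integrator, sampled at the design times, perturbed with
    i.i.d. Gaussian noise (SD in % points) per fraction, clipped at zero
    and renormalised to 100 %.
    """
    if scheme is None:
        scheme = build_scheme(4)
    rng = np.random.default_rng(design.seed)
    subsets = []
    for T in design.temperatures:
        ts = np.asarray(design.times[T], float)
        for c in design.concentrations:
            cond = Condition(T, c, design.molecular_weight)
            try:
                tc = simulate(scheme, truth.params, cond, float(ts[-1]),
                              method="reference", eval_times=ts)
            except Exception as exc:
                raise type(exc)(
                    f"generation failed at T={T} degC, c={c} mg/mL: {exc}"
                ) from exc
            frac = tc.observed_array()
            t_obs = ts
            if design.n_replicates > 1:
                # replicate injections: same model value, independent noise;
                # nominal times offset by multiples of 0.001 h (seconds on
                # the lab clock) so every (condition, time) key is unique
                t_obs = (np.repeat(ts, design.n_replicates)
                         + np.tile(np.arange(design.n_replicates) * 1e-3,
                                   len(ts)))
                frac = np.repeat(frac, design.n_replicates, axis=0)
            if design.noise_sd > 0:
                frac = frac + rng.normal(0.0, design.noise_sd, frac.shape)
                frac = np.clip(frac, 0.0, None)
                frac = 100.0 * frac / frac.sum(axis=1, keepdims=True)
            subsets.append(Subset(
                temperature=T, c_total=c, times=t_obs, fractions=frac,
                stderr=(np.full(frac.shape, design.noise_sd)
                        if design.noise_sd > 0 else None),
                formulation=formulation,
                molecular_weight=design.molecular_weight,
            ))
    return StudyDataset(subsets)
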