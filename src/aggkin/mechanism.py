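"""Branched two-pathway aggregation mechanism and its kinetic integration.

The mechanism describes monoclonal-antibody (mAb) aggregation as two
competing irreversible routes out of the native monomer N:

* the low-temperature (LT) pathway, initiated by slow chemical modification
  (``N -> I``) followed by bimolecular dimerisation (``N + I -> NI``);
* the high-temperature (HT) pathway, initiated by partial unfolding
  (``N -> D``) followed by oligomer growth (``D + D -> D2``,
  ``D2 + D -> D3`` and optionally ``D3 + D -> HMW``).

Every reaction carries an Arrhenius pair ``(k_ref, E_a)`` where ``k_ref``
is the rate constant at the 5 degC reference temperature.  Concentrations
are molar internally; the observable is the SEC area-fraction vector
(monomer / dimer / trimer / HMW, mass-weighted, summing to 100 %).
Integration uses fixed-step forward Euler ("linear propagation", default
3000 steps) with an adaptive high-accuracy integrator as reference oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "GAS_CONSTANT_KCAL",
    "T_REF_C",
    "T_REF_K",
    "HOURS_PER_MONTH",
    "KineticsError",
    "InvalidParameterError",
    "StiffnessError",
    "IntegrationError",
    "Species",
    "Reaction",
    "ArrheniusParam",
    "ParameterSet",
    "Condition",
    "ObservedFractions",
    "TimeCourse",
    "KineticScheme",
    "arrhenius_rate",
    "build_scheme",
    "fraction_map",
    "simulate",
]

# ---------------------------------------------------------------------------
# Constants & errors
# ---------------------------------------------------------------------------

#: Gas constant in kcal mol^-1 K^-1 (activation energies are in kcal/mol).
GAS_CONSTANT_KCAL = 1.987204e-3

#: Reference temperature for rate constants, degC / K.
T_REF_C = 5.0
T_REF_K = 278.15

#: Fixed time convention: one month = 730 h.
HOURS_PER_MONTH = 730.0

_KELVIN = 273.15


class KineticsError(Exception):
    """Base class for kinetic-model errors."""


class InvalidParameterError(KineticsError, ValueError):
    """A rate parameter, temperature or concentration is out of range."""


class StiffnessError(KineticsError):
    """Forward-Euler propagation produced a negative concentration."""


class IntegrationError(KineticsError):
    """The integrator violated mass balance or failed to converge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Monomer-unit accounting size of each known species.  N, I and D are
#: monomeric (I is chemically modified, D partially unfolded; SEC separates
#: by size only, so all three elute in the monomer peak).  HMW lumps every
#: aggregate of four or more units at an accounting size of 4.
SPECIES_SIZES: dict[str, int] = {
    "N": 1, "I": 1, "D": 1, "NI": 2, "D2": 2, "D3": 3, "HMW": 4,
}


@dataclass(frozen=True)
class Species:
    name: str
    stoichiometric_size: int

    def __post_init__(self) -> None:
        if self.stoichiometric_size < 1:
            raise InvalidParameterError(
                f"species {self.name!r}: stoichiometric_size must be >= 1"
            )


@dataclass(frozen=True)
class Reaction:
    """Irreversible mass-action reaction.

    ``reactants`` / ``products`` map species name -> stoichiometric count.
    ``param_label`` names the Arrhenius parameter this reaction draws from;
    several reactions may share one label (HT oligomer growth).
    """

    label: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    param_label: str

    @property
    def order(self) -> int:
        return sum(n for _, n in self.reactants)


@dataclass(frozen=True)
class ArrheniusParam:
    """Rate constant at 5 degC (h^-1 or M^-1 h^-1) and activation energy (kcal/mol)."""

    k_ref: float
    E_a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_ref) and math.isfinite(self.E_a)):
            raise InvalidParameterError("nonfinite Arrhenius parameter")
        if self.k_ref < 0:
            raise InvalidParameterError(f"k_ref must be >= 0, got {self.k_ref}")
        if self.E_a < 0:
            raise InvalidParameterError(f"E_a must be >= 0, got {self.E_a}")


class ParameterSet(dict):
    """Mapping from parameter label to :class:`ArrheniusParam`."""

    def validate_for(self, scheme: "KineticScheme") -> None:
        missing = set(scheme.param_labels) - set(self)
        extra = set(self) - set(scheme.param_labels)
        if missing or extra:
            raise InvalidParameterError(
                f"parameter set does not match scheme labels "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def to_dict(self) -> dict:
        return {lbl: {"k_ref": p.k_ref, "E_a": p.E_a} for lbl, p in self.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls({lbl: ArrheniusParam(v["k_ref"], v["E_a"]) for lbl, v in d.items()})


@dataclass(frozen=True)
class Condition:
    """One experimental condition: temperature, concentration, initial state."""

    temperature: float            # degC
    c_total: float                # mg/mL
    molecular_weight: float = 150_000.0   # g/mol
    #: species -> initial mass fraction (monomer-unit mass), summing to 1.
    initial_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"N": 1.0}
    )

    def __post_init__(self) -> None:
        if not self.c_total > 0:
            raise InvalidParameterError("c_total must be positive")
        if self.temperature <= -_KELVIN:
            raise InvalidParameterError("temperature below absolute zero")
        fr = dict(self.initial_fractions)
        if any(not (0.0 <= f <= 1.0) for f in fr.values()):
            raise InvalidParameterError("initial fractions must lie in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise InvalidParameterError("initial fractions must sum to 1")

    @property
    def m_total(self) -> float:
        """Total monomer-unit molar concentration (mol/L)."""
        return self.c_total / self.molecular_weight  # mg/mL == g/L


@dataclass(frozen=True)
class ObservedFractions:
    """SEC mass fractions in percent; sums to 100 within 1e-6."""

    f_monomer: float
    f_dimer: float
    f_trimer: float
    f_hmw: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < -1e-9) or np.any(vals > 100.0 + 1e-9):
            raise InvalidParameterError("fractions must lie in [0, 100]")
        if abs(float(vals.sum()) - 100.0) > 1e-6:
            raise InvalidParameterError(
                f"fractions must sum to 100, got {vals.sum():.8f}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_monomer, self.f_dimer, self.f_trimer, self.f_hmw], float
        )


@dataclass
class TimeCourse:
    """Simulated trajectory: molar states and SEC observables on a time grid."""

    times: np.ndarray                       # h, strictly increasing, t[0] = 0
    species: tuple[str, ...]
    state: np.ndarray                       # (n_times, n_species) molar
    observed: list[ObservedFractions]
    condition: Condition

    def observed_array(self) -> np.ndarray:
        return np.array([o.as_array() for o in self.observed])

    def total_aggregate(self) -> np.ndarray:
        """Total aggregate mass fraction (%) = 100 - monomer peak."""
        return 100.0 - self.observed_array()[:, 0]


@dataclass(frozen=True)
class KineticScheme:
    """Ordered species list plus the irreversible mass-action reaction set."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    n_max_oligomer: int

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise InvalidParameterError("duplicate species names in scheme")
        sizes = {s.name: s.stoichiometric_size for s in self.species}
        for r in self.reactions:
            lhs = sum(sizes[n] * c for n, c in r.reactants)
            rhs = sum(sizes[n] * c for n, c in r.products)
            if lhs != rhs:
                raise InvalidParameterError(
                    f"reaction {r.label}: monomer-unit mass not balanced "
                    f"({lhs} -> {rhs})"
                )

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s.stoichiometric_size for s in self.species], float)

    @property
    def param_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.reactions:
            if r.param_label not in seen:
                seen.append(r.param_label)
        return tuple(seen)

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def stoichiometry(self) -> tuple[np.ndarray, np.ndarray]:
        """Reactant and net-change matrices, shape (n_reactions, n_species)."""
        ns = len(self.species)
        idx = {s.name: i for i, s in enumerate(self.species)}
        react = np.zeros((len(self.reactions), ns))
        net = np.zeros((len(self.reactions), ns))
        for j, r in enumerate(self.reactions):
            for n, c in r.reactants:
                react[j, idx[n]] += c
                net[j, idx[n]] -= c
            for n, c in r.products:
                net[j, idx[n]] += c
        return react, net

    def rates_at(self, params: ParameterSet, temperature: float) -> np.ndarray:
        """Per-reaction rate constants at ``temperature`` (degC)."""
        params.validate_for(self)
        return np.array(
            [arrhenius_rate(params[r.param_label], temperature) for r in self.reactions]
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def arrhenius_rate(p: ArrheniusParam, T: float) -> float:
    """Rate constant at temperature ``T`` (degC) from the 5 degC reference.

    ``k(T) = k_ref * exp[-(E_a/R) * (1/T_K - 1/278.15)]`` with R in
    kcal mol^-1 K^-1, so the units of the result match ``k_ref``.
    """
    if not (math.isfinite(T) and T > -_KELVIN):
        raise InvalidParameterError(f"temperature {T!r} degC is not physical")
    t_k = T + _KELVIN
    return p.k_ref * math.exp(-(p.E_a / GAS_CONSTANT_KCAL) * (1.0 / t_k - 1.0 / T_REF_K))


def build_scheme(n_max_oligomer: int = 4) -> KineticScheme:
    """Construct the branched LT/HT scheme.

    ``n_max_oligomer=3`` stops HT growth at the trimer D3 (5 reactions,
    6 species); ``n_max_oligomer=4`` adds a lumped HMW species fed by
    ``D3 + D -> HMW`` sharing the D2+D growth parameter (6 reactions,
    7 species).
    """
    if n_max_oligomer not in (3, 4):
        raise InvalidParameterError(
            f"n_max_oligomer must be 3 or 4, got {n_max_oligomer}"
        )
    names = ["N", "I", "D", "NI", "D2", "D3"] + (
        ["HMW"] if n_max_oligomer == 4 else []
    )
    species = tuple(Species(n, SPECIES_SIZES[n]) for n in names)
    reactions = [
        Reaction("r_I", (("N", 1),), (("I", 1),), "r_I"),
        Reaction("r_NI", (("N", 1), ("I", 1)), (("NI", 1),), "r_NI"),
        Reaction("r_D", (("N", 1),), (("D", 1),), "r_D"),
        Reaction("r_D2", (("D", 2),), (("D2", 1),), "r_D2"),
        Reaction("r_Dn", (("D2", 1), ("D", 1)), (("D3", 1),), "r_Dn"),
    ]
    if n_max_oligomer == 4:
        # D3 + D -> HMW(4 units); growth steps share one Arrhenius parameter.
        reactions.append(
            Reaction("r_Dn4", (("D3", 1), ("D", 1)), (("HMW", 1),), "r_Dn")
        )
    return KineticScheme(species, tuple(reactions), n_max_oligomer)


def fraction_map(
    scheme: KineticScheme, state: Mapping[str, float] | np.ndarray
) -> ObservedFractions:
    """Map molar concentrations to SEC area fractions (mass %, sum 100).

    The monomer peak collects N, I and D (all monomeric in size); dimer
    collects NI and D2 with mass weight 2; trimer D3 with weight 3; the
    HMW peak the lumped species at its accounting size.
    """
    names = scheme.species_names
    if isinstance(state, np.ndarray):
        conc = np.asarray(state, float)
    else:
        conc = np.array([state.get(n, 0.0) for n in names], float)
    if np.any(conc < -1e-30):
        raise InvalidParameterError("negative concentration in fraction_map")
    mass = conc * scheme.sizes
    total = float(mass.sum())
    if total <= 0.0:
        raise InvalidParameterError("zero total mass: fractions undefined")
    peaks = {"monomer": 0.0, "dimer": 0.0, "trimer": 0.0, "hmw": 0.0}
    peak_of = {1: "monomer", 2: "dimer", 3: "trimer"}
    for i, sp in enumerate(scheme.species):
        peaks[peak_of.get(sp.stoichiometric_size, "hmw")] += mass[i]
    f = {k: 100.0 * v / total for k, v in peaks.items()}
    # absorb rounding residue into the monomer peak so the invariant holds
    f["monomer"] += 100.0 - sum(f.values())
    return ObservedFractions(f["monomer"], f["dimer"], f["trimer"], f["hmw"])


# ---------------------------------------------------------------------------
# Fixed-step linear propagation (forward Euler), numba fast path
# ---------------------------------------------------------------------------

@njit(cache=True)
def _euler_branched(y0, k, t_end, n_steps, neg_tol):  # pragma: no cover - jit
    """Forward-Euler propagation of the 7-species branched scheme.

    ``y0``: [N, I, D, NI, D2, D3, HMW] molar; ``k``: rate constants
    [k_I, k_NI, k_D, k_D2, k_Dn(D2+D), k_Dn(D3+D)] at the run temperature.
    Returns (trajectory (n_steps+1, 7), max relative mass error, status)
    with status 0 = ok, 1 = negative concentration beyond ``neg_tol``.
    """
    dt = t_end / n_steps
    out = np.empty((n_steps + 1, 7))
    n, i, d, ni, d2, d3, h = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5], y0[6]
    m0 = n + i + d + 2.0 * ni + 2.0 * d2 + 3.0 * d3 + 4.0 * h
    out[0, 0] = n; out[0, 1] = i; out[0, 2] = d; out[0, 3] = ni
    out[0, 4] = d2; out[0, 5] = d3; out[0, 6] = h
    max_err = 0.0
    for s in range(n_steps):
        r1 = k[0] * n
        r2 = k[1] * n * i
        r3 = k[2] * n
        r4 = k[3] * d * d
        r5 = k[4] * d2 * d
        r6 = k[5] * d3 * d
        n += dt * (-r1 - r2 - r3)
        i += dt * (r1 - r2)
        d += dt * (r3 - 2.0 * r4 - r5 - r6)
        ni += dt * r2
        d2 += dt * (r4 - r5)
        d3 += dt * (r5 - r6)
        h += dt * r6
        if (n < -neg_tol or i < -neg_tol or d < -neg_tol or ni < -neg_tol
                or d2 < -neg_tol or d3 < -neg_tol or h < -neg_tol):
            return out[: s + 1], max_err, 1
        m = n + i + d + 2.0 * ni + 2.0 * d2 + 3.0 * d3 + 4.0 * h
        err = abs(m - m0) / m0
        if err > max_err:
            max_err = err
        out[s + 1, 0] = n; out[s + 1, 1] = i; out[s + 1, 2] = d
        out[s + 1, 3] = ni; out[s + 1, 4] = d2; out[s + 1, 5] = d3
        out[s + 1, 6] = h
    return out, max_err, 0


@njit(cache=True)
def _fractions_from_traj(traj, t_end, eval_times):  # pragma: no cover - jit
    """SEC fraction curves (%, [monomer, dimer, trimer, hmw]) linearly
    interpolated from a 7-species uniform-grid trajectory."""
    n_steps = traj.shape[0] - 1
    dt = t_end / n_steps
    out = np.empty((eval_times.shape[0], 4))
    for i in range(eval_times.shape[0]):
        pos = eval_times[i] / dt
        j = int(pos)
        if j >= n_steps:
            j = n_steps - 1
        w = pos - j
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        y = traj[j] * (1.0 - w) + traj[j + 1] * w
        mono = y[0] + y[1] + y[2]
        dim = 2.0 * (y[3] + y[4])
        tri = 3.0 * y[5]
        hmw = 4.0 * y[6]
        total = mono + dim + tri + hmw
        out[i, 0] = 100.0 * mono / total
        out[i, 1] = 100.0 * dim / total
        out[i, 2] = 100.0 * tri / total
        out[i, 3] = 100.0 * hmw / total
    return out


def _branched_rate_vector(scheme: KineticScheme, rates: np.ndarray) -> np.ndarray | None:
    """Return the 6-rate vector for the jit kernel, or None if the scheme
    is not the built-in branched topology."""
    labels = tuple(r.label for r in scheme.reactions)
    if labels == ("r_I", "r_NI", "r_D", "r_D2", "r_Dn"):
        return np.append(rates, 0.0)
    if labels == ("r_I", "r_NI", "r_D", "r_D2", "r_Dn", "r_Dn4"):
        return np.asarray(rates, float)
    return None


def _pad_state(scheme: KineticScheme, y: np.ndarray) -> np.ndarray:
    """Pad a 6-species state with a zero HMW column for the jit kernel."""
    if len(scheme.species) == 7:
        return y
    return np.append(y, 0.0)


def _generic_rhs(react: np.ndarray, net: np.ndarray, rates: np.ndarray):
    def rhs(_t, y):
        yc = np.clip(y, 0.0, None)
        flux = rates.copy()
        for j in range(react.shape[0]):
            for s in range(react.shape[1]):
                c = react[j, s]
                if c == 1:
                    flux[j] *= yc[s]
                elif c == 2:
                    flux[j] *= yc[s] * yc[s]
                elif c > 2:
                    flux[j] *= yc[s] ** c
        return net.T @ flux
    return rhs


def initial_state(scheme: KineticScheme, cond: Condition) -> np.ndarray:
    """Molar initial state from the condition's mass fractions."""
    m0 = cond.m_total
    y0 = np.zeros(len(scheme.species))
    for name, frac in cond.initial_fractions.items():
        if frac == 0.0:
            continue
        i = scheme.index(name)
        y0[i] = frac * m0 / scheme.species[i].stoichiometric_size
    return y0


def _propagate_euler(
    scheme: KineticScheme,
    rates: np.ndarray,
    y0: np.ndarray,
    t_end: float,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euler grid propagation; returns (grid times, trajectory, max mass err)."""
    m0 = float((scheme.sizes * y0).sum())
    neg_tol = 1e-12 * m0
    kvec = _branched_rate_vector(scheme, rates)
    if kvec is not None:
        traj, max_err, status = _euler_branched(
            _pad_state(scheme, y0), kvec, t_end, n_steps, neg_tol
        )
        if status == 1:
            raise StiffnessError(
                f"negative concentration during linear propagation at step "
                f"{traj.shape[0] - 1}/{n_steps}; increase n_steps"
            )
        traj = traj[:, : len(scheme.species)]
    else:  # generic (slow) path for user-supplied schemes
        react, net = scheme.stoichiometry()
        rhs = _generic_rhs(react, net, rates)
        dt = t_end / n_steps
        traj = np.empty((n_steps + 1, len(y0)))
        traj[0] = y0
        y = y0.astype(float).copy()
        max_err = 0.0
        for s in range(n_steps):
            y = y + dt * rhs(0.0, y)
            if np.any(y < -neg_tol):
                raise StiffnessError(
                    f"negative concentration during linear propagation at "
                    f"step {s + 1}/{n_steps}; increase n_steps"
                )
            max_err = max(max_err, abs((scheme.sizes * y).sum() - m0) / m0)
            traj[s + 1] = y
    if max_err > 1e-6:
        raise IntegrationError(
            f"mass balance violated by relative error {max_err:.2e} (> 1e-6)"
        )
    grid = np.linspace(0.0, t_end, n_steps + 1)
    return grid, traj, max_err


def _propagate_reference(
    scheme: KineticScheme,
    rates: np.ndarray,
    y0: np.ndarray,
    eval_times: np.ndarray,
) -> np.ndarray:
    react, net = scheme.stoichiometry()
    rhs = _generic_rhs(react, net, rates)
    m0 = float((scheme.sizes * y0).sum())
    sol = solve_ivp(
        rhs,
        (0.0, float(eval_times[-1])),
        y0,
        method="LSODA",
        t_eval=eval_times,
        rtol=1e-10,
        atol=1e-14 * max(m0, 1e-30),
    )
    if not sol.success:
        raise IntegrationError(f"reference integration failed: {sol.message}")
    traj = np.clip(sol.y.T, 0.0, None)
    mass = traj @ scheme.sizes
    err = float(np.max(np.abs(mass - m0)) / m0)
    if err > 1e-9:
        raise IntegrationError(
            f"reference integrator mass error {err:.2e} exceeds 1e-9"
        )
    return traj


def simulate(
    scheme: KineticScheme,
    params: ParameterSet,
    cond: Condition,
    t_end: float,
    n_steps: int = 3000,
    method: str = "linear_propagation",
    eval_times: Sequence[float] | None = None,
) -> TimeCourse:
    """Integrate the mechanism at one condition and report SEC observables.

    ``linear_propagation`` is the production integrator: forward Euler on a
    uniform ``n_steps`` grid over ``[0, t_end]`` with linear interpolation
    to ``eval_times``.  ``reference`` is the adaptive high-accuracy oracle
    (relative tolerance 1e-10).
    """
    if not t_end > 0:
        raise InvalidParameterError("t_end must be positive")
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    rates = scheme.rates_at(params, cond.temperature)
    y0 = initial_state(scheme, cond)
    if eval_times is None:
        n_out = min(int(n_steps), 200)
        eval_times = np.linspace(0.0, t_end, n_out + 1)
    eval_times = np.asarray(eval_times, float)
    if eval_times.ndim != 1 or np.any(np.diff(eval_times) <= 0):
        raise InvalidParameterError("eval_times must be strictly increasing")
    if eval_times[0] < 0 or eval_times[-1] > t_end * (1 + 1e-12):
        raise InvalidParameterError("eval_times must lie within [0, t_end]")

    if method == "linear_propagation":
        grid, traj, _ = _propagate_euler(scheme, rates, y0, t_end, n_steps)
        state = np.column_stack(
            [np.interp(eval_times, grid, traj[:, s]) for s in range(traj.shape[1])]
        )
    elif method == "reference":
        tq = eval_times if eval_times[0] == 0 else np.insert(eval_times, 0, 0.0)
        state = _propagate_reference(scheme, rates, y0, tq)
        if eval_times[0] != 0:
            state = state[1:]
    else:
        raise InvalidParameterError(f"unknown integration method {method!r}")

    state = np.clip(state, 0.0, None)
    observed = [fraction_map(scheme, state[i]) for i in range(state.shape[0])]
    return TimeCourse(eval_times, scheme.species_names, state, observed, cond)


def simulate_fractions(
    scheme: KineticScheme,
    rates: np.ndarray,
    m_total: float,
    eval_times: np.ndarray,
    n_steps: int = 3000,
    y0: np.ndarray | None = None,
) -> np.ndarray:
    """Fast path used by the fitting loop: Euler-propagate with precomputed
    per-reaction rates and return the (n_times, 4) SEC fraction array (%).

    Raises :class:`StiffnessError` on negative concentrations like
    :func:`simulate`, but skips object construction for speed.
    """
    if y0 is None:
        y0 = np.zeros(len(scheme.species))
        y0[scheme.index("N")] = m_total
    t_end = float(eval_times[-1])
    kvec = _branched_rate_vector(scheme, rates)
    if kvec is not None:
        # jit fast path: propagate and map to SEC fractions in one pass
        m0 = float((scheme.sizes * y0).sum())
        traj, max_err, status = _euler_branched(
            _pad_state(scheme, y0), kvec, t_end, n_steps, 1e-12 * m0
        )
        if status == 1:
            raise StiffnessError(
                f"negative concentration during linear propagation at step "
                f"{traj.shape[0] - 1}/{n_steps}; increase n_steps"
            )
        if max_err > 1e-6:
            raise IntegrationError(
                f"mass balance violated by relative error {max_err:.2e}"
            )
        return _fractions_from_traj(traj, t_end, np.asarray(eval_times, float))
    grid, traj, _ = _propagate_euler(scheme, rates, y0, t_end, n_steps)
    state = np.column_stack(
        [np.interp(eval_times, grid, traj[:, s]) for s in range(traj.shape[1])]
    )
    state = np.clip(state, 0.0, None)
    mass = state * scheme.sizes
    total = mass.sum(axis=1)
    sizes = scheme.sizes
    out = np.zeros((state.shape[0], 4))
    for i, sz in enumerate(sizes):
        col = 3 if sz >= 4 else int(sz) - 1
        out[:, col] += mass[:, i]
    return 100.0 * out / total[:, None]


def zero_params(scheme: KineticScheme) -> ParameterSet:
    """All-zero rate constants (useful for pathway knockouts)."""
    return ParameterSet({lbl: ArrheniusParam(0.0, 0.0) for lbl in scheme.param_labels})


def knockout(params: ParameterSet, labels: Sequence[str]) -> ParameterSet:
    """Copy of ``params`` with the listed reactions' rate constants zeroed."""
    out = ParameterSet(params)
    for lbl in labels:
        out[lbl] = ArrheniusParam(0.0, out[lbl].E_a)
    return out
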