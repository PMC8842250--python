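"""File formats and run configuration.

The shared time-course CSV dialect has columns::

    formulation, temperature_C, conc_mg_ml, time_h,
    f_monomer_pct, f_dimer_pct, f_trimer_pct, f_hmw_pct

An empty HMW cell is computed as ``100 - (monomer + dimer + trimer)``;
rows whose four fractions miss 100 % by more than 0.5 % points are
rejected with their row numbers.  Parameter sets and fit results travel
as JSON with units stated in a header block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .fitting import FitResult, StudyDataset, Subset
from .mechanism import InvalidParameterError, ParameterSet

__all__ = [
    "TIMECOURSE_COLUMNS",
    "RunConfig",
    "read_timecourse",
    "write_timecourse",
    "write_fit_result",
    "read_parameter_set",
    "write_parameter_set",
    "config_hash",
]

TIMECOURSE_COLUMNS = [
    "formulation", "temperature_C", "conc_mg_ml", "time_h",
    "f_monomer_pct", "f_dimer_pct", "f_trimer_pct", "f_hmw_pct",
]

_FRACTION_COLS = TIMECOURSE_COLUMNS[4:]


class ParseError(InvalidParameterError):
    """Malformed time-course CSV."""


@dataclass(frozen=True)
class RunConfig:
    """Validated options for a pipeline run; unknown keys are rejected."""

    n_max_oligomer: int = 4
    method: str = "linear_propagation"
    n_steps: int = 3000
    n_starts: int = 8
    seed: int = 0
    n_rep: int = 2000
    sigma: float | None = None
    coverage: float = 0.95
    storage_temperature: float = 5.0
    horizon_months: float = 36.0
    molecular_weight: float = 150_000.0

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown config keys: {sorted(unknown)} "
                f"(known: {sorted(known)})"
            )
        cfg = cls(**data)
        if cfg.n_max_oligomer not in (3, 4):
            raise InvalidParameterError("n_max_oligomer must be 3 or 4")
        if cfg.n_steps < 1 or cfg.n_starts < 1 or cfg.n_rep < 1:
            raise InvalidParameterError("n_steps, n_starts, n_rep must be >= 1")
        if not 0.0 < cfg.coverage <= 1.0:
            raise InvalidParameterError("coverage must lie in (0, 1]")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def read_timecourse(path: str | Path) -> StudyDataset:
    """Read the shared time-course CSV into a grouped study."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")
    for col in TIMECOURSE_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if col != "f_hmw_pct" and df[col].isna().any():
            bad = df.index[df[col].isna()].tolist()
            raise ParseError(f"malformed numeric values in {col}, rows {bad}")
    if (df["time_h"] < 0).any():
        bad = df.index[df["time_h"] < 0].tolist()
        raise ParseError(f"negative times in rows {bad}")

    keys = ["formulation", "temperature_C", "conc_mg_ml", "time_h"]
    dup = df.duplicated(subset=keys, keep="first")
    if dup.any():
        bad = df.index[dup].tolist()
        raise ParseError(
            f"duplicate (formulation, temperature, concentration, time) "
            f"rows: {bad}"
        )

    partial = df[_FRACTION_COLS[:3]].sum(axis=1)
    filled = df["f_hmw_pct"].copy()
    empty_hmw = filled.isna()
    filled[empty_hmw] = 100.0 - partial[empty_hmw]
    total = partial + filled
    bad_rows = df.index[(total - 100.0).abs() > 0.5].tolist()
    if bad_rows:
        raise ParseError(
            f"fractions fail SEC closure (sum != 100 +- 0.5): rows {bad_rows}"
        )
    df = df.assign(f_hmw_pct=filled.clip(lower=0.0))

    subsets = []
    for (form, temp, conc), g in df.groupby(
        ["formulation", "temperature_C", "conc_mg_ml"], sort=True
    ):
        g = g.sort_values("time_h")
        subsets.append(Subset(
            temperature=float(temp), c_total=float(conc),
            times=g["time_h"].to_numpy(),
            fractions=g[_FRACTION_COLS].to_numpy(),
            formulation=str(form),
        ))
    return StudyDataset(subsets)


def write_timecourse(dataset: StudyDataset, path: str | Path) -> None:
    rows = []
    for s in dataset.subsets:
        for i, t in enumerate(s.times):
            rows.append({
                "formulation": s.formulation,
                "temperature_C": s.temperature,
                "conc_mg_ml": s.c_total,
                "time_h": t,
                **dict(zip(_FRACTION_COLS, s.fractions[i])),
            })
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


_PARAM_HEADER = {
    "k_ref_units": "h^-1 (order 1) or M^-1 h^-1 (order 2), at 5 degC",
    "E_a_units": "kcal/mol",
}


def write_parameter_set(params: ParameterSet, path: str | Path,
                        extra: Mapping | None = None) -> None:
    doc = {"units": _PARAM_HEADER, "parameters": params.to_dict()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_parameter_set(path: str | Path) -> ParameterSet:
    """Read a parameter-set JSON (also accepts fit-result JSON)."""
    doc = json.loads(Path(path).read_text())
    key = "parameters" if "parameters" in doc else "params"
    return ParameterSet.from_dict(doc[key])


def write_fit_result(fit: FitResult, path: str | Path,
                     extra: Mapping | None = None) -> None:
    doc = {"units": _PARAM_HEADER, **fit.to_dict()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
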