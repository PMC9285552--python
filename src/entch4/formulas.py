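"""Closed-form physiological and prediction formulas.

This module holds the non-statistical core of the methane-prediction
workflow for lactating dairy cows:

* energy-corrected milk (ECM, Tyrrell & Reid standardization),
* the days-in-pregnancy imputation rule used when breeding records are
  unavailable (126-day open period, 280-day gestation),
* the heat producing unit (HPU, CIGR) and its fixed CO2 equivalent of
  180 L/h per HPU, which together turn a breath CH4/CO2 ratio into a
  daily CH4 volume (the CO2-tracer or "Madsen" route),
* evaluation of the bundled multiple-regression prediction equations
  (CH4 in L/day or methane conversion factor in J/100 J GEI), and
* the methane conversion factor (MCF) itself.

All quantities are in the units stated in the docstrings; gas volumes
are litres at 0 degC and 1 atm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CH4_ENERGY_KJ_PER_L",
    "CO2_L_PER_HOUR_PER_HPU",
    "GESTATION_LENGTH_DAYS",
    "OPEN_PERIOD_DAYS",
    "CowRecord",
    "EquationSpec",
    "HpuResult",
    "compute_ecm",
    "days_in_pregnancy",
    "compute_hpu",
    "predict_ch4_hpu",
    "evaluate_equation",
    "compute_mcf",
    "load_equations",
    "read_cow_table",
]

#: Gross energy density of methane (kJ per litre at 0 degC, 1 atm),
#: the Brouwer combustion constant. Exposed as a parameter everywhere
#: it is used.
CH4_ENERGY_KJ_PER_L = 39.54

#: Fixed CO2 production equivalent of one heat producing unit (L/h).
CO2_L_PER_HOUR_PER_HPU = 180.0

#: Gestation length (days) used by the pregnancy imputation rule.
GESTATION_LENGTH_DAYS = 280

#: Open period (days in milk before conception) assumed when no
#: breeding record exists; days in pregnancy is zero before this.
OPEN_PERIOD_DAYS = 126

_COVARIATE_KEYS = frozenset({"LW", "DMI", "ECM", "CH4CO2"})
_RESPONSES = frozenset({"CH4_L_per_day", "MCF_J_per_100J"})


@dataclass(frozen=True)
class CowRecord:
    """One cow-period: morphometrics, intake, milk, and energy.

    Parameters
    ----------
    cow_id : str
        Animal (or animal-period) identifier.
    live_weight : float
        Live weight, kg.
    milk_yield : float
        Milk yield, kg/day.
    milk_fat, milk_protein : float
        Milk fat and true-protein content, % (0-100).
    dmi : float
        Dry matter intake, kg/day.
    days_in_milk : float
        Days since calving.
    gei : float
        Gross energy intake, MJ/day.
    diet : str
        Diet label; the feeding-trial levels are ``LF``/``MF``/``HF``
        (low/medium/high dietary NDF) but any label is accepted.
    """

    cow_id: str
    live_weight: float
    milk_yield: float
    milk_fat: float
    milk_protein: float
    dmi: float
    days_in_milk: float
    gei: float
    diet: str = "other"

    def __post_init__(self) -> None:
        if self.live_weight <= 0:
            raise ValueError("live_weight must be positive")
        if self.milk_yield < 0 or self.dmi < 0 or self.days_in_milk < 0 or self.gei < 0:
            raise ValueError("milk_yield, dmi, days_in_milk and gei must be non-negative")
        for name in ("milk_fat", "milk_protein"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")

    @property
    def ecm(self) -> float:
        """Energy-corrected milk (kg/day) for this record."""
        return compute_ecm(self.milk_yield, self.milk_fat, self.milk_protein)


@dataclass(frozen=True)
class EquationSpec:
    """A linear CH4 (or MCF) prediction equation with published metadata.

    ``coefficients`` maps covariate keys (``LW``, ``DMI``, ``ECM``,
    ``CH4CO2``) to slopes in response units per covariate unit.
    """

    name: str
    response: str
    intercept: float
    coefficients: Mapping[str, float]
    coefficient_se: Mapping[str, float] = field(default_factory=dict)
    intercept_se: float | None = None
    adj_r2: float | None = None
    rmse: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.coefficients) - _COVARIATE_KEYS
        if bad:
            raise ValueError(f"unknown covariate keys {sorted(bad)}")
        if self.response not in _RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.adj_r2 is not None and not 0 < self.adj_r2 <= 1:
            raise ValueError("adj_r2 must be in (0, 1]")
        if self.rmse is not None and self.rmse <= 0:
            raise ValueError("rmse must be positive")

    def __call__(self, covariates: Mapping[str, float]) -> float:
        return evaluate_equation(self, covariates)


@dataclass(frozen=True)
class HpuResult:
    """Heat producing unit and its predicted daily CO2 output."""

    hpu: float  # x 10^3 W
    days_in_pregnancy: float  # day
    co2_predicted: float  # L/day


def compute_ecm(milk_yield, milk_fat, milk_protein):
    """Energy-corrected milk (kg/day).

    ECM = milk_yield x (376 x fat% + 209 x protein% + 948) / 3138,
    the Tyrrell & Reid energy standardization. Linear and homogeneous
    in milk yield. Accepts scalars or arrays.
    """
    m = np.asarray(milk_yield, dtype=float)
    f = np.asarray(milk_fat, dtype=float)
    p = np.asarray(milk_protein, dtype=float)
    if np.any(m < 0) or np.any(f < 0) or np.any(p < 0):
        raise ValueError("milk yield, fat and protein must be non-negative")
    out = m * (376.0 * f + 209.0 * p + 948.0) / 3138.0
    return float(out) if out.ndim == 0 else out


def days_in_pregnancy(days_in_milk: float) -> float:
    """Impute days in pregnancy from days in milk.

    Cows are assumed to conceive after a 126-day open period, so the
    value is 0 before 126 days in milk and ``days_in_milk - 126``
    afterwards, capped at the 280-day gestation length.
    """
    if days_in_milk < 0:
        raise ValueError("days_in_milk must be non-negative")
    return min(max(days_in_milk - OPEN_PERIOD_DAYS, 0.0), float(GESTATION_LENGTH_DAYS))


def compute_hpu(live_weight: float, ecm: float, dip: float) -> HpuResult:
    """Heat producing unit (x 10^3 W) and predicted CO2 output (L/day).

    HPU = (5.6 LW^0.75 + 22 ECM + 1.6e-3 DIP) / 1000 (CIGR), and the
    predicted daily CO2 volume is HPU x 180 L/h x 24 h.
    """
    if live_weight <= 0:
        raise ValueError("live_weight must be positive")
    if ecm < 0 or dip < 0:
        raise ValueError("ecm and days in pregnancy must be non-negative")
    hpu = (5.6 * live_weight**0.75 + 22.0 * ecm + 1.6e-3 * dip) / 1000.0
    co2 = hpu * CO2_L_PER_HOUR_PER_HPU * 24.0
    return HpuResult(hpu=hpu, days_in_pregnancy=dip, co2_predicted=co2)


def predict_ch4_hpu(ratio: float, hpu: float) -> float:
    """Daily CH4 (L/day) by the CO2-tracer route.

    CH4 = CH4/CO2 ratio x 180 x HPU x 24, i.e. the breath ratio scaled
    by the HPU-predicted daily CO2 volume.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if hpu <= 0:
        raise ValueError("hpu must be positive")
    return ratio * CO2_L_PER_HOUR_PER_HPU * hpu * 24.0


def evaluate_equation(spec: EquationSpec, covariates: Mapping[str, float]) -> float:
    """Evaluate a linear prediction equation at the given covariates.

    Every covariate the equation uses must be supplied; extra keys are
    ignored. Returns the response in the equation's units (L/day for
    CH4 equations, J/100 J GEI for MCF equations).
    """
    missing = [k for k in spec.coefficients if k not in covariates]
    if missing:
        raise KeyError(f"equation {spec.name!r} is missing covariate(s) {missing}")
    return spec.intercept + sum(
        coef * float(covariates[key]) for key, coef in spec.coefficients.items()
    )


def compute_mcf(ch4: float, gei: float, ch4_energy: float = CH4_ENERGY_KJ_PER_L) -> float:
    """Methane conversion factor (J CH4 energy per 100 J GEI).

    MCF = (ch4 [L/day] x ch4_energy [kJ/L] / 1000) / GEI [MJ/day] x 100.
    """
    if gei <= 0:
        raise ValueError("gei must be positive")
    if ch4 < 0:
        raise ValueError("ch4 must be non-negative")
    return ch4 * ch4_energy / 1000.0 / gei * 100.0


def _spec_from_dict(name: str, d: Mapping) -> EquationSpec:
    return EquationSpec(
        name=name,
        response=d["response"],
        intercept=float(d["intercept"]),
        intercept_se=float(d["intercept_se"]) if d.get("intercept_se") is not None else None,
        coefficients={k: float(v) for k, v in d["coefficients"].items()},
        coefficient_se={k: float(v) for k, v in d.get("coefficient_se", {}).items()},
        adj_r2=float(d["adj_r2"]) if d.get("adj_r2") is not None else None,
        rmse=float(d["rmse"]) if d.get("rmse") is not None else None,
    )


def load_equations(path: str | None = None) -> dict[str, EquationSpec]:
    """Load an equation bundle.

    With no ``path`` the twelve bundled published equations (eq1-eq12)
    are returned. A path may point to any file in the same YAML
    dialect, e.g. one written by the model-fitting layer, so refitted
    equations round-trip back into the evaluator.
    """
    if path is None:
        text = resources.files("entch4.data").joinpath("published_equations.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["equations"]
    return {name: _spec_from_dict(name, d) for name, d in raw.items()}


def save_equations(specs: Mapping[str, EquationSpec], path: str) -> None:
    """Write equation specs in the same YAML dialect ``load_equations`` reads."""
    out = {}
    for name, s in specs.items():
        out[name] = {
            "response": s.response,
            "intercept": float(s.intercept),
            "intercept_se": None if s.intercept_se is None else float(s.intercept_se),
            "coefficients": {k: float(v) for k, v in s.coefficients.items()},
            "coefficient_se": {k: float(v) for k, v in s.coefficient_se.items()},
            "adj_r2": None if s.adj_r2 is None else float(s.adj_r2),
            "rmse": None if s.rmse is None else float(s.rmse),
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"equations": out}, fh, sort_keys=False)


_COW_COLUMNS = [
    "cow_id",
    "live_weight",
    "milk_yield",
    "milk_fat",
    "milk_protein",
    "dmi",
    "days_in_milk",
    "gei",
    "diet",
]


def read_cow_table(path) -> pd.DataFrame:
    """Read a cow table CSV (one row per cow-period).

    Required columns: cow_id, live_weight, milk_yield, milk_fat,
    milk_protein, dmi, days_in_milk, gei; ``diet`` is optional and
    defaults to ``other``. An ``ecm`` column is added.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COW_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"cow table is missing column(s) {missing}")
    if "diet" not in df.columns:
        df["diet"] = "other"
    df["ecm"] = compute_ecm(
        df["milk_yield"].to_numpy(),
        df["milk_fat"].to_numpy(),
        df["milk_protein"].to_numpy(),
    )
    return df
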