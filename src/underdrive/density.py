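"""Density-dependent intraspecific competition.

Three classical single-species competition functions — Maynard Smith &
Slatkin (MSS), Hassell, and Bellows — each in two modes:

* births: a multiplicative factor f(N) in (0, 1] on the birth rate, with
  f(0) = 1, strictly decreasing in total density N;
* deaths: an additive hazard f(N) >= 0 on top of the baseline death
  rate, with f(0) = 0, strictly increasing in N.

=========  =======================  =====================
family     births f(N)              deaths f(N)
=========  =======================  =====================
MSS        (1 + (aN)^b)^-1          ln(1 + (aN)^b)
Hassell    (1 + aN)^-b              b * ln(1 + aN)
Bellows    exp(-a N^b)              a N^b
=========  =======================  =====================

b is the compensation strength (b < 1 undercompensating, b = 1 perfect,
b > 1 overcompensating); at b = 1 MSS and Hassell coincide. The scaling
parameter a is calibrated in closed form so that wild-type dynamics
equilibrate at a target density K. Note the Bellows family applies a
*after* the exponent (a*N^b), so a is not dimensionally comparable
across families; compare the dimensionless f values instead.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Family",
    "Mode",
    "EcologicalRates",
    "DensityModel",
    "feedback",
    "solve_density_parameter",
    "calibrated_model",
    "per_capita_growth",
]


class Family(str, enum.Enum):
    MSS = "mss"
    HASSELL = "hassell"
    BELLOWS = "bellows"


class Mode(str, enum.Enum):
    BIRTHS = "births"
    DEATHS = "deaths"


@dataclass(frozen=True)
class EcologicalRates:
    """Per-capita birth rate r and death rate mu, per day.

    Defaults approximate Anopheles mosquitoes. A positive equilibrium
    requires r > mu > 0.
    """

    r: float = 1.1
    mu: float = 0.1

    def __post_init__(self) -> None:
        if not self.r > self.mu > 0.0:
            raise ValueError(
                f"need r > mu > 0 for a positive equilibrium, got r={self.r}, mu={self.mu}"
            )


@dataclass(frozen=True)
class DensityModel:
    """A density-dependence family/mode with strength b and scaling a."""

    family: Family
    mode: Mode
    b: float
    a: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "mode", Mode(self.mode))
        if not self.b > 0.0:
            raise ValueError(f"compensation strength b must be positive, got {self.b}")
        if not self.a > 0.0:
            raise ValueError(f"density scaling a must be positive, got {self.a}")

    def feedback(self, total: np.ndarray | float) -> np.ndarray | float:
        return feedback(self, total)


def feedback(model: DensityModel, total: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the competition function f at total density N.

    Births mode returns the multiplicative birth factor in (0, 1];
    deaths mode the additive death hazard >= 0.
    """
    n = np.asarray(total, dtype=float)
    if np.any(n < 0.0):
        raise ValueError("total density must be non-negative")
    a, b = model.a, model.b
    if model.mode is Mode.BIRTHS:
        if model.family is Family.MSS:
            out = 1.0 / (1.0 + (a * n) ** b)
        elif model.family is Family.HASSELL:
            out = (1.0 + a * n) ** -b
        else:
            out = np.exp(-a * n**b)
    else:
        if model.family is Family.MSS:
            out = np.log1p((a * n) ** b)
        elif model.family is Family.HASSELL:
            out = b * np.log1p(a * n)
        else:
            out = a * n**b
    return out if np.ndim(total) else float(out)


def solve_density_parameter(
    family: Family | str,
    mode: Mode | str,
    b: float,
    rates: EcologicalRates,
    K: float,
) -> float:
    """Scaling parameter a giving a wild-type equilibrium at density K.

    At equilibrium births balance deaths: births mode requires
    f(K) = mu/r, deaths mode f(K) = r - mu. All six combinations invert
    in closed form.
    """
    family, mode = Family(family), Mode(mode)
    if K <= 0.0:
        raise ValueError(f"target equilibrium K must be positive, got {K}")
    if b <= 0.0:
        raise ValueError(f"compensation strength b must be positive, got {b}")
    ratio = rates.r / rates.mu
    span = rates.r - rates.mu
    if mode is Mode.BIRTHS:
        if family is Family.MSS:
            aK = (ratio - 1.0) ** (1.0 / b)
        elif family is Family.HASSELL:
            aK = ratio ** (1.0 / b) - 1.0
        else:
            return math.log(ratio) / K**b
    else:
        if family is Family.MSS:
            aK = math.expm1(span) ** (1.0 / b)
        elif family is Family.HASSELL:
            aK = math.expm1(span / b)
        else:
            return span / K**b
    return aK / K


def calibrated_model(
    family: Family | str,
    mode: Mode | str,
    b: float,
    rates: EcologicalRates = EcologicalRates(),
    K: float = 10_000.0,
) -> DensityModel:
    """A DensityModel with a solved so the wild-type equilibrium is K."""
    a = solve_density_parameter(family, mode, b, rates, K)
    return DensityModel(family=Family(family), mode=Mode(mode), b=b, a=a)


def recalibrated(model: DensityModel, rates: EcologicalRates, K: float) -> DensityModel:
    """Same family/mode/b, a re-solved for new rates at equilibrium K."""
    return replace(model, a=solve_density_parameter(model.family, model.mode, model.b, rates, K))


def per_capita_growth(
    model: DensityModel,
    rates: EcologicalRates,
    total: np.ndarray | float,
) -> np.ndarray | float:
    """Net per-capita growth rate (per day) at total density N.

    Births mode: r*f(N) - mu; deaths mode: r - (mu + f(N)). With default
    rates and calibrated a the growth rate is 1 at vanishing density and
    0 exactly at the equilibrium.
    """
    f = feedback(model, total)
    if model.mode is Mode.BIRTHS:
        return rates.r * f - rates.mu
    return rates.r - (rates.mu + f)
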