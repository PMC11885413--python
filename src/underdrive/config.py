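"""Run configuration: a validated YAML-backed schema.

Defaults equal the study's baseline: r = 1.1 / day, mu = 0.1 / day,
equilibrium K = 10,000, 10-generation burn-in, 1:1 release and a
200-generation horizon. Unknown keys are rejected so silent typos cannot
change a run. The density scaling parameter ``a`` is usually left as
``"auto"`` and solved from (family, mode, b, r, mu, K).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .density import (
    DensityModel,
    EcologicalRates,
    solve_density_parameter,
)
from .dynamics import ModelSpec, SimulationProtocol
from .genetics import FitnessParams

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RatesConfig(_Strict):
    r: float = 1.1
    mu: float = 0.1


class DensityConfig(_Strict):
    family: Literal["mss", "hassell", "bellows"] = "mss"
    mode: Literal["births", "deaths"] = "births"
    b: float = 1.0
    a: float | Literal["auto"] = "auto"


class FitnessConfig(_Strict):
    s_a: float = 0.0
    s_b: float = 0.0
    h_a: float = 0.5
    h_b: float = 0.5


class ModelConfig(_Strict):
    rates: RatesConfig = Field(default_factory=RatesConfig)
    density: DensityConfig = Field(default_factory=DensityConfig)
    fitness: FitnessConfig = Field(default_factory=FitnessConfig)


class ProtocolConfig(_Strict):
    K: float = 10_000.0
    burn_in: int = 10
    release_ratio: float = 1.0
    horizon: int = 200
    generation_length: float = 10.0
    dt: float = 0.1


class ExperimentConfig(_Strict):
    """Grids for the scan subcommands; unused fields are ignored by
    commands that do not need them."""

    s_min: float = 0.0
    s_max: float = 0.30
    s_step: float = 0.01
    h_min: float = 0.0
    h_max: float = 1.0
    h_step: float = 0.01
    s_fixed: float = 0.23
    h_fixed: float = 0.5
    ratio_min: float = 1.0
    ratio_max: float = 2.0
    ratio_step: float = 0.1
    sa_max: float = 0.5


class RunConfig(_Strict):
    model: ModelConfig = Field(default_factory=ModelConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)
    output_dir: str = "."

    # -- converters to domain objects -------------------------------------
    def rates(self) -> EcologicalRates:
        return EcologicalRates(r=self.model.rates.r, mu=self.model.rates.mu)

    def density(self) -> DensityModel:
        d = self.model.density
        a = d.a
        if a == "auto":
            a = solve_density_parameter(d.family, d.mode, d.b, self.rates(), self.protocol.K)
        return DensityModel(family=d.family, mode=d.mode, b=d.b, a=a)

    def fitness(self) -> FitnessParams:
        f = self.model.fitness
        return FitnessParams(s_a=f.s_a, s_b=f.s_b, h_a=f.h_a, h_b=f.h_b)

    def spec(self) -> ModelSpec:
        return ModelSpec(rates=self.rates(), density=self.density(), fitness=self.fitness())

    def sim_protocol(self) -> SimulationProtocol:
        p = self.protocol
        return SimulationProtocol(
            K=p.K,
            burn_in=p.burn_in,
            release_ratio=p.release_ratio,
            horizon=p.horizon,
            generation_length=p.generation_length,
            dt=p.dt,
        )


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Read a YAML config file and apply dotted-key overrides.

    Overrides use keys like ``"model.density.family"``; None values are
    dropped. With no path, defaults apply.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return RunConfig.model_validate(data)
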