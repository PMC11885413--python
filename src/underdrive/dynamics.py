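"""Coupled genetic-ecological ODE system and its fixed-step integrator.

The state is the vector of nine genotype densities N_i. Births replace
parental densities with panmictic offspring densities nu_i, weighted by
relative fitness psi_i (fitness always acts at birth); deaths are linear.
Density dependence enters either as a multiplicative factor on births or
an additive hazard on deaths, as a function of total density:

    births:  dN_i/dt = r * nu_i * psi_i * f(N) - mu * N_i
    deaths:  dN_i/dt = r * nu_i * psi_i - (mu + f(N)) * N_i

Random union of gametes conserves density (sum nu_i == sum N_i), so the
competition argument is evaluated on sum N_i directly.

Integration uses classical fourth-order Runge-Kutta with a fixed step,
which keeps trajectories bit-reproducible. The release protocol is:
establish the wild type at its equilibrium K for a burn-in period, add
an instantaneous cohort of drive homozygotes (AABB) proportional to the
current wild-type density, then integrate to the horizon.

The integrator broadcasts over leading batch axes of the fitness table,
so many release experiments sharing one ecological configuration can be
integrated simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import DensityModel, EcologicalRates, Mode
from .genetics import (
    GENOTYPE_LABELS,
    N_GENOTYPES,
    WILD_TYPE,
    FitnessParams,
    fitness_table,
    offspring_densities,
    partition,
)

__all__ = [
    "ModelSpec",
    "SimulationProtocol",
    "Trajectory",
    "derivative",
    "rk4_step",
    "simulate",
    "trajectory_frame",
]


@dataclass(frozen=True)
class ModelSpec:
    """Ecological rates, density dependence and drive fitness together."""

    rates: EcologicalRates
    density: DensityModel
    fitness: FitnessParams


@dataclass(frozen=True)
class SimulationProtocol:
    """Release protocol and integrator settings.

    K : wild-type equilibrium density the model is calibrated to.
    burn_in : generations of wild-type-only settling before release.
    release_ratio : released AABB density per unit wild-type density.
    horizon : generations simulated after release.
    generation_length : days per generation. Durations given in
        generations are converted with this factor; equilibrium outcomes
        and thresholds do not depend on it, absolute day-times do.
    dt : integrator step in days.
    """

    K: float = 10_000.0
    burn_in: int = 10
    release_ratio: float = 1.0
    horizon: int = 200
    generation_length: float = 10.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if min(self.K, self.generation_length, self.dt) <= 0 or self.burn_in < 0:
            raise ValueError("K, generation_length, dt must be positive; burn_in >= 0")
        if self.release_ratio < 0 or self.horizon <= 0:
            raise ValueError("release_ratio must be >= 0 and horizon positive")
        if self.dt > self.generation_length / 10.0:
            raise ValueError("dt must not exceed generation_length / 10")

    @property
    def steps_per_generation(self) -> int:
        return max(1, round(self.generation_length / self.dt))


@dataclass
class Trajectory:
    """Genotype densities sampled once per generation.

    states has shape (n_samples, ..., 9); any middle axes index a batch
    of fitness parameterisations integrated together. The release
    happens instantaneously at ``release_time``; the pre-release state
    is the sample at ``release_index`` and the post-release state (with
    the AABB cohort added) at ``release_index + 1``, both at the same
    time stamp.
    """

    times: np.ndarray
    states: np.ndarray
    release_time: float
    release_index: int
    max_clamp: float = 0.0
    generation_length: float = 10.0

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def generations_after_release(self) -> np.ndarray:
        """Whole generations elapsed since release for each sample."""
        return (self.times - self.release_time) / self.generation_length


def derivative(state: np.ndarray, spec: ModelSpec, psi: np.ndarray | None = None) -> np.ndarray:
    """Rates of change of the nine genotype densities."""
    n = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(n)):
        raise ValueError("non-finite genotype densities")
    if psi is None:
        psi = fitness_table(spec.fitness)
    return _rhs(n, psi, spec.density, spec.rates)


def _rhs(n: np.ndarray, psi: np.ndarray, density: DensityModel, rates: EcologicalRates) -> np.ndarray:
    nu = offspring_densities(n)
    total = n.sum(axis=-1, keepdims=True)
    f = density.feedback(total)
    births = rates.r * nu * psi
    if density.mode is Mode.BIRTHS:
        return births * f - rates.mu * n
    return births - (rates.mu + f) * n


def rk4_step(
    state: np.ndarray,
    spec: ModelSpec,
    dt: float,
    psi: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """One classical RK4 step.

    Negative components produced by truncation error are clamped to
    zero; the magnitude of the largest clamp is returned alongside the
    new state so callers can audit it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = np.asarray(state, dtype=float)
    if psi is None:
        psi = fitness_table(spec.fitness)
    density, rates = spec.density, spec.rates
    k1 = _rhs(n, psi, density, rates)
    k2 = _rhs(np.maximum(n + 0.5 * dt * k1, 0.0), psi, density, rates)
    k3 = _rhs(np.maximum(n + 0.5 * dt * k2, 0.0), psi, density, rates)
    k4 = _rhs(np.maximum(n + dt * k3, 0.0), psi, density, rates)
    new = n + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    clamp = float(max(0.0, -new.min())) if new.size else 0.0
    return np.maximum(new, 0.0), clamp


def _integrate(
    state: np.ndarray,
    psi: np.ndarray,
    density: DensityModel,
    rates: EcologicalRates,
    generations: int,
    protocol: SimulationProtocol,
    t0: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Integrate ``generations`` generations, sampling once per generation.

    Returns (times, states, max_clamp) where states[0] is the input.
    """
    spg = protocol.steps_per_generation
    dt = protocol.generation_length / spg
    blow_up = 1e3 * protocol.K
    samples = np.empty((generations + 1, *state.shape))
    samples[0] = state
    times = t0 + protocol.generation_length * np.arange(generations + 1)
    spec = ModelSpec(rates=rates, density=density, fitness=FitnessParams())
    max_clamp = 0.0
    n = state
    for g in range(generations):
        for s in range(spg):
            n, clamp = rk4_step(n, spec, dt, psi=psi)
            max_clamp = max(max_clamp, clamp)
            if not np.all(np.isfinite(n)) or n.max(initial=0.0) > blow_up:
                raise RuntimeError(
                    f"integration blow-up at generation {g}, step {s} (t = {times[g] + (s + 1) * dt:.2f} days)"
                )
        samples[g + 1] = n
    return times, samples, max_clamp


def simulate(
    spec: ModelSpec,
    protocol: SimulationProtocol = SimulationProtocol(),
    psi: np.ndarray | None = None,
) -> Trajectory:
    """Run the burn-in / release / horizon protocol.

    Phase 1 initialises a pure wild-type population at K and integrates
    ``burn_in`` generations; phase 2 instantaneously adds an AABB cohort
    of ``release_ratio`` times the current wild-type density; phase 3
    integrates ``horizon`` further generations.

    ``psi`` may supply a batch of fitness vectors with shape (..., 9) to
    integrate many releases under the same ecology at once; by default
    it is derived from ``spec.fitness``.
    """
    if psi is None:
        psi = fitness_table(spec.fitness)
    psi = np.asarray(psi, dtype=float)

    state0 = np.zeros(psi.shape)
    state0[..., WILD_TYPE] = protocol.K
    t_burn, s_burn, clamp1 = _integrate(
        state0, psi, spec.density, spec.rates, protocol.burn_in, protocol, t0=0.0
    )

    released = s_burn[-1].copy()
    released[..., 0] += protocol.release_ratio * released[..., WILD_TYPE]
    t_run, s_run, clamp2 = _integrate(
        released, psi, spec.density, spec.rates, protocol.horizon, protocol, t0=t_burn[-1]
    )

    times = np.concatenate([t_burn, t_run])
    states = np.concatenate([s_burn, s_run])
    return Trajectory(
        times=times,
        states=states,
        release_time=float(t_burn[-1]),
        release_index=protocol.burn_in,
        max_clamp=max(clamp1, clamp2),
        generation_length=protocol.generation_length,
    )


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy per-generation table of a (non-batched) trajectory."""
    states = traj.states
    if states.ndim != 2:
        raise ValueError("trajectory_frame expects a single (non-batched) trajectory")
    wild, drive, total = partition(states)
    df = pd.DataFrame(states, columns=[f"N_{g}" for g in GENOTYPE_LABELS])
    df.insert(0, "time_days", traj.times)
    df.insert(1, "generation", np.round(traj.times / traj.generation_length).astype(int))
    df["N_total"] = total
    df["N_drive"] = drive
    df["N_wildtype"] = wild
    return df
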