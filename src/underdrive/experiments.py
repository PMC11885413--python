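"""Release experiments: outcome metrics, parameter scans, sensitivity.

Every experiment runs the same protocol — wild-type burn-in, 1:1 drive
homozygote release, fixed horizon — and summarises each run by three
efficacy measures: final total density, final drive-carrying density,
and the wild-type *return time* (generations after release until the
wild-type density again exceeds 99% of the pre-release equilibrium,
censored when the drive fixes and no recovery occurs).

Because the drive is a high-threshold system, each scan exhibits a sharp
establishment threshold in the fitness cost s (and, near-threshold, in
the dominance h). The threshold is a property of the genetics alone: a
frequency-only discrete-generation recursion with no ecology at all
(`discrete_generation_establishment`) reproduces the same classification
and serves as an independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import (
    DensityModel,
    EcologicalRates,
    Family,
    Mode,
    calibrated_model,
)
from .dynamics import ModelSpec, SimulationProtocol, Trajectory, simulate
from .genetics import FitnessParams, fitness_table, offspring_densities, partition

__all__ = [
    "OutcomeMetrics",
    "ScanResult",
    "HeatmapResult",
    "outcome_metrics",
    "scan_s",
    "scan_h",
    "heatmap_asymmetric",
    "sensitivity_scenarios",
    "discrete_generation_establishment",
    "frequency_dynamics_establishment",
    "all_density_configs",
    "DEFAULT_SCENARIOS",
    "FAST_PROTOCOL",
]

#: Drive-carrying frequency at the horizon above which the drive is
#: classified as established, and below one minus which as lost.
ESTABLISHED_FREQ = 0.99
LOST_FREQ = 0.01

#: Coarser profile for quick runs: s step 0.05, 100-generation horizon.
FAST_PROTOCOL = SimulationProtocol(horizon=100)

#: Ecological scenarios probed by the sensitivity analysis.
DEFAULT_SCENARIOS = {
    "control": EcologicalRates(r=1.1, mu=0.1),
    "high_r": EcologicalRates(r=2.1, mu=0.1),
    "high_mu": EcologicalRates(r=1.1, mu=0.2),
}


@dataclass(frozen=True)
class OutcomeMetrics:
    """Efficacy summary of one release simulation.

    wildtype_return_generations is None (censored) when the wild type
    never re-exceeds the 99% threshold within the horizon — in
    particular whenever the drive establishes.
    """

    final_total: float
    final_drive_carrying: float
    wildtype_return_generations: int | None
    establishment: str  # "established" | "lost" | "undetermined"

    @property
    def final_wildtype(self) -> float:
        return self.final_total - self.final_drive_carrying


def _classify(drive_freq: float) -> str:
    if drive_freq >= ESTABLISHED_FREQ:
        return "established"
    if drive_freq <= LOST_FREQ:
        return "lost"
    return "undetermined"


def _return_time(wild_series: np.ndarray, threshold: float) -> int | None:
    """First whole generation after release at which the wild type is
    back above ``threshold``, having been at or below it at some earlier
    post-release sample; 0 if it never dipped; None if censored."""
    below = wild_series <= threshold
    if not below.any():
        return 0
    first_below = int(np.argmax(below))
    above_again = wild_series[first_below:] > threshold
    if not above_again.any():
        return None
    return first_below + int(np.argmax(above_again))


def outcome_metrics(traj: Trajectory, protocol: SimulationProtocol) -> OutcomeMetrics:
    """Efficacy measures of a single (non-batched) trajectory."""
    if traj.states.ndim != 2:
        raise ValueError("outcome_metrics expects a single trajectory; see batch helpers")
    return _outcomes_batch(traj, protocol)[0]


def _outcomes_batch(traj: Trajectory, protocol: SimulationProtocol) -> list[OutcomeMetrics]:
    """Outcome metrics for each run of a (possibly batched) trajectory."""
    states = traj.states
    if states.ndim == 2:
        states = states[:, None, :]
    post = states[traj.release_index + 1 :]  # generations 0..horizon after release
    wild, drive, total = partition(post)
    threshold = 0.99 * protocol.K
    out = []
    for j in range(post.shape[1]):
        ft, fd = float(total[-1, j]), float(drive[-1, j])
        freq = fd / ft if ft > 0 else 0.0
        out.append(
            OutcomeMetrics(
                final_total=ft,
                final_drive_carrying=fd,
                wildtype_return_generations=_return_time(wild[:, j], threshold),
                establishment=_classify(freq),
            )
        )
    return out


@dataclass
class ScanResult:
    """A 1-D parameter scan and its establishment threshold.

    threshold is the largest grid value at which the drive establishes,
    or None if it establishes nowhere on the grid.
    """

    parameter: str
    grid: np.ndarray
    metrics: list[OutcomeMetrics]
    threshold: float | None
    config: dict

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                self.parameter: self.grid,
                "final_total": [m.final_total for m in self.metrics],
                "final_drive": [m.final_drive_carrying for m in self.metrics],
                "return_generations": [
                    m.wildtype_return_generations for m in self.metrics
                ],
                "establishment": [m.establishment for m in self.metrics],
            }
        )
        df["threshold"] = self.threshold
        return df


def _run_scan(
    parameter: str,
    grid: np.ndarray,
    psi: np.ndarray,
    density: DensityModel,
    rates: EcologicalRates,
    protocol: SimulationProtocol,
    config: dict,
) -> ScanResult:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError(f"{parameter} grid must be strictly increasing")
    spec = ModelSpec(rates=rates, density=density, fitness=FitnessParams())
    traj = simulate(spec, protocol, psi=psi)
    metrics = _outcomes_batch(traj, protocol)
    established = [g for g, m in zip(grid, metrics) if m.establishment == "established"]
    threshold = float(max(established)) if established else None
    return ScanResult(parameter, grid, metrics, threshold, config)


def scan_s(
    density: DensityModel,
    grid: np.ndarray,
    h: float = 0.5,
    rates: EcologicalRates = EcologicalRates(),
    protocol: SimulationProtocol = SimulationProtocol(),
) -> ScanResult:
    """Scan the (equal-locus) fitness cost s at fixed dominance h."""
    grid = np.asarray(grid, dtype=float)
    psi = np.stack([fitness_table(FitnessParams.symmetric(s, h)) for s in grid])
    cfg = {"parameter": "s", "h": h, "family": density.family.value, "mode": density.mode.value, "b": density.b}
    return _run_scan("s", grid, psi, density, rates, protocol, cfg)


def scan_h(
    density: DensityModel,
    grid: np.ndarray,
    s: float = 0.23,
    rates: EcologicalRates = EcologicalRates(),
    protocol: SimulationProtocol = SimulationProtocol(),
) -> ScanResult:
    """Scan the dominance h at fixed (equal-locus) fitness cost s."""
    grid = np.asarray(grid, dtype=float)
    psi = np.stack([fitness_table(FitnessParams.symmetric(s, h)) for h in grid])
    cfg = {"parameter": "h", "s": s, "family": density.family.value, "mode": density.mode.value, "b": density.b}
    return _run_scan("h", grid, psi, density, rates, protocol, cfg)


@dataclass
class HeatmapResult:
    """Final-total percentages over an (s_b/s_a ratio) x s_a grid."""

    s_a_grid: np.ndarray
    ratio_grid: np.ndarray
    percent_total: np.ndarray  # (n_ratio, n_sa), 100 * final_total / K
    established: np.ndarray  # boolean, same shape
    boundary_s_a: np.ndarray  # per ratio row: largest establishing s_a (nan if none)
    config: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ratio in enumerate(self.ratio_grid):
            for j, sa in enumerate(self.s_a_grid):
                rows.append(
                    {
                        "s_a": sa,
                        "ratio": ratio,
                        "s_b": ratio * sa,
                        "percent_total": self.percent_total[i, j],
                        "established": bool(self.established[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def heatmap_asymmetric(
    density: DensityModel,
    s_a_grid: np.ndarray,
    ratio_grid: np.ndarray,
    h: float = 0.5,
    rates: EcologicalRates = EcologicalRates(),
    protocol: SimulationProtocol = SimulationProtocol(),
) -> HeatmapResult:
    """Release outcomes with asymmetric locus costs s_b = ratio * s_a.

    Cell values are final total density as a percentage of K. The
    establishment boundary (largest establishing s_a per ratio row)
    declines roughly linearly as the ratio rises.
    """
    s_a_grid = np.asarray(s_a_grid, dtype=float)
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    if np.max(ratio_grid) * np.max(s_a_grid) > 1.0 + 1e-12:
        raise ValueError("s_b = ratio * s_a exceeds 1 somewhere on the grid")
    psi = np.stack(
        [
            np.stack(
                [
                    fitness_table(FitnessParams(s_a=sa, s_b=min(r * sa, 1.0), h_a=h, h_b=h))
                    for sa in s_a_grid
                ]
            )
            for r in ratio_grid
        ]
    )  # (n_ratio, n_sa, 9)
    spec = ModelSpec(rates=rates, density=density, fitness=FitnessParams())
    flat = psi.reshape(-1, 9)
    traj = simulate(spec, protocol, psi=flat)
    metrics = _outcomes_batch(traj, protocol)
    shape = (len(ratio_grid), len(s_a_grid))
    percent = np.array([100.0 * m.final_total / protocol.K for m in metrics]).reshape(shape)
    est = np.array([m.establishment == "established" for m in metrics]).reshape(shape)
    boundary = np.array(
        [s_a_grid[row].max() if row.any() else np.nan for row in est]
    )
    cfg = {"h": h, "family": density.family.value, "mode": density.mode.value, "b": density.b}
    return HeatmapResult(s_a_grid, ratio_grid, percent, est, boundary, cfg)


def all_density_configs(
    bs: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> list[tuple[Family, Mode, float]]:
    """The 18 (family, mode, b) density-dependence configurations."""
    return [
        (fam, mode, b)
        for fam, mode, b in itertools.product(Family, Mode, bs)
    ]


def sensitivity_scenarios(
    s_grid: np.ndarray,
    configs: list[tuple[Family, Mode, float]] | None = None,
    scenarios: dict[str, EcologicalRates] | None = None,
    h: float = 0.5,
    protocol: SimulationProtocol = SimulationProtocol(),
) -> pd.DataFrame:
    """Wild-type return times across ecological scenarios.

    For each scenario the density parameter a is re-solved so the
    wild-type equilibrium stays at protocol.K; return times are then
    compared across scenarios at each fitness cost. Returns a tidy frame
    with one row per (scenario, config, s).
    """
    if configs is None:
        configs = [
            (fam, Mode.BIRTHS, b) for fam, b in itertools.product(Family, (0.5, 2.0))
        ]
    if scenarios is None:
        scenarios = DEFAULT_SCENARIOS
    rows = []
    for name, rates in scenarios.items():
        for fam, mode, b in configs:
            density = calibrated_model(fam, mode, b, rates, protocol.K)
            result = scan_s(density, s_grid, h=h, rates=rates, protocol=protocol)
            for s, m in zip(result.grid, result.metrics):
                rows.append(
                    {
                        "scenario": name,
                        "r": rates.r,
                        "mu": rates.mu,
                        "family": fam.value,
                        "mode": mode.value,
                        "b": b,
                        "s": s,
                        "final_total": m.final_total,
                        "return_generations": m.wildtype_return_generations,
                        "establishment": m.establishment,
                    }
                )
    return pd.DataFrame(rows)


def discrete_generation_establishment(
    fitness: FitnessParams,
    release_ratio: float = 1.0,
    generations: int = 200,
) -> str:
    """Establishment classification from genetics alone.

    A discrete-generation recursion on genotype *frequencies*: each
    generation the panmictic offspring frequencies are weighted by
    relative fitness and renormalised — no births, deaths or density
    dependence. Agreement of this recursion's establishment/loss call
    with the full ecological model demonstrates that the invasion
    threshold is determined by the drive genetics, not the ecology.
    """
    psi = fitness_table(fitness)
    freq = np.zeros(9)
    freq[0] = release_ratio / (1.0 + release_ratio)
    freq[-1] = 1.0 / (1.0 + release_ratio)
    for _ in range(generations):
        nu = offspring_densities(freq)
        weighted = nu * psi
        total = weighted.sum()
        if total <= 0.0:
            freq = np.zeros(9)
            break
        freq = weighted / total
    wild, drive, total = partition(freq)
    return _classify(float(drive / total) if total > 0 else 0.0)


def frequency_dynamics_establishment(
    fitness: FitnessParams,
    release_ratio: float = 1.0,
    days: float = 4000.0,
    dt: float = 0.1,
) -> str:
    """Establishment from the continuous-time frequency dynamics.

    In the full model the genotype-frequency dynamics decouple from the
    ecology: under death-acting density dependence the competition term
    cancels exactly from dp_i/dt, and under birth-acting density
    dependence it only rescales time. What remains is the replicator-type
    system

        dp_i/dt = q_i(p) * psi_i - p_i * sum_j q_j(p) * psi_j,

    with q(p) the panmictic offspring frequencies. Its basin boundary is
    therefore *the* establishment threshold shared by every density
    configuration; this integrator reproduces the full model's threshold
    exactly, while the generation-based recursion in
    `discrete_generation_establishment` is a genuinely different
    dynamical system and can place the threshold a few grid steps away.
    """
    psi = fitness_table(fitness)
    p = np.zeros(9)
    p[0] = release_ratio / (1.0 + release_ratio)
    p[-1] = 1.0 / (1.0 + release_ratio)

    def rhs(p: np.ndarray) -> np.ndarray:
        q = offspring_densities(np.maximum(p, 0.0))
        w = q * psi
        return w - p * w.sum()

    for _ in range(int(days / dt)):
        k1 = rhs(p)
        k2 = rhs(p + 0.5 * dt * k1)
        k3 = rhs(p + 0.5 * dt * k2)
        k4 = rhs(p + dt * k3)
        p = np.maximum(p + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), 0.0)
        p /= p.sum()
    wild, drive, total = partition(p)
    return _classify(float(drive / total) if total > 0 else 0.0)
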