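"""ODE assembly, RK4 integration and the release protocol."""

import numpy as np
import pytest

from underdrive import (
    DensityModel,
    EcologicalRates,
    FitnessParams,
    ModelSpec,
    SimulationProtocol,
    calibrated_model,
    derivative,
    rk4_step,
    simulate,
    trajectory_frame,
)
from underdrive.dynamics import _integrate
from underdrive.experiments import all_density_configs
from underdrive.genetics import GENOTYPE_LABELS, WILD_TYPE, fitness_table

K = 10_000.0


def wt_state(density: float) -> np.ndarray:
    n = np.zeros(9)
    n[WILD_TYPE] = density
    return n


def default_spec(family="mss", mode="births", b=1.0, s=0.0, h=0.5, rates=None) -> ModelSpec:
    rates = rates or EcologicalRates()
    return ModelSpec(
        rates=rates,
        density=calibrated_model(family, mode, b, rates, K),
        fitness=FitnessParams.symmetric(s, h),
    )


class TestDerivative:
    @pytest.mark.parametrize("family, mode, b", all_density_configs())
    def test_wild_type_equilibrium_is_fixed_point(self, family, mode, b):
        spec = default_spec(family, mode, b)
        np.testing.assert_allclose(derivative(wt_state(K), spec), np.zeros(9), atol=1e-9)

    def test_empty_state_has_zero_derivative(self):
        np.testing.assert_array_equal(derivative(np.zeros(9), default_spec()), np.zeros(9))

    def test_hand_computed_value_below_equilibrium(self):
        # wild type at 5000 under MSS births b=1 (a = 1e-3):
        # dN/dt = 1.1 * 5000 * (1/6) - 0.1 * 5000
        d = derivative(wt_state(5000.0), default_spec())
        assert d[WILD_TYPE] == pytest.approx(1.1 * 5000 / 6 - 500.0)
        assert np.all(d[:WILD_TYPE] == 0.0)

    def test_non_finite_state_rejected(self):
        bad = wt_state(K)
        bad[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            derivative(bad, default_spec())


class TestRK4Step:
    def test_equilibrium_is_fixed(self):
        spec = default_spec()
        new, clamp = rk4_step(wt_state(K), spec, dt=0.1)
        np.testing.assert_allclose(new, wt_state(K), rtol=1e-12)
        assert clamp == 0.0

    def test_empty_state_stays_empty(self):
        new, _ = rk4_step(np.zeros(9), default_spec(), dt=0.1)
        np.testing.assert_array_equal(new, np.zeros(9))

    def test_fourth_order_convergence(self):
        # Richardson: over a fixed interval, halving dt cuts the error ~16x
        spec = default_spec(s=0.2)
        start = np.full(9, 500.0)

        def advance(dt, steps):
            n = start
            for _ in range(steps):
                n, _ = rk4_step(n, spec, dt)
            return n

        ref = advance(0.005, 800)
        err_coarse = np.abs(advance(0.4, 10) - ref).max()
        err_fine = np.abs(advance(0.2, 20) - ref).max()
        assert 8.0 < err_coarse / err_fine < 32.0

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            rk4_step(wt_state(K), default_spec(), dt=0.0)


class TestSimulate:
    def test_zero_release_stays_at_equilibrium(self):
        proto = SimulationProtocol(release_ratio=0.0, horizon=20)
        traj = simulate(default_spec(), proto)
        totals = traj.states.sum(axis=-1)
        np.testing.assert_allclose(totals, K, rtol=1e-6)

    def test_costless_drive_fixes_and_population_recovers(self, protocol):
        traj = simulate(default_spec(s=0.0), protocol)
        final = traj.final_state
        assert final[WILD_TYPE] < 1e-3 * K  # wild type eliminated
        assert final.sum() == pytest.approx(K, rel=1e-3)  # no cost: total back at K

    def test_lethal_dominant_drive_is_lost(self, fast_protocol):
        traj = simulate(default_spec(s=1.0, h=1.0), fast_protocol)
        final = traj.final_state
        assert final.sum() - final[WILD_TYPE] < 1e-6 * K  # drive carriers gone
        assert final[WILD_TYPE] == pytest.approx(K, rel=1e-3)  # wild type back

    def test_trajectory_shape_and_release_bookkeeping(self, fast_protocol):
        traj = simulate(default_spec(s=0.1), fast_protocol)
        n_samples = fast_protocol.burn_in + 1 + fast_protocol.horizon + 1
        assert traj.states.shape == (n_samples, 9)
        assert traj.times[traj.release_index] == traj.release_time
        pre = traj.states[traj.release_index]
        post = traj.states[traj.release_index + 1]
        # release adds an AABB cohort equal to the wild-type density
        assert post[0] == pytest.approx(pre[WILD_TYPE])
        assert post[WILD_TYPE] == pre[WILD_TYPE]

    def test_non_negative_with_small_clamp(self, fast_protocol):
        traj = simulate(default_spec("hassell", "deaths", 2.0, s=0.24), fast_protocol)
        assert np.all(traj.states >= 0.0)
        assert traj.max_clamp < 1e-6 * K

    @pytest.mark.parametrize("family, mode, b", all_density_configs())
    def test_wild_type_converges_from_below(self, family, mode, b, rates):
        # from 0.5 K every configuration settles within 0.1% of K, no overshoot
        spec = default_spec(family, mode, b, rates=rates)
        psi = fitness_table(spec.fitness)
        proto = SimulationProtocol(horizon=30)
        times, states, _ = _integrate(
            wt_state(0.5 * K), psi, spec.density, spec.rates, 30, proto, t0=0.0
        )
        totals = states.sum(axis=-1)
        assert np.all(totals <= K * 1.001)
        assert np.all(np.abs(totals[-5:] - K) < 1e-3 * K)

    def test_dt_halving_changes_little(self):
        spec = default_spec("mss", "births", 0.5, s=0.24)
        f1 = simulate(spec, SimulationProtocol(horizon=50, dt=0.1)).final_state
        f2 = simulate(spec, SimulationProtocol(horizon=50, dt=0.05)).final_state
        assert np.abs(f1 - f2).max() < 1e-4 * K

    def test_locus_swap_symmetric_release(self, fast_protocol):
        # equal per-locus parameters: the AaBB and AABb classes stay equal
        traj = simulate(default_spec(s=0.2, h=0.3), fast_protocol)
        i_AABb = GENOTYPE_LABELS.index("AABb")
        i_AaBB = GENOTYPE_LABELS.index("AaBB")
        np.testing.assert_allclose(
            traj.states[:, i_AABb], traj.states[:, i_AaBB], rtol=1e-9, atol=1e-9
        )
        i_Aabb = GENOTYPE_LABELS.index("Aabb")
        i_aaBb = GENOTYPE_LABELS.index("aaBb")
        np.testing.assert_allclose(
            traj.states[:, i_Aabb], traj.states[:, i_aaBb], rtol=1e-9, atol=1e-9
        )

    def test_blow_up_raises_with_step_location(self):
        # an uncalibrated, essentially unregulated model grows without bound
        rates = EcologicalRates(r=5.0, mu=0.1)
        spec = ModelSpec(
            rates=rates,
            density=DensityModel("mss", "births", b=1.0, a=1e-12),
            fitness=FitnessParams(),
        )
        with pytest.raises(RuntimeError, match="blow-up at generation"):
            simulate(spec, SimulationProtocol(burn_in=5, horizon=5))

    def test_batched_matches_individual_runs(self, fast_protocol):
        spec = default_spec("hassell", "births", 0.5)
        psi = np.stack(
            [fitness_table(FitnessParams.symmetric(s, 0.5)) for s in (0.1, 0.24)]
        )
        batch = simulate(spec, fast_protocol, psi=psi)
        for j, s in enumerate((0.1, 0.24)):
            solo = simulate(default_spec("hassell", "births", 0.5, s=s), fast_protocol)
            np.testing.assert_allclose(batch.states[:, j], solo.states, rtol=1e-12)


class TestTrajectoryFrame:
    def test_columns_and_partition_identity(self, fast_protocol):
        traj = simulate(default_spec(s=0.1), fast_protocol)
        df = trajectory_frame(traj)
        assert list(df.columns[:2]) == ["time_days", "generation"]
        assert [c for c in df.columns if c.startswith("N_")][:9] == [
            f"N_{g}" for g in GENOTYPE_LABELS
        ]
        np.testing.assert_allclose(df["N_total"], df["N_drive"] + df["N_wildtype"])

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            SimulationProtocol(dt=5.0)  # coarser than generation_length / 10
        with pytest.raises(ValueError):
            SimulationProtocol(K=-1.0)
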