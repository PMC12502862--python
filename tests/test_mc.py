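"""Monte Carlo moves, Metropolis sampling and closed-form equilibrium checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import drivenchain as dc
from drivenchain.mc import (
    MCSchedule,
    blocked_standard_error,
    crankshaft_move,
    has_overlap,
    metropolis_step,
    pivot_move,
    run_simulation,
)
from drivenchain.polymer import ChainConfiguration, EnergyParameters


def random_walk(n, seed):
    return dc.make_fixture("ideal_random_walk", {"n_bonds": n}, seed=seed)


class TestMoves:
    def test_crankshaft_of_collinear_chain_is_identity(self, rng):
        rod = ChainConfiguration.straight_rod(10)
        prop = crankshaft_move(rod, rng, np.pi)
        # rotation axis is collinear with the chain: nothing can move
        assert np.allclose(prop.joints, rod.joints, atol=1e-12)

    @pytest.mark.parametrize("mover", [crankshaft_move, pivot_move])
    def test_moves_preserve_bond_lengths(self, mover, rng):
        config = random_walk(30, 4)
        ref = config.bond_lengths()
        for _ in range(50):
            config = mover(config, rng, np.pi / 2)
        # oracle: recompute every bond length after many rigid rotations
        assert np.allclose(config.bond_lengths(), ref, rtol=1e-9)

    @pytest.mark.parametrize("mover", [crankshaft_move, pivot_move])
    def test_anchored_joint_never_moves(self, mover, rng):
        config = random_walk(12, 8)
        for _ in range(30):
            config = mover(config, rng, np.pi / 2)
            assert np.array_equal(config.joints[0], [0, 0, 0])

    def test_pivot_at_last_joint_moves_only_tail(self, rng):
        config = random_walk(8, 1)
        moved_last_only = False
        for _ in range(200):
            prop = pivot_move(config, rng, np.pi / 2)
            changed = np.any(prop.joints != config.joints, axis=1)
            if changed.sum() == 1 and changed[-1]:
                d = np.linalg.norm(prop.joints[-1] - prop.joints[-2])
                assert d == pytest.approx(1.0, rel=1e-9)
                moved_last_only = True
        assert moved_last_only  # pivot index N-1 occurs within 200 draws

    def test_crankshaft_needs_three_bonds(self, rng):
        with pytest.raises(ValueError):
            crankshaft_move(ChainConfiguration.straight_rod(2), rng, 1.0)


class TestOverlap:
    def test_straight_chain_has_none(self):
        assert not has_overlap(ChainConfiguration.straight_rod(50))

    def test_folded_chain_detected(self):
        joints = np.array([[0, 0, 0], [1, 0, 0], [0.2, 0.6, 0]], float)
        assert has_overlap(ChainConfiguration(joints))

    def test_touching_spheres_do_not_trigger(self):
        # equilateral triangle: joints 0 and 2 at distance exactly 1
        joints = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        assert not has_overlap(ChainConfiguration(joints))

    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_pair_loop(self, seed):
        config = random_walk(20, seed)
        joints = config.joints
        verdict = False
        for i in range(len(joints)):
            for j in range(i + 2, len(joints)):
                if np.linalg.norm(joints[i] - joints[j]) < 1.0 - 1e-12:
                    verdict = True
        assert has_overlap(config) == verdict


class TestMetropolis:
    def test_zero_energy_always_accepts(self, rng):
        config = random_walk(10, 2)
        schedule = MCSchedule(1, 1, 1, seed=0)
        params = EnergyParameters(0, 0, 0)
        accepted = [
            metropolis_step(config, params, rng, schedule, self_avoiding=False)[1]
            for _ in range(50)
        ]
        assert all(accepted)

    def test_rejection_returns_input(self, rng):
        # huge stretching force: downhill moves get accepted, uphill rejected;
        # a rejected step must hand back the identical configuration object state
        rod = ChainConfiguration.straight_rod(10)
        params = EnergyParameters(0, 50.0, 0)
        schedule = MCSchedule(1, 1, 1, seed=0)
        saw_rejection = False
        config = rod
        for _ in range(100):
            new, acc = metropolis_step(config, params, rng, schedule)
            if not acc:
                assert new is config
                saw_rejection = True
            config = new
        assert saw_rejection


class TestRunSimulation:
    def test_seeded_determinism(self):
        params = EnergyParameters(5, 0.1, 0.01)
        sched = MCSchedule(50, 100, 10, seed=42)
        a = run_simulation(params, 20, sched)
        b = run_simulation(params, 20, sched)
        assert np.array_equal(a.samples, b.samples)
        assert a.observables.equals(b.observables)

    def test_retained_samples_satisfy_chain_invariants(self):
        params = EnergyParameters(8, 0.3, 0.02)
        res = run_simulation(params, 25, MCSchedule(200, 200, 20, seed=3))
        assert res.n_samples == 10
        for config in res.configurations():
            config.validate(self_avoiding=True)

    def test_acceptance_rates_in_unit_interval(self):
        res = run_simulation(EnergyParameters(5), 20, MCSchedule(50, 50, 10, seed=1))
        for v in res.acceptance_rates.values():
            assert 0 <= v <= 1
        assert np.all(np.isfinite(res.energy_trace))

    def test_freely_jointed_chain_end_to_end(self):
        # <R^2> = N l_b^2 for the ideal chain (self-avoidance off)
        res = run_simulation(
            EnergyParameters(0, 0, 0),
            50,
            MCSchedule(500, 10_000, 5, seed=4),
            self_avoiding=False,
        )
        r2 = res.observables["r2"].to_numpy()
        se = blocked_standard_error(r2)
        assert abs(r2.mean() - 50.0) <= 3 * se

    def test_bending_only_tangent_correlation_decay(self):
        # <t_i . t_{i+k}> = (coth k - 1/k)^k for the discrete worm-like chain
        kappa = 5.0
        res = run_simulation(
            EnergyParameters(kappa),
            60,
            MCSchedule(1000, 4000, 10, seed=6),
            self_avoiding=False,
        )
        t = np.diff(res.samples, axis=1)
        base = 1 / np.tanh(kappa) - 1 / kappa
        for k in range(1, 6):
            dots = np.einsum("sij,sij->si", t[:, :-k], t[:, k:]).mean(axis=1)
            se = blocked_standard_error(dots)
            assert abs(dots.mean() - base**k) <= max(4 * se, 5e-3)

    def test_uncorrelated_tangents_without_energy(self):
        res = run_simulation(
            EnergyParameters(0),
            40,
            MCSchedule(500, 4000, 10, seed=7),
            self_avoiding=False,
        )
        t = np.diff(res.samples, axis=1)
        dots = np.einsum("sij,sij->si", t[:, :-3], t[:, 3:]).mean(axis=1)
        assert abs(dots.mean()) <= max(4 * blocked_standard_error(dots), 5e-3)

    def test_extension_increases_with_force(self):
        means = []
        for f in (0.1, 0.3, 0.6):
            res = run_simulation(
                EnergyParameters(0, f, 0), 30, MCSchedule(300, 2000, 10, seed=9)
            )
            means.append((res.samples[:, -1, 0] - res.samples[:, 0, 0]).mean())
        assert means[0] > 0
        assert means[0] < means[1] < means[2]

    def test_energy_trace_matches_reference_energy(self):
        # jitted kernel energy must agree with the polymer-module expression
        params = EnergyParameters(6, 0.2, 0.03)
        res = run_simulation(params, 15, MCSchedule(50, 50, 10, seed=11))
        for config, e in zip(res.configurations(), res.energy_trace):
            assert dc.total_energy(config, params) == pytest.approx(e, rel=1e-9, abs=1e-9)
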