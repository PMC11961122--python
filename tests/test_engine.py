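import math

import numpy as np
import pytest

from psmclock import SimConfig, SubdomainId, TerminationReason
from psmclock._kernels import brute_force_pairs, neighbor_pairs
from psmclock.config import apply_overrides
from psmclock.engine import initialize_tissue, neighbors_within, run, step
from psmclock.experiments import mini_fixture
from psmclock.geometry import cylinder_polar, subdomain_density, subdomain_of, torus_polar


class TestInitialization:
    def test_initial_counts_from_floor_formulas(self, relaxed_state):
        # floor(rho0 pi rT^2 Xc) = 883 per cylinder, floor(rho0 pi^2 rT^2 R) = 555
        assert relaxed_state.n_cells == 2 * 883 + 555

    def test_initial_phases_synchronous(self):
        cfg = SimConfig(relax_duration=0.0, seed=0)
        state = initialize_tissue(cfg)
        assert np.all(state.theta == 3 * math.pi / 2)

    def test_relaxation_confines_to_tube(self, relaxed_state, geom):
        rr = np.empty(relaxed_state.n_cells)
        for i, p in enumerate(relaxed_state.pos):
            sub = subdomain_of(p, geom)
            if sub is SubdomainId.TAILBUD:
                rr[i] = torus_polar(p, geom).r
            else:
                rr[i] = cylinder_polar(p, sub, geom).r
        assert np.mean(rr <= geom.rT + 1.0) >= 0.99

    def test_relaxed_density_near_target(self, relaxed_state, geom):
        # relaxation loses a few dozen cells out of the open anterior end
        # (no advection or replenishment yet), so allow ~3.5% below target;
        # the density-maintenance loop restores rho0 once the run starts
        for sub in SubdomainId:
            rho = subdomain_density(relaxed_state.pos, sub, geom)
            assert rho == pytest.approx(0.0015, rel=0.035)

    def test_directions_are_unit(self, relaxed_state):
        assert np.allclose(np.linalg.norm(relaxed_state.n, axis=1), 1.0)


class TestNeighborSearch:
    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 220))
            scale = rng.uniform(10, 120)
            pos = rng.uniform(0, scale, (n, 3))
            radius = rng.uniform(2.0, 20.0)
            got = {tuple(sorted(p)) for p in zip(*neighbor_pairs(pos, radius))}
            want = {tuple(sorted(p)) for p in zip(*brute_force_pairs(pos, radius))}
            assert got == want

    def test_closed_ball_includes_exact_distance(self):
        pos = np.array([[0.0, 0.0, 0.0], [11.0, 0.0, 0.0], [22.0, 0.0, 0.0]])
        pi, pj = neighbor_pairs(pos, 11.0)
        pairs = set(zip(pi.tolist(), pj.tolist()))
        assert pairs == {(0, 1), (1, 2)}  # exactly dc apart: neighbours
        pi, pj = neighbor_pairs(np.array([[0.0, 0, 0], [11.0 + 1e-6, 0, 0]]), 11.0)
        assert len(pi) == 0  # just beyond dc: not neighbours

    def test_adjacency_lists_symmetric_no_self(self, rng):
        pos = rng.uniform(0, 40, (150, 3))
        adj = neighbors_within(pos, 9.0)
        for i, nbrs in enumerate(adj):
            assert i not in nbrs
            for j in nbrs:
                assert i in adj[j]


class TestStep:
    def test_decoupled_single_cell_update(self):
        cfg = apply_overrides(
            mini_fixture("two_cell"),
            {"clock.kappa": 0.0, "motion.vs": 0.5, "motion.va": 0.2, "motion.vp": 0.0},
        )
        state = initialize_tissue(cfg)
        # separate the pair so no interactions remain
        state.pos[1] = [300.0, 25.0, 25.0]
        x0, th0 = state.pos[0].copy(), state.theta[0]
        step(state, cfg)
        from psmclock.motion import advection_speed, motility_magnitude

        vx = -advection_speed(x0[0], cfg.geometry, cfg.motion) + motility_magnitude(
            x0[0], cfg.geometry, cfg.motion
        )  # n = ex, no neighbours, boundary force disabled
        assert np.allclose(state.pos[0], x0 + cfg.dt * np.array([vx, 0.0, 0.0]), atol=1e-9)
        assert state.theta[0] == pytest.approx(th0 + 0.2094 * cfg.dt)

    def test_population_bookkeeping_reconciles(self):
        cfg = mini_fixture("mini_psm", t_max=10.0, seed=5,
                           **{"lifecycle.division_enabled": True})
        state = initialize_tissue(cfg)
        n0 = state.n_cells
        for _ in range(int(10.0 / cfg.dt)):
            step(state, cfg)
        assert state.n_cells == n0 + state.additions + state.divisions - state.culls

    def test_frozen_cells_keep_phase(self):
        cfg = mini_fixture("mini_psm", t_max=0.0, seed=2)
        state = initialize_tissue(cfg)
        for _ in range(500):
            step(state, cfg)
        frozen_ids = state.ids[state.pos[:, 0] < cfg.geometry.xa]
        assert frozen_ids.size > 0
        theta_before = {
            int(i): state.theta[state.ids == i][0] for i in frozen_ids
        }
        for _ in range(300):
            step(state, cfg)
        still = np.isin(state.ids, frozen_ids)
        for i, th in zip(state.ids[still], state.theta[still]):
            assert th == theta_before[int(i)]

    def test_no_nonfinite_state(self):
        traj = run(mini_fixture("mini_psm", t_max=30.0, seed=9), keep_final_state=True)
        st = traj.final_state
        assert np.all(np.isfinite(st.pos)) and np.all(np.isfinite(st.theta))


class TestDeterminism:
    def test_identical_seeds_identical_trajectories(self):
        a = run(mini_fixture("mini_psm", t_max=8.0, seed=42), keep_final_state=True)
        b = run(mini_fixture("mini_psm", t_max=8.0, seed=42), keep_final_state=True)
        assert a.metrics.equals(b.metrics)
        assert np.array_equal(a.final_state.pos, b.final_state.pos)
        assert np.array_equal(a.final_state.theta, b.final_state.theta)

    def test_different_seeds_differ(self):
        a = run(mini_fixture("mini_psm", t_max=5.0, seed=1))
        b = run(mini_fixture("mini_psm", t_max=5.0, seed=2))
        assert not a.metrics.equals(b.metrics)

    def test_disabled_shrinkage_is_inert(self):
        base = mini_fixture("mini_psm", t_max=5.0, seed=3)
        explicit = apply_overrides(base, {"shrinkage.enabled": False})
        a = run(base, keep_final_state=True)
        b = run(explicit, keep_final_state=True)
        assert np.array_equal(a.final_state.pos, b.final_state.pos)


class TestRun:
    def test_step_count_and_sampling(self):
        traj = run(mini_fixture("mini_psm", t_max=12.0, seed=0))
        assert traj.termination is TerminationReason.TIME_LIMIT
        assert traj.metrics["t"].iloc[-1] == pytest.approx(12.0)
        assert (np.diff(traj.metrics["t"]) > 0).all()

    def test_dt_convergence_of_anterior_synchrony(self):
        # halving dt changes end-time anterior r only slightly
        rs = {}
        for dt in (0.02, 0.01):
            vals = [
                run(mini_fixture("mini_psm", t_max=100.0, seed=s, dt=dt))
                .metrics["r_anterior"].iloc[-1]
                for s in (0, 1, 2)
            ]
            rs[dt] = np.median(vals)
        assert abs(rs[0.02] - rs[0.01]) <= 0.05

    def test_compaction_terminates_early(self):
        from psmclock.experiments import preset

        cfg = preset("fig5_compaction", dt=0.05, sample_interval=5.0)
        traj = run(cfg)
        assert traj.termination in (
            TerminationReason.LENGTH_EXHAUSTED,
            TerminationReason.ANTERIOR_GAP,
        )
        assert traj.metrics["t"].iloc[-1] < cfg.t_max
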