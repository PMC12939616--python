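"""Unit and property tests for the ALA/AHALA optimizer core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma as gamma_fn

import lemopt as L
from lemopt.optimizer import _levy_sigma, draw_energy


def make_space(lb, ub):
    return L.SearchSpace(lb=np.asarray(lb, float), ub=np.asarray(ub, float))


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

class TestInitPopulation:
    def test_bound_containment(self, rng):
        space = make_space([0, 0], [1, 1])
        pop = L.init_population(space, 3, rng)
        assert pop.Z.shape == (3, 2)
        assert (pop.Z >= 0).all() and (pop.Z <= 1).all()

    def test_degenerate_bounds_collapse_to_point(self, rng):
        space = make_space([5], [5])
        pop = L.init_population(space, 4, rng)
        assert (pop.Z == 5.0).all()

    def test_same_seed_reproduces_matrix(self):
        space = make_space([-3, 0, 2], [1, 5, 9])
        Z1 = L.init_population(space, 6, np.random.default_rng(11)).Z
        Z2 = L.init_population(space, 6, np.random.default_rng(11)).Z
        np.testing.assert_array_equal(Z1, Z2)

    def test_nonfinite_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_space([0, -np.inf], [1, 1])


# ---------------------------------------------------------------------------
# Energy factor
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "t,tmax,rand,expected",
    [
        (100, 100, 0.37, 0.0),  # (1 - t/Tmax) vanishes at the horizon
        (13, 100, 1.0, 0.0),  # ln(1) = 0
        (0, 100, math.exp(-1.0), 4.0),  # 4 * 1 * ln(e)
    ],
)
def test_energy_factor_closed_form(t, tmax, rand, expected):
    assert L.energy_factor(t, tmax, rand) == pytest.approx(expected)


def test_energy_factor_rejects_zero_rand():
    with pytest.raises(ValueError):
        L.energy_factor(5, 10, 0.0)


def test_energy_draw_nonnegative(rng):
    vals = [draw_energy(t, 50, rng) for t in range(51) for _ in range(5)]
    assert min(vals) >= 0.0
    assert all(draw_energy(50, 50, rng) == 0.0 for _ in range(5))


# ---------------------------------------------------------------------------
# Lévy step
# ---------------------------------------------------------------------------

class TestLevyStep:
    def test_sigma_matches_gamma_oracle(self):
        beta = 1.5
        num = gamma_fn(1 + beta) * math.sin(math.pi * beta / 2)
        den = gamma_fn((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
        assert _levy_sigma() == pytest.approx((num / den) ** (1 / beta), rel=1e-12)
        assert _levy_sigma() == pytest.approx(0.6966, abs=1e-4)

    def test_heavy_tails_vs_normal(self, rng):
        # excess kurtosis of the Lévy components must be clearly positive
        steps = np.concatenate([L.levy_step(1000, rng) for _ in range(100)])
        z = (steps - steps.mean()) / steps.std()
        assert np.mean(z**4) - 3.0 > 0

    def test_shape_and_validation(self, rng):
        assert L.levy_step(7, rng).shape == (7,)
        with pytest.raises(ValueError):
            L.levy_step(0, rng)


# ---------------------------------------------------------------------------
# Behavioural moves
# ---------------------------------------------------------------------------

class TestMoves:
    def test_migration_fixed_point(self):
        z = np.array([1.0, -2.0])
        s = L.MoveSample(F=1.0, BM=np.ones(2), R=np.full(2, 0.3))
        np.testing.assert_allclose(L.migration_update(z, z, z, s), z)

    def test_migration_algebraic_reduction(self):
        # F=+1, BM=1, R=1 collapses to z_best + (z_best - z_i)
        z_i = np.array([1.0, 2.0])
        z_a = np.array([-5.0, 4.0])
        z_best = np.array([0.5, 0.5])
        s = L.MoveSample(F=1.0, BM=np.ones(2), R=np.ones(2))
        np.testing.assert_allclose(
            L.migration_update(z_i, z_a, z_best, s), z_best + (z_best - z_i)
        )

    def test_migration_output_dim(self, rng):
        z = rng.normal(size=5)
        s = L.MoveSample.draw_migration(5, rng)
        assert L.migration_update(z, rng.normal(size=5), rng.normal(size=5), s).shape == (5,)

    def test_dig_zero_difference_returns_self(self, rng):
        z_i = np.array([3.0, 1.0])
        z = np.array([2.0, 2.0])
        np.testing.assert_allclose(L.dig_update(z_i, z, z, F=1.0, t=4, rng=rng), z_i)

    def test_dig_length_range(self, rng):
        # L = rand * (1 + sin(t/2)) stays in [0, 2]
        for t in rng.integers(0, 500, size=200):
            Ls = rng.random() * (1 + math.sin(t / 2))
            assert 0.0 <= Ls <= 2.0

    def test_forage_collapses_at_best(self, rng):
        z = np.array([1.0, 4.0])
        np.testing.assert_allclose(L.forage_update(z, z, F=1.0, rng=rng), z)

    def test_forage_radius_is_euclidean(self, rng):
        # 3-4-5 triangle: spiral magnitude bounded by radius * sqrt(2)
        z_best = np.zeros(2)
        z_i = np.array([3.0, 4.0])
        for _ in range(500):
            out = L.forage_update(z_i, z_best, F=1.0, rng=rng)
            # out = best + F * spiral * rand * z_i, |spiral| <= 5*sqrt(2), rand <= 1
            assert np.linalg.norm(out - z_best) <= 5.0 * math.sqrt(2) * np.linalg.norm(z_i) + 1e-9

    def test_spiral_bounded_by_radius_sqrt2(self, rng):
        # max over theta of sin + cos is sqrt(2) (grid-search oracle)
        theta = np.linspace(0, 1, 100001)
        oracle_max = np.max(np.sin(2 * np.pi * theta) + np.cos(2 * np.pi * theta))
        assert oracle_max == pytest.approx(math.sqrt(2), abs=1e-6)
        t = rng.random(10000)
        draws = np.sin(2 * np.pi * t) + np.cos(2 * np.pi * t)
        assert np.abs(draws).max() <= math.sqrt(2) + 1e-12

    def test_evade_endpoints(self, rng):
        z_i = np.array([1.0, 1.0])
        z_b = np.array([0.0, 3.0])
        z_best = np.array([2.0, 2.0])
        # t = Tmax: escape coefficient is zero, result is exactly z_best
        out = L.evade_update(z_i, z_b, z_best, F=1.0, t=50, Tmax=50, rng=rng)
        np.testing.assert_allclose(out, z_best)
        # z_b = z_best: zero difference
        out = L.evade_update(z_i, z_best, z_best, F=-1.0, t=3, Tmax=50, rng=rng)
        np.testing.assert_allclose(out, z_best)

    def test_escape_coefficient_linear(self):
        G = lambda t, T: 2.0 * (1.0 - t / T)
        assert G(0, 100) == 2.0 and G(100, 100) == 0.0
        ts = np.arange(101)
        np.testing.assert_allclose(np.diff([G(t, 100) for t in ts]), -0.02)


def test_clip_to_bounds():
    space = make_space([0], [1])
    assert L.clip_to_bounds(np.array([-1.0]), space) == np.array([0.0])
    assert L.clip_to_bounds(np.array([0.5]), space) == np.array([0.5])
    assert L.clip_to_bounds(np.array([7.0]), space) == np.array([1.0])


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------

class TestHillClimb:
    def test_constant_objective_decays_step_geometrically(self, rng):
        space = make_space([0, 0], [1, 1])
        x0 = np.array([0.5, 0.5])
        x, fx, alpha = L.hill_climb(
            x0, 1.0, lambda z: 1.0, space, M=10, alpha0=0.01, beta_decay=0.9, rng=rng
        )
        np.testing.assert_array_equal(x, x0)
        assert fx == 1.0
        assert alpha == pytest.approx(0.01 * 0.9**10)
        assert alpha == pytest.approx(0.003487, abs=1e-6)

    def test_global_optimum_is_fixed_point(self, rng):
        space = make_space([-1], [1])
        f = lambda z: float(z[0] ** 2)
        x, fx, _ = L.hill_climb(np.zeros(1), 0.0, f, space, 20, 0.1, 0.9, rng)
        np.testing.assert_array_equal(x, np.zeros(1))
        assert fx == 0.0

    def test_improves_quadratic_from_offset_start(self):
        space = make_space([-1], [1])
        f = lambda z: float((z[0] - 0.3) ** 2)
        rng = np.random.default_rng(123)
        x, fx, _ = L.hill_climb(np.zeros(1), 0.09, f, space, 50, 0.5, 0.9, rng)
        assert fx < 0.09

    def test_never_worsens(self, rng):
        space = make_space([-5, -5], [5, 5])
        f = lambda z: float(np.sum(np.sin(z) + z**2))
        x0 = rng.uniform(-5, 5, 2)
        f0 = f(x0)
        _, fx, _ = L.hill_climb(x0, f0, f, space, 30, 0.2, 0.8, rng)
        assert fx <= f0


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

SPHERE = L.test_function("sphere", 2)


class TestRuns:
    def test_ala_budget_is_exact(self):
        cfg = L.AHALAConfig(N=13, Tmax=17, seed=5)
        _, _, trace = L.run_ala(SPHERE, SPHERE.space, cfg)
        assert trace.eval_count == 13 * 18

    def test_ahala_budget_is_exact(self):
        cfg = L.AHALAConfig(N=13, Tmax=17, k=5, M=4, seed=5)
        _, _, trace = L.run_ahala(SPHERE, SPHERE.space, cfg)
        assert trace.eval_count == 13 * 18 + (17 // 5) * 4

    @pytest.mark.parametrize("runner", [L.run_ala, L.run_ahala])
    def test_best_curve_non_increasing(self, runner):
        cfg = L.AHALAConfig(N=10, Tmax=60, seed=9)
        _, f_best, trace = runner(SPHERE, SPHERE.space, cfg)
        assert (np.diff(trace.best_per_iter) <= 0).all()
        assert trace.best_per_iter[-1] == f_best

    def test_seed_determinism(self):
        cfg = L.AHALAConfig(N=8, Tmax=30, seed=21)
        r1 = L.run_ahala(SPHERE, SPHERE.space, cfg)
        r2 = L.run_ahala(SPHERE, SPHERE.space, cfg)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1] == r2[1]
        np.testing.assert_array_equal(r1[2].best_per_iter, r2[2].best_per_iter)

    def test_limit_equivalence_k_beyond_horizon(self):
        cfg_a = L.AHALAConfig(N=12, Tmax=40, seed=3)
        cfg_h = L.AHALAConfig(N=12, Tmax=40, k=41, seed=3)
        xa, fa, ta = L.run_ala(SPHERE, SPHERE.space, cfg_a)
        xh, fh, th = L.run_ahala(SPHERE, SPHERE.space, cfg_h)
        np.testing.assert_array_equal(xa, xh)
        assert fa == fh
        np.testing.assert_array_equal(ta.best_per_iter, th.best_per_iter)
        assert ta.eval_count == th.eval_count

    def test_degenerate_space_returns_the_point(self):
        space = make_space([2.5, -1.0], [2.5, -1.0])
        f = lambda z: float(np.sum(z**2))
        x, fx, _ = L.run_ala(f, space, L.AHALAConfig(N=4, Tmax=3, seed=1))
        np.testing.assert_array_equal(x, [2.5, -1.0])
        assert fx == pytest.approx(2.5**2 + 1.0)

    def test_nonfinite_objective_treated_as_inf(self):
        calls = {"n": 0}

        def nasty(z):
            calls["n"] += 1
            return np.nan if calls["n"] % 3 == 0 else float(np.sum(z**2))

        space = make_space([-1, -1], [1, 1])
        _, fx, trace = L.run_ala(nasty, space, L.AHALAConfig(N=5, Tmax=10, seed=2))
        assert np.isfinite(fx)
        assert (np.isfinite(trace.best_per_iter)).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        lo=st.floats(-10, 0),
        width=st.floats(0.1, 20),
        dim=st.integers(1, 5),
    )
    def test_bound_containment_property(self, seed, lo, width, dim):
        """Every coordinate the optimizer visits stays inside the box."""
        space = make_space([lo] * dim, [lo + width] * dim)
        seen = []

        def f(z):
            seen.append(z.copy())
            return float(np.sum(z**2))

        L.run_ahala(f, space, L.AHALAConfig(N=5, Tmax=10, k=3, M=2, seed=seed))
        Z = np.array(seen)
        assert (Z >= space.lb - 1e-12).all() and (Z <= space.ub + 1e-12).all()

    def test_greedy_agent_update_flag_changes_dynamics(self):
        cfg1 = L.AHALAConfig(N=10, Tmax=30, seed=4, greedy_agent_update=False)
        cfg2 = L.AHALAConfig(N=10, Tmax=30, seed=4, greedy_agent_update=True)
        _, f1, t1 = L.run_ala(SPHERE, SPHERE.space, cfg1)
        _, f2, t2 = L.run_ala(SPHERE, SPHERE.space, cfg2)
        # both remain valid optimizers; greedy runs never let an agent worsen
        assert np.isfinite(f1) and np.isfinite(f2)
        assert (np.diff(t2.best_per_iter) <= 0).all()


class TestStandaloneHillClimbing:
    def test_constant_objective_keeps_start(self):
        space = make_space([0, 0], [1, 1])
        x, fx, trace = L.run_hill_climbing(lambda z: 7.0, space, 25, seed=0)
        assert fx == 7.0
        assert trace.eval_count == 26

    def test_sphere_improves_from_random_start(self):
        # reconstruct the seeded start point to get the initial fitness
        start_rng = np.random.default_rng(5)
        space = SPHERE.space
        start = space.lb + start_rng.random(2) * (space.ub - space.lb)
        f0 = SPHERE(start)
        _, fx, trace = L.run_hill_climbing(SPHERE, space, 100, alpha0=0.1, seed=5)
        assert fx < f0
        assert fx <= trace.best_per_iter[0]

    def test_trace_non_increasing(self):
        _, _, trace = L.run_hill_climbing(SPHERE, SPHERE.space, 200, seed=8)
        assert (np.diff(trace.best_per_iter) <= 0).all()


def test_config_validation():
    with pytest.raises(ValueError):
        L.AHALAConfig(N=0)
    with pytest.raises(ValueError):
        L.AHALAConfig(k=0)
    with pytest.raises(ValueError):
        L.AHALAConfig(M=0)
    with pytest.raises(ValueError):
        L.AHALAConfig(beta_decay=1.0)
    with pytest.raises(ValueError):
        L.AHALAConfig(alpha0=0.0)
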