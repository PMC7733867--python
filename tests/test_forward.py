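"""Forward M recursion: generating-function epoch solve, event updates, closed forms."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from occpop import (
    EventKind,
    ModelParams,
    ProbVector,
    build_schedule,
    compute_L,
    compute_M,
    density_backward,
    density_forward,
    evolve_M_epoch,
    init_M,
    M_closed_form_no_omega,
    p_of,
    parse_occurrences,
    parse_tree,
    update_L_event,
    update_M_event,
)
from .conftest import random_params, simulate_dataset


class TestInitM:
    def test_point_mass_on_single_individual(self):
        M = init_M(5, t_or=3.0)
        assert list(M.values) == [1, 0, 0, 0, 0, 0]
        assert M.values.sum() == 1.0
        assert M.k == 1
        assert M.t == 3.0


class TestEvolveM:
    def test_zero_duration_is_identity(self, params_full):
        rng = np.random.default_rng(0)
        M = ProbVector(rng.random(11), 0.0, k=2, t=1.0)
        out = evolve_M_epoch(M, 0.0, params_full)
        assert np.array_equal(out.values, M.values)

    def test_trivial_tree_recovers_density(self, params_full):
        """One lineage from origin to present, then rho-weighting, equals p(t_or, 1-rho)."""
        N = 60
        M = evolve_M_epoch(init_M(N, params_full.t_or), params_full.t_or, params_full)
        i = np.arange(N + 1)
        got = params_full.rho * np.sum((1 - params_full.rho) ** i * M.values)
        got = math.log(got) + M.log_scale
        assert got == pytest.approx(math.log(p_of(2.0, 0.5, params_full)), abs=1e-10)

    @pytest.mark.parametrize("dt", [1e-8, 1e-3, 0.3, 0.9, 2.5])
    def test_generating_function_matches_buffered_ode(self, dt):
        """Coefficient extraction vs the master equation with a truncation buffer.

        The generating-function step yields the exact order-0..N Taylor
        coefficients of the continuum flow, so the ODE oracle is given 40
        extra states (initialised to zero) and compared on the first N+1:
        this isolates the epoch solve from top-boundary truncation effects.
        """
        rng = np.random.default_rng(4)
        N, buf = 40, 40
        worst = 0.0
        for _ in range(10):
            prm = random_params(rng)
            k = int(rng.integers(1, 6))
            v = rng.random(N + 1) * rng.uniform(0.3, 0.8) ** np.arange(N + 1)
            v /= v.sum()
            a = evolve_M_epoch(ProbVector(v.copy(), 0.0, k=k, t=5.0), dt, prm, method="gf")
            vbuf = np.concatenate([v, np.zeros(buf)])
            b = evolve_M_epoch(ProbVector(vbuf, 0.0, k=k, t=5.0), dt, prm, method="ode")
            worst = max(
                worst,
                np.max(
                    np.abs(
                        a.values * math.exp(a.log_scale)
                        - b.values[: N + 1] * math.exp(b.log_scale)
                    )
                ),
            )
        assert worst < 1e-7

    def test_ode_path_matches_solve_ivp(self):
        rng = np.random.default_rng(9)
        N = 30
        prm = random_params(rng)
        k = 2
        v = rng.random(N + 1) * 0.5 ** np.arange(N + 1)
        M = ProbVector(v.copy(), 0.0, k=k, t=5.0)
        out = evolve_M_epoch(M, 0.7, prm, method="ode")

        def rhs(s, y):
            i = np.arange(N + 1)
            d = -prm.gamma * (k + i) * y
            d[1:] += prm.lam * (2 * k + i[1:] - 1) * y[:-1]
            d[:-1] += prm.mu * (i[:-1] + 1) * y[1:]
            return d

        ref = solve_ivp(rhs, (0, 0.7), v, rtol=1e-12, atol=1e-16).y[:, -1]
        assert np.max(np.abs(out.values * math.exp(out.log_scale) - ref)) < 1e-9


class TestUpdateM:
    def setup_method(self):
        self.params = ModelParams(lam=1.0, mu=0.5, psi=0.3, omega=0.6, rho=0.5, r=0.2, t_or=2.0)
        rng = np.random.default_rng(6)
        self.M = ProbVector(rng.random(6), 0.0, k=2, t=1.0)

    def test_nonremoved_leaf_zeroes_state_zero(self):
        out = update_M_event(self.M, EventKind.NONREMOVED_LEAF, self.params)
        assert out.values[0] == 0.0
        assert out.k == 1

    def test_present_update_with_full_sampling(self):
        rho1 = ModelParams(lam=1.0, mu=0.5, psi=0.3, omega=0.6, rho=1.0, r=0.2, t_or=2.0)
        i = np.arange(6)
        weights = (1 - rho1.rho) ** i
        assert np.all(weights[1:] == 0.0)  # only i=0 survives

    def test_event_pair_preserves_inner_product(self):
        """A removed occurrence's L and M updates leave sum_i L(i) M(i) unchanged."""
        rng = np.random.default_rng(8)
        L = ProbVector(rng.random(8), 0.0, k=3, t=1.0)
        M = ProbVector(rng.random(8), 0.0, k=3, t=1.0)
        for kind in (
            EventKind.REMOVED_OCCURRENCE,
            EventKind.NONREMOVED_OCCURRENCE,
            EventKind.UNKNOWN_OCCURRENCE,
            EventKind.REMOVED_LEAF,
            EventKind.NONREMOVED_LEAF,
            EventKind.UNKNOWN_LEAF,
            EventKind.SAMPLED_ANCESTOR,
            EventKind.BRANCHING,
        ):
            # L-update maps the below vector to above; M-update maps above to below.
            # Pair <L_above, M_above> = <updated-L(below), M_above>; the identity
            # is <L_below, M_below> = <L_below, updated-M(above)>.
            L_above = update_L_event(L, kind, self.params)
            lhs = float(np.dot(L_above.values, M.values)) * math.exp(L_above.log_scale)
            M_below = update_M_event(M, kind, self.params)
            rhs = float(np.dot(L.values, M_below.values)) * math.exp(M_below.log_scale)
            assert lhs == pytest.approx(rhs, rel=1e-12), kind


class TestComputeM:
    def test_density_forward_trivial(self, params_full):
        rt = parse_tree("(A:1);")
        sch = build_schedule(rt, None, params_full, [])
        expect = math.log(p_of(2.0, 0.5, params_full))
        assert density_forward(sch, params_full, 60) == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 2, 4, 6])
    def test_inner_product_constant_across_grid(self, params_full, seed):
        """sum_i L_t(i) M_t(i) is flat over the grid and equals P(T, O)."""
        grid = np.linspace(0.0, params_full.t_or, 21)
        sim, sch, N = simulate_dataset(params_full, seed, grid=grid)
        Ls, _ = compute_L(sch, params_full, N)
        Ms, _ = compute_M(sch, params_full, N)
        logs = []
        for t in grid:
            ip = float(np.dot(Ls[t].values, Ms[t].values))
            logs.append(math.log(ip) + Ls[t].log_scale + Ms[t].log_scale)
        logs = np.array(logs)
        assert logs.max() - logs.min() < 1e-6
        assert logs.mean() == pytest.approx(density_backward(sch, params_full, N), abs=1e-6)

    def test_closed_form_matches_sweep_where_stable(self, params_no_omega):
        """omega=0 recursion vs the epoch/update pipeline on its stability domain."""
        rt = parse_tree("(((A:0.9,B:0.55[&rm=1]):0.5,C:0.1[&rm=0]):0.4);")
        grid = [0.2, 0.75, 1.6]  # not shortly below the non-removed leaf at 1.3
        sch = build_schedule(rt, None, params_no_omega, grid)
        rec, _ = compute_M(sch, params_no_omega, 50)
        for t in grid:
            cf = M_closed_form_no_omega(sch, params_no_omega, t, 15)
            a = rec[t].values * math.exp(rec[t].log_scale)
            b = cf.values * math.exp(cf.log_scale)
            mask = b > 1e-10 * b.max()
            assert np.max(np.abs(a[:16][mask] - b[mask]) / b[mask]) < 1e-6

    def test_closed_form_head_equals_finite_difference(self, params_no_omega):
        """The i=1 closed-form entry equals the numerically differentiated gen. function."""
        rt = parse_tree("((A:1,B:0.6[&rm=0]):0.8);")
        sch = build_schedule(rt, None, params_no_omega, [0.3])
        cf = M_closed_form_no_omega(sch, params_no_omega, 0.3, 5)
        # Mhat(z) from the sweep-free product form, via its own coefficients:
        rec, _ = compute_M(sch, params_no_omega, 60)
        vals = rec[0.3].values * math.exp(rec[0.3].log_scale)
        z = 1e-4
        mhat = np.polyval(vals[::-1], z)
        deriv = (np.polyval(vals[::-1], z) - np.polyval(vals[::-1], -z)) / (2 * z)
        got = cf.values * math.exp(cf.log_scale)
        assert got[1] == pytest.approx(deriv, rel=1e-6)
        assert got[0] == pytest.approx(mhat - deriv * z, rel=1e-4)
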