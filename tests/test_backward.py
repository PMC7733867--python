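"""Backward L recursion: initialisation, epoch evolution, event updates, densities."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from occpop import (
    EventKind,
    ImpossibleDataError,
    ModelParams,
    ProbVector,
    build_schedule,
    compute_L,
    density_backward,
    density_forward,
    evolve_L_epoch,
    fbd_tree_density,
    init_L,
    L_closed_form_no_omega,
    parse_occurrences,
    parse_tree,
    p_of,
    update_L_event,
)
from .conftest import random_params, simulate_dataset


class TestInitL:
    def test_two_present_tips(self):
        L = init_L(k0=2, rho=0.5, N=4)
        got = L.values * math.exp(L.log_scale)
        assert got[:3] == pytest.approx([0.25, 0.125, 0.0625])

    def test_complete_sampling_leaves_no_hidden_survivors(self):
        L = init_L(k0=3, rho=1.0, N=5)
        assert L.values[0] == 1.0
        assert np.all(L.values[1:] == 0.0)

    def test_no_present_tips(self):
        L = init_L(k0=0, rho=0.2, N=3)
        assert L.values == pytest.approx(0.8 ** np.arange(4))
        assert L.log_scale == 0.0

    def test_rho_zero_with_tips_impossible(self):
        with pytest.raises(ImpossibleDataError):
            init_L(k0=1, rho=0.0, N=3)


class TestEvolveL:
    def test_zero_duration_is_identity(self, params_full):
        L = init_L(2, 0.5, 10)
        out = evolve_L_epoch(L, 0.0, params_full)
        assert np.array_equal(out.values, L.values)

    def test_single_lineage_recovers_p(self, params_full):
        """With one lineage and no events, L_t(0) = p(t, 1-rho)."""
        L = init_L(1, params_full.rho, 50)
        for t in (0.5, 1.5, 3.0):
            out = evolve_L_epoch(L, t, params_full)
            got = out.values[0] * math.exp(out.log_scale)
            assert got == pytest.approx(p_of(t, 1 - params_full.rho, params_full), rel=1e-10)

    def test_matches_adaptive_ode_integration(self):
        """Matrix-exponential epoch step vs solve_ivp on the truncated system."""
        rng = np.random.default_rng(3)
        N = 40
        worst = 0.0
        for _ in range(20):
            prm = random_params(rng)
            k = int(rng.integers(1, 6))
            v = rng.random(N + 1) * rng.uniform(0.3, 0.8) ** np.arange(N + 1)
            v /= v.max()
            dt = rng.uniform(0.05, 1.2)
            L = ProbVector(v.copy(), 0.0, k=k, t=0.0)
            out = evolve_L_epoch(L, dt, prm)

            def rhs(t, y):
                i = np.arange(N + 1)
                d = -prm.gamma * (k + i) * y
                d[:-1] += prm.lam * (2 * k + i[:-1]) * y[1:]
                d[1:] += prm.mu * i[1:] * y[:-1]
                return d

            ref = solve_ivp(rhs, (0, dt), v, rtol=1e-12, atol=1e-16).y[:, -1]
            worst = max(worst, np.max(np.abs(out.values * math.exp(out.log_scale) - ref)))
        assert worst < 1e-9


class TestUpdateL:
    def setup_method(self):
        self.params = ModelParams(lam=1.0, mu=0.5, psi=0.3, omega=0.6, rho=0.5, r=0.2, t_or=2.0)
        rng = np.random.default_rng(5)
        self.L = ProbVector(rng.random(6), 0.0, k=2, t=1.0)

    def scaled(self, vec):
        return vec.values * math.exp(vec.log_scale)

    def test_sampled_ancestor_is_uniform_scaling(self):
        out = update_L_event(self.L, EventKind.SAMPLED_ANCESTOR, self.params)
        assert self.scaled(out) == pytest.approx(0.24 * self.L.values)
        assert out.k == 2

    def test_unknown_leaf_is_sum_of_both_labels(self):
        out = update_L_event(self.L, EventKind.UNKNOWN_LEAF, self.params)
        expect = 0.06 * self.L.values.copy()
        expect[:-1] += 0.24 * self.L.values[1:]
        assert self.scaled(out) == pytest.approx(expect)
        assert out.k == 3

    def test_removed_occurrence_kills_state_zero(self):
        out = update_L_event(self.L, EventKind.REMOVED_OCCURRENCE, self.params)
        assert out.values[0] == 0.0
        got = self.scaled(out)
        i = np.arange(6)
        assert got[1:] == pytest.approx(0.6 * 0.2 * i[1:] * self.L.values[:-1])

    def test_nonremoved_leaf_shifts_and_zeroes_top(self):
        out = update_L_event(self.L, EventKind.NONREMOVED_LEAF, self.params)
        assert out.values[-1] == 0.0
        assert self.scaled(out)[:-1] == pytest.approx(0.24 * self.L.values[1:])
        assert out.k == 3

    def test_branching_merges_lineages(self):
        out = update_L_event(self.L, EventKind.BRANCHING, self.params)
        assert out.k == 1
        assert self.scaled(out) == pytest.approx(self.params.lam * self.L.values)

    def test_psi_zero_tree_event_gives_zero_density_flag(self):
        prm = ModelParams(lam=1.0, mu=0.5, psi=0.0, omega=0.6, rho=0.5, r=0.2, t_or=2.0)
        out = update_L_event(self.L, EventKind.REMOVED_LEAF, prm)
        assert out.is_zero


class TestDensities:
    def test_trivial_tree_density(self, params_full):
        rt = parse_tree("(A:1);")
        sch = build_schedule(rt, None, params_full, [])
        expect = math.log(p_of(2.0, 0.5, params_full))
        assert density_backward(sch, params_full, 60) == pytest.approx(expect, abs=1e-10)

    def test_conditioning_on_sampling_reduces_density(self, params_full):
        rt = parse_tree("(A:1);")
        sch = build_schedule(rt, None, params_full, [])
        plain = density_backward(sch, params_full, 40)
        cond = density_backward(sch, params_full, 40, condition_on_sampling=True)
        assert cond > plain  # dividing by P(>=1 sample) < 1

    def test_closed_form_L_matches_sweep(self, params_no_omega):
        """omega=0: L_t(i) = u_t^i W_t at every grid time (above the mass floor)."""
        rt = parse_tree("((A:1,B:0.6[&rm=0]):0.8);")
        grid = [0.3, 0.7, 1.2, 1.7]
        sch = build_schedule(rt, None, params_no_omega, grid)
        rec, _ = compute_L(sch, params_no_omega, 60)
        for t in grid:
            a = rec[t].values * math.exp(rec[t].log_scale)
            cf = L_closed_form_no_omega(sch, params_no_omega, t, 60)
            b = cf.values * math.exp(cf.log_scale)
            mask = b > 1e-12 * b.max()
            assert np.max(np.abs(a[mask] - b[mask]) / b[mask]) < 1e-6

    def test_fbd_closed_form_matches_both_algorithms(self):
        """omega=0 tree density: Algorithm sweeps vs the product formula across lam."""
        for lam in (0.5, 1.0, 1.5, 2.0):
            prm = ModelParams(lam=lam, mu=1.0, psi=0.3, omega=0.0, rho=0.5, r=0.2, t_or=2.0)
            rt = parse_tree("(((A:0.9,B:0.55[&rm=1]):0.5,C:0.1[&rm=0]):0.4);")
            sch = build_schedule(rt, None, prm, [])
            cf = fbd_tree_density(sch, prm)
            assert density_backward(sch, prm, 90) == pytest.approx(cf, rel=1e-8)
            assert density_forward(sch, prm, 90) == pytest.approx(cf, rel=1e-8)

    def test_r_one_removes_nonremoved_factor(self):
        """r=1 makes any tree with sampled ancestors or non-removed leaves impossible."""
        prm = ModelParams(lam=1.0, mu=0.5, psi=0.3, omega=0.0, rho=0.5, r=1.0, t_or=2.0)
        rt = parse_tree("((A:1,B:0.6[&rm=0]):0.8);")
        sch = build_schedule(rt, None, prm, [])
        assert density_backward(sch, prm, 40) == -math.inf
        assert fbd_tree_density(sch, prm) == -math.inf

    @pytest.mark.parametrize("seed", [0, 2, 3])
    def test_cross_algorithm_on_simulated_data(self, params_full, seed):
        sim, sch, N = simulate_dataset(params_full, seed)
        lb = density_backward(sch, params_full, N)
        lf = density_forward(sch, params_full, N)
        assert lf == pytest.approx(lb, rel=1e-6)


class TestMicroEnumerationOracle:
    """P(T, O) on a micro dataset vs exhaustive enumeration of event histories.

    Dataset: a single rho-sampled lineage plus one non-removed occurrence at
    time tau, with small rates and short t_or so that histories with more
    than three events in the full process are negligible (relative weight
    of order (gamma*t_or)^3/3! ~ 2e-4 here).  The oracle enumerates every
    full-process history with at most 3 events by recursing on the first
    event: U(x, n, hw) is the density of a hidden individual's subtree from
    age x producing exactly n events and (if hw) the occurrence at tau and
    nothing observable otherwise; V is the same for the rho-sampled main
    lineage.  Integrals over latent event times use fixed Gauss-Legendre
    quadrature.  This is fully independent of the L/M recursions.
    """

    def test_density_matches_enumeration(self):
        prm = ModelParams(lam=0.1, mu=0.05, psi=0.03, omega=0.1, rho=0.7, r=0.3, t_or=0.4)
        tau = 0.15
        g = prm.gamma
        rho = prm.rho
        womega = prm.omega * (1 - prm.r)

        def gauss(f, a, b, n=32):
            if b <= a:
                return 0.0
            x, w = np.polynomial.legendre.leggauss(n)
            xm = 0.5 * (b - a) * x + 0.5 * (a + b)
            return 0.5 * (b - a) * float(np.dot(w, [f(v) for v in xm]))

        def U(x, n, hw):
            """Hidden subtree from age x: n events total, occurrence iff hw."""
            if n == 0:
                return 0.0 if hw else math.exp(-g * x) * (1 - rho)
            out = 0.0
            if hw and x > tau:
                out += math.exp(-g * (x - tau)) * womega * U(tau, n - 1, False)
            lo = tau if hw else 0.0

            def birth(y):
                s = 0.0
                for n1 in range(n):
                    n2 = n - 1 - n1
                    if hw:
                        s += U(y, n1, True) * U(y, n2, False)
                        s += U(y, n1, False) * U(y, n2, True)
                    else:
                        s += U(y, n1, False) * U(y, n2, False)
                return math.exp(-g * (x - y)) * prm.lam * s

            out += gauss(birth, lo, x)
            if not hw and n == 1:  # death as the only event
                out += gauss(lambda y: math.exp(-g * (x - y)) * prm.mu, 0.0, x)
            return out

        def V(x, n, hw):
            """Main (rho-sampled) lineage from age x: n events below, occurrence iff hw."""
            if n == 0:
                return 0.0 if hw else math.exp(-g * x)
            out = 0.0
            if hw and x > tau:
                out += math.exp(-g * (x - tau)) * womega * V(tau, n - 1, False)
            lo = tau if hw else 0.0

            def birth(y):
                # the surviving-to-sampling role can continue through either
                # the mother or the child: both assignments are distinct histories
                s = 0.0
                for n1 in range(n):
                    n2 = n - 1 - n1
                    if hw:
                        for h1 in (True, False):
                            h2 = not h1
                            s += U(y, n1, h1) * V(y, n2, h2)
                            s += V(y, n1, h1) * U(y, n2, h2)
                    else:
                        s += U(y, n1, False) * V(y, n2, False)
                        s += V(y, n1, False) * U(y, n2, False)
                return math.exp(-g * (x - y)) * prm.lam * s

            out += gauss(birth, lo, x)
            return out

        oracle = rho * sum(V(prm.t_or, n, True) for n in (1, 2, 3))

        rt = parse_tree("(A:0.3);")
        occ = parse_occurrences(f"time\tremoved\n{tau}\t0\n")
        sch = build_schedule(rt, occ, prm, [])
        got = math.exp(density_backward(sch, prm, 60))
        assert got == pytest.approx(oracle, rel=1e-3)
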