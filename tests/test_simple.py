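"""Simple-model RHS, fixed points, thresholds, boundary and stability."""

import numpy as np
import pytest

from crisprdyn import params as pp
from crisprdyn import simple as sm


def make_params(**kw):
    base = dict(A_P=2.0, G_Pphi=2.0, G_Qphi=1.0, G_Qp=1.0, G_Qv=1.0,
                G_V=10.0, alpha_v=50.0, delta=0.0)
    base.update(kw)
    return pp.SimpleParams(**base)


class TestRhs:
    def test_extinction_is_fixed_point(self, benchmark_simple):
        assert np.all(sm.simple_rhs(np.zeros(3), benchmark_simple) == 0)

    def test_phage_free_annihilates_field(self):
        p = make_params(delta=0.5)
        P_f = 1.0 - p.delta * p.G_Pphi / p.A_P
        r = sm.simple_rhs(np.array([P_f, 0.0, 0.0]), p)
        assert np.allclose(r, 0.0, atol=1e-14)

    def test_pure_logistic_term(self):
        p = make_params(delta=0.0)
        r = sm.simple_rhs(np.array([0.5, 0.0, 0.0]), p)
        assert r[0] == pytest.approx(0.5)  # A_P*P*(1-P) = 2*0.5*0.5
        assert r[1] == r[2] == 0.0

    def test_jacobian_matches_finite_differences(self, rng):
        p = make_params(delta=0.4)
        s = rng.uniform(0.01, 1.0, size=3)
        J = sm.simple_jacobian(s, p)
        eps = 1e-7
        for j in range(3):
            sp = s.copy()
            sp[j] += eps
            fd = (sm.simple_rhs(sp, p) - sm.simple_rhs(s, p)) / eps
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-5)


class TestFixedPoints:
    def test_phage_free_at_carrying_capacity(self):
        recs = {r.kind: r for r in sm.fixed_points(make_params(delta=0.0))}
        assert recs["F"].state[0] == pytest.approx(1.0)

    def test_phage_free_formula(self):
        recs = {r.kind: r for r in sm.fixed_points(make_params(delta=0.5))}
        assert recs["F"].state[0] == pytest.approx(0.5)  # 1 - 0.5*2/2

    def test_closed_form_without_immune_advantage(self):
        # no infected-cell immunity/autoimmunity: P_c = G_V/alpha_v
        p = make_params(G_Qphi=0.0, G_Qp=0.0, G_V=10.0, alpha_v=50.0)
        C = {r.kind: r for r in sm.fixed_points(p)}["C"]
        assert C.closed_form[0] == pytest.approx(0.2)

    def test_closed_form_vs_exact_in_validity_regime(self):
        # the closed form drops the adsorption sink; with
        # alpha_v*G_Qv/G_Q >> 1 it must agree with the refined exact root
        p = make_params(G_Qphi=0.3, G_Qp=0.2, G_Qv=1.0, alpha_v=2000.0)
        assert p.alpha_v * p.G_Qv / p.G_Q > 100
        C = {r.kind: r for r in sm.fixed_points(p)}["C"]
        assert C.discrepancy < 1e-2
        assert np.max(np.abs(sm.simple_rhs(C.state, p))) < 1e-10

    def test_no_lysis_reports_absent_coexistence(self):
        C = {r.kind: r for r in sm.fixed_points(make_params(G_Qv=0.0))}["C"]
        assert C.state is None
        assert "absent_reason" in C.diagnostics


class TestThresholds:
    def test_delta1_unity_when_autoimmunity_matches_growth(self):
        d1, _ = sm.delta_thresholds(make_params(G_Pphi=2.0, A_P=2.0))
        assert d1 == pytest.approx(1.0)

    def test_delta1_ratio(self):
        d1, _ = sm.delta_thresholds(make_params(A_P=2.0, G_Pphi=4.0))
        assert d1 == pytest.approx(0.5)

    def test_unbounded_without_free_cell_autoimmunity(self):
        d1, d2 = sm.delta_thresholds(make_params(G_Pphi=0.0))
        assert np.isinf(d1) and np.isinf(d2)

    def test_delta2_vanishes_as_Pc_approaches_one(self):
        # closed-form P_c = (G_V/alpha_v)*(1+adv); tune it to approach 1
        p = make_params(G_Qphi=0.0, G_Qp=0.0, G_V=49.99, alpha_v=50.0)
        _, d2 = sm.delta_thresholds(p)
        assert 0 < d2 < 2e-4

    def test_ordering_delta2_below_delta1(self, rng):
        # whenever 0 < P_c < 1 the coexistence bound is the tighter one
        found = 0
        for _ in range(200):
            p = make_params(
                A_P=rng.uniform(0.5, 5), G_Pphi=rng.uniform(0.1, 5),
                G_Qphi=rng.uniform(0, 2), G_Qp=rng.uniform(0, 2),
                G_Qv=rng.uniform(0.2, 3), G_V=rng.uniform(0.5, 20),
                alpha_v=rng.uniform(10, 500))
            d1, d2 = sm.delta_thresholds(p)
            if d2 is not None:
                assert d2 < d1
                found += 1
        assert found > 50

    def test_closed_form_phage_density_vanishes_at_delta2(self):
        p = make_params(G_Qphi=0.5, G_Qp=0.2, alpha_v=200.0, G_V=10.0)
        _, d2 = sm.delta_thresholds(p)
        pc = pp.with_overrides(p, delta=d2)
        C = {r.kind: r for r in sm.fixed_points(pc)}["C"]
        F = {r.kind: r for r in sm.fixed_points(pc)}["F"]
        assert C.closed_form[2] == pytest.approx(0.0, abs=1e-12)
        # and the coexistence state coincides with the phage-free state
        assert np.allclose(C.closed_form, F.state, atol=1e-9)

    def test_phage_density_decreasing_in_delta(self):
        p = make_params(G_Qphi=0.5, G_Qp=0.2, alpha_v=200.0, G_V=10.0)
        _, d2 = sm.delta_thresholds(p)
        deltas = np.linspace(0.0, 0.95 * d2, 8)
        vcs = []
        for d in deltas:
            C = {r.kind: r for r in
                 sm.fixed_points(pp.with_overrides(p, delta=d))}["C"]
            vcs.append(C.closed_form[2])
        assert np.all(np.diff(vcs) < 0)


class TestCoexistenceBoundary:
    def test_intercepts_hand_values(self):
        p = make_params(A_P=2.0, G_Pphi=2.0, G_V=10.0, alpha_v=50.0,
                        G_Qp=0.0, G_Qv=2.0)
        b = sm.coexistence_boundary(p)
        assert b.K1 == pytest.approx(0.8)
        assert b.K2 == pytest.approx(8.0)

    def test_immunity_shrinks_the_wedge(self):
        ks = []
        for gqp in (0.0, 0.5, 1.5):
            b = sm.coexistence_boundary(make_params(G_Qp=gqp, G_Qv=2.0))
            ks.append((b.K1, b.K2))
        assert all(a1 > b1 and a2 > b2
                   for (a1, a2), (b1, b2) in zip(ks, ks[1:]))

    def test_degenerate_boundary_raises(self):
        with pytest.raises(sm.NoCoexistenceWedgeError):
            sm.coexistence_boundary(make_params(alpha_v=10.0, G_V=10.0,
                                                G_Qp=0.0))


class TestStability:
    def test_extinction_eigenvalues_analytic(self):
        # J at the origin is triangular-ish: eigenvalues are
        # A_P - delta*G_Pphi, -G_Q, -G_V
        for delta, expect in [(0.2, "unstable"), (1.4, "stable")]:
            p = make_params(delta=delta)  # delta1 = 1
            E = sm.FixedPointRecord("E", np.zeros(3), feasible=True)
            sm.assess_stability(E, p)
            assert E.stability == expect
            eigs = np.sort(E.diagnostics["eigenvalues"].real)
            expected = np.sort([p.A_P - delta * p.G_Pphi, -p.G_Q, -p.G_V])
            assert np.allclose(eigs, expected)

    def test_diagonal_jacobian_stable(self):
        verdict, _ = sm.routh_hurwitz(np.diag([-1.0, -2.0, -3.0]))
        assert verdict == "stable"

    def test_routh_hurwitz_agrees_with_eigenvalues(self, rng):
        # independent oracle: sign of the largest real part
        checked = 0
        for _ in range(150):
            J = rng.normal(size=(3, 3)) * rng.choice([0.5, 2.0, 10.0])
            verdict, _ = sm.routh_hurwitz(J)
            max_re = np.max(np.linalg.eigvals(J).real)
            if verdict == "marginal" or abs(max_re) < 1e-9:
                continue
            assert verdict == ("stable" if max_re < 0 else "unstable")
            checked += 1
        assert checked >= 100

    def test_not_a_fixed_point_raises(self, benchmark_simple):
        bogus = sm.FixedPointRecord("F", np.array([0.37, 0.1, 0.2]))
        with pytest.raises(ValueError, match="not a fixed point"):
            sm.assess_stability(bogus, benchmark_simple)

    def test_coexistence_stable_in_wedge(self, benchmark_simple):
        recs = {r.kind: r for r in sm.fixed_points(benchmark_simple)}
        assert recs["C"].feasible and recs["C"].stability == "stable"
        assert recs["E"].stability == "unstable"
        assert recs["F"].stability == "unstable"
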