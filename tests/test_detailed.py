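"""Detailed-model RHS, phage-free analysis, variants, and the reduction
to the simple model."""

import math

import numpy as np
import pytest

from crisprdyn import detailed as det
from crisprdyn import params as pp
from crisprdyn import simple as sm
from crisprdyn.dynamics import SolverOptions, find_steady_state, integrate


def make_params(**kw):
    base = dict(A_P=1e6, A_V=2.5e7, G_Qp=1e9, G_Qphi=1e9, G_Qv=1e6,
                G_V=5e6, G_C=1.0, M_V=0.3, beta=1.0, delta=0.01,
                mu_v=3e-7, alpha_v=50.0)
    base.update(kw)
    return pp.DetailedParams(**base)


class TestRhs:
    def test_phage_free_fixed_point_annihilates_field(self):
        p = make_params(beta=1.0, G_C=2.0, delta=0.01)
        fp = det.phage_free_fixed_point(p)
        r = det.detailed_rhs(fp.state, p)
        assert np.allclose(r, 0.0, atol=1e-9)

    def test_no_self_targeting_source(self):
        # beta = 0 and delta = 0: nothing creates self-targeting spacers
        p = make_params(beta=0.0, delta=0.0)
        s = det.make_state(P=0.5, Q=0.1, V=0.2, X_A=0.5, Y_QA=0.3,
                           Y_PA=0.2)
        r = det.detailed_rhs(s, p)
        names = det.STATE_NAMES
        assert r[names.index("Y_QS")] == 0.0
        assert r[names.index("Y_PS")] == 0.0

    def test_protospacer_quota_inflow(self):
        # fresh infections carry the mutation-reduced protospacer load
        p = make_params()
        s = det.make_state(P=0.1, Q=0.1, V=0.1)
        r = det.detailed_rhs(s, p)
        assert r[3] == pytest.approx(p.A_V * 0.1 * (1.0 - p.mu_v))

    def test_nan_input_signals(self):
        s = det.make_state(P=np.nan)
        with pytest.raises(ValueError, match="NaN"):
            det.detailed_rhs(s, make_params())

    def test_jit_and_python_paths_agree(self, rng):
        # the numba-compiled core and its pure-Python source must match
        core = det._rhs_quota_core
        py = getattr(core, "py_func", core)
        p = make_params()
        c = det.pack_params(p)
        for _ in range(5):
            s = rng.uniform(0.0, 1.0, size=10)
            assert np.array_equal(np.asarray(core(s, c)),
                                  np.asarray(py(s, c)))

    def test_gating_of_singular_terms(self):
        # empty infected pool: the per-infected-cell mixing terms vanish
        p = make_params()
        s = det.make_state(P=0.5, V=0.3, Y_PA=0.2)
        r = det.detailed_rhs(s, p)
        assert r[3] == 0.0  # no X_A inflow without infected cells
        assert np.isfinite(r).all()


class TestTotalContentMode:
    def test_conversion_round_trip(self, rng):
        s = rng.uniform(0.01, 1.0, size=10)
        back = det.totals_to_quotas(det.quotas_to_totals(s))
        assert np.allclose(back, s, rtol=1e-12)

    def test_rhs_consistency_via_product_rule(self, rng):
        # d(Y*N)/dt from the totals core must equal Ydot*N + Y*Ndot from
        # the quota core at any interior state
        p = make_params()
        for _ in range(10):
            s = rng.uniform(0.05, 0.8, size=10)
            rq = det.detailed_rhs(s, p)
            rt = det.detailed_rhs_totals(det.quotas_to_totals(s), p)
            P, Q = s[0], s[1]
            dP, dQ = rq[0], rq[1]
            expect = np.empty(10)
            expect[:3] = rq[:3]
            expect[3:7] = rq[3:7] * Q + s[3:7] * dQ
            expect[7:10] = rq[7:10] * P + s[7:10] * dP
            assert np.allclose(rt, expect, rtol=1e-8, atol=1e-8)

    def test_terminal_agreement_on_benchmark(self, reference_detailed):
        # a coexistence run (all pools occupied throughout) must agree
        # between the two integration modes; where a pool empties the
        # modes legitimately differ in its meaningless quota rows
        p = pp.with_overrides(reference_detailed, delta=0.01, G_C=1e6)
        s0 = det.make_state(P=0.1, V=0.01)
        a = integrate("detailed", p, s0, horizon=0.05,
                      opts=SolverOptions(mode="quota")).final_state
        b = integrate("detailed", p, s0, horizon=0.05,
                      opts=SolverOptions(mode="totals")).final_state
        assert np.allclose(a, b, rtol=1e-3, atol=1e-8)


class TestPhageFreeAnalysis:
    def test_no_self_targeting_protospacers(self):
        fp = det.phage_free_fixed_point(make_params(beta=0.0))
        assert fp.state[det.STATE_NAMES.index("Y_PS")] == 0.0
        assert fp.state[0] == pytest.approx(1.0)

    def test_self_targeting_quota_ratio(self):
        fp = det.phage_free_fixed_point(make_params(beta=1.0, G_C=2.0))
        assert fp.state[det.STATE_NAMES.index("Y_PS")] == pytest.approx(0.5)

    def test_infeasible_above_delta_max(self):
        p = make_params(beta=100.0, G_C=1.0, delta=0.5)
        assert p.delta > det.delta_max(p)
        assert not det.phage_free_fixed_point(p).feasible

    def test_unbounded_accumulation_raises(self):
        p = make_params(G_C=0.0, beta=1.0, delta=0.1)
        with pytest.raises(det.NoPhageFreeSteadyStateError):
            det.phage_free_fixed_point(p)

    def test_delta_max_value(self):
        p = make_params(A_P=1e6, G_C=1.0, G_Qphi=1e8, beta=1.0)
        assert det.delta_max(p) == pytest.approx(0.01)

    def test_delta_max_unbounded_sentinels(self):
        assert math.isinf(det.delta_max(make_params(beta=0.0)))
        assert math.isinf(det.delta_max(make_params(G_Qphi=0.0)))

    def test_delta_max_scaling_in_beta(self):
        assert det.delta_max(make_params(beta=2.0)) == pytest.approx(
            0.5 * det.delta_max(make_params(beta=1.0)))


class TestVariants:
    def test_parse(self):
        assert det.VariantSpec.parse("no-abi") is det.VariantSpec.no_abi
        assert det.VariantSpec.parse("del-const") is \
            det.VariantSpec.deletion_constitutive
        with pytest.raises(ValueError, match="unknown variant"):
            det.VariantSpec.parse("frobnicate")

    def test_no_abi_only_changes_infected_loss(self, rng):
        p = make_params()
        s = rng.uniform(0.05, 0.8, size=10)
        base = det.detailed_rhs(s, p)
        noabi = det.detailed_rhs(s, p, det.VariantSpec.no_abi)
        diff = noabi - base
        yqs = s[det.STATE_NAMES.index("Y_QS")]
        assert diff[1] == pytest.approx(p.G_Qphi * yqs * s[1], rel=1e-12)
        mask = np.ones(10, bool)
        mask[1] = False
        assert np.allclose(diff[mask], 0.0, atol=1e-16 * p.G_Qphi)

    def test_constitutive_deletion_reduces_self_targeting_quota(self):
        # free-cell deletion at full rate: Y_PS* = delta*beta/G_C <= beta/G_C
        p = make_params(beta=1.0, G_C=2.0, delta=0.25)
        fp = det.phage_free_fixed_point(
            p, det.VariantSpec.deletion_constitutive)
        i = det.STATE_NAMES.index("Y_PS")
        assert fp.state[i] == pytest.approx(0.125)
        base = det.phage_free_fixed_point(p)
        assert fp.state[i] <= base.state[i]
        # and the stated quota annihilates the variant's field
        assert np.allclose(det.detailed_rhs(
            fp.state, p, det.VariantSpec.deletion_constitutive), 0,
            atol=1e-9)

    def test_inverse_deletion_freezes_infected_deletion(self, rng):
        p = make_params()
        s = rng.uniform(0.05, 0.8, size=10)
        base = det.detailed_rhs(s, p)
        inv = det.detailed_rhs(s, p, det.VariantSpec.deletion_inverse)
        # infected quota rows gain back their G_C loss terms
        for k in ("Y_QA", "Y_QI", "Y_QS"):
            i = det.STATE_NAMES.index(k)
            assert inv[i] - base[i] == pytest.approx(p.G_C * s[i], rel=1e-9)


class TestReduction:
    def test_zero_quotas_remove_immunity(self, reference_detailed):
        sp, _ = det.reduce_to_simple(reference_detailed, (0.0, 0.0, 0.0))
        assert sp.G_Qp == sp.G_Qphi == sp.G_Pphi == 0.0
        # immune-advantage factor of the closed form collapses to 1
        C = {r.kind: r for r in sm.fixed_points(sp)}["C"]
        assert C.closed_form[0] == pytest.approx(sp.G_V / sp.alpha_v)

    def test_pure_abortive_infection_limit(self, reference_detailed):
        sp, _ = det.reduce_to_simple(reference_detailed, (0.0, 0.5, 0.1))
        assert sp.G_Qp == 0.0 and sp.G_Qphi > 0.0

    def test_population_block_matches_simple_rhs(self, rng,
                                                 reference_detailed):
        # frozen quotas: the mapped simple model must reproduce the
        # population block exactly after the state/time/phage-unit maps
        p = pp.with_overrides(reference_detailed, delta=0.005)
        quotas = (0.3, 0.2, 0.1)
        sp, conv = det.reduce_to_simple(p, quotas)
        c = conv.time_scale
        for _ in range(10):
            P, Q, Vd = rng.uniform(0.01, 0.9, size=3)
            s10 = det.make_state(P=P, Q=Q, V=Vd, Y_QA=quotas[0],
                                 Y_QS=quotas[1], Y_PS=quotas[2])
            r10 = det.detailed_rhs(s10, p)
            r3 = sm.simple_rhs(conv.to_simple_state(s10), sp)
            assert r3[0] == pytest.approx(c * r10[0], rel=1e-10)
            assert r3[1] == pytest.approx(c * r10[1], rel=1e-10)
            assert r3[2] == pytest.approx(
                conv.phage_scale * c * r10[2], rel=1e-10)

    def test_negative_quotas_rejected(self, reference_detailed):
        with pytest.raises(ValueError, match="nonnegative"):
            det.reduce_to_simple(reference_detailed, (-0.1, 0.0, 0.0))


class TestLongRunBehavior:
    def test_phage_free_quota_relaxation(self, rng):
        # active/inactive spacers are progressively lost; self-targeting
        # spacers settle at the acquisition/deletion balance beta/G_C
        for _ in range(5):
            p = make_params(
                beta=10 ** rng.uniform(-2, 2),
                G_C=10 ** rng.uniform(-1, 3),
                delta=10 ** rng.uniform(-2, 0),
                G_Qphi=1e7)  # mild autoimmunity so hosts survive
            if p.delta >= 0.95 * det.delta_max(p):
                continue
            s0 = det.make_state(P=0.1, Y_PA=0.1, Y_PI=0.1, Y_PS=0.1)
            ss = find_steady_state("detailed", p, s0)
            assert ss.converged
            names = det.STATE_NAMES
            assert ss.state[names.index("Y_PS")] == pytest.approx(
                p.beta / p.G_C, rel=1e-2)
            assert ss.state[names.index("Y_PA")] < 1e-6
            assert ss.state[names.index("Y_PI")] < 1e-6

    def test_active_protospacer_quota_bounded(self, reference_detailed):
        # X_A relaxes toward 1 - mu_v and never exceeds it
        p = pp.with_overrides(reference_detailed, delta=0.0, G_C=100.0)
        s0 = det.make_state(P=0.1, V=0.01)
        traj = integrate("detailed", p, s0, horizon=5.0)
        x = traj.column("X_A")
        assert np.max(x) <= 1.0 - p.mu_v + 1e-6
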