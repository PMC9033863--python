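"""Tests for the one-shot federated protocol and surrogate likelihood."""

import numpy as np
import pytest

import fedcox as fc
from fedcox.cox_core import NoEventsError
from fedcox.protocol import StaleDerivativesError, choose_lead_site

from .conftest import random_site


def _msg(site_id, n, beta_hat, vcov):
    return fc.SiteInitMessage(site_id, n, np.atleast_1d(beta_hat),
                              np.atleast_2d(vcov), True)


class TestMetaCombine:
    def test_equal_weights_give_mean(self):
        bb, v = fc.meta_combine([_msg("a", 10, 1.0, 1.0),
                                 _msg("b", 10, 3.0, 1.0)])
        assert bb == pytest.approx([2.0])
        np.testing.assert_allclose(v, [[0.5]])

    def test_inverse_variance_weighting(self):
        bb, _ = fc.meta_combine([_msg("a", 10, 1.0, 0.5),
                                 _msg("b", 10, 3.0, 1.0)])
        assert bb == pytest.approx([5 / 3])

    def test_single_message_identity(self):
        bb, v = fc.meta_combine([_msg("a", 10, 1.7, 0.3)])
        assert bb == pytest.approx([1.7])
        np.testing.assert_allclose(v, [[0.3]])

    def test_failed_fits_excluded_with_warning(self):
        msgs = [_msg("a", 10, 1.0, 1.0),
                fc.SiteInitMessage("b", 10, None, None, False)]
        with pytest.warns(UserWarning, match="excluded"):
            bb, _ = fc.meta_combine(msgs)
        assert bb == pytest.approx([1.0])

    def test_no_usable_messages_errors(self):
        with pytest.raises(ValueError, match="no usable"):
            fc.meta_combine([fc.SiteInitMessage("a", 5, None, None, False)])


class TestAggregateDerivatives:
    def test_identical_messages_equal_local(self, d0):
        bb = np.array([0.2])
        msgs = [fc.make_deriv_message(d0, bb) for _ in range(4)]
        g, H = fc.aggregate_derivatives(msgs)
        np.testing.assert_allclose(g, msgs[0].grad)
        np.testing.assert_allclose(H, msgs[0].hess)

    def test_size_weighted_mean(self):
        bb = np.zeros(1)
        m1 = fc.SiteDerivMessage("a", 100, [0.4], [[-1.0]], bb)
        m2 = fc.SiteDerivMessage("b", 300, [0.0], [[-2.0]], bb)
        g, H = fc.aggregate_derivatives([m1, m2])
        assert g == pytest.approx([0.1])
        np.testing.assert_allclose(H, [[-1.75]])

    def test_equals_pooled_stratified_derivatives(self, rng):
        """The distributive identity: the n_j-weighted average of site
        derivatives is exactly the pooled stratified score/Hessian."""
        sites = [random_site(rng, n=8, p=2, site_id=f"s{j}")
                 for j in range(3)]
        bb = rng.normal(scale=0.3, size=2)
        msgs = [fc.make_deriv_message(s, bb) for s in sites]
        g, H = fc.aggregate_derivatives(msgs)
        N = sum(s.n for s in sites)
        g_pool = sum(s.n * fc.score(s, bb) for s in sites) / N
        H_pool = sum(s.n * fc.hessian(s, bb) for s in sites) / N
        np.testing.assert_allclose(g, g_pool, atol=1e-12)
        np.testing.assert_allclose(H, H_pool, atol=1e-12)

    def test_mixed_anchor_rounds_refused(self, d0):
        m1 = fc.make_deriv_message(d0, np.array([0.1]))
        m2 = fc.make_deriv_message(d0, np.array([0.2]))
        with pytest.raises(StaleDerivativesError):
            fc.aggregate_derivatives([m1, m2])


class TestSurrogate:
    def test_single_site_surrogate_is_local_likelihood(self, d0):
        bb = np.array([0.3])
        g, H = fc.score(d0, bb), fc.hessian(d0, bb)
        prob = fc.build_surrogate(d0, bb, g, H)
        for b in np.linspace(-1.5, 1.5, 7):
            assert prob.loglik([b]) == pytest.approx(
                fc.log_partial_likelihood(d0, [b]), abs=1e-12)

    def test_anchor_identities(self, rng):
        """At the anchor, the surrogate gradient/Hessian equal the global
        ones exactly (the lead-site terms cancel algebraically)."""
        sites = [random_site(rng, n=10, p=2, site_id=f"s{j}")
                 for j in range(3)]
        bb = rng.normal(scale=0.3, size=2)
        msgs = [fc.make_deriv_message(s, bb) for s in sites]
        g, H = fc.aggregate_derivatives(msgs)
        prob = fc.build_surrogate(sites[0], bb, g, H)
        np.testing.assert_allclose(prob.grad(bb), g, atol=1e-14)
        np.testing.assert_allclose(prob.hess(bb), H, atol=1e-14)

    def test_lead_without_events_refused(self, all_censored_site):
        with pytest.raises(NoEventsError):
            fc.build_surrogate(all_censored_site, np.zeros(1),
                               np.zeros(1), np.zeros((1, 1)))

    def test_single_site_estimate_is_local_mle(self, d0):
        local = fc.fit_local_cox(d0)
        est, bb, _ = fc.run_odach([d0])
        np.testing.assert_allclose(est.beta_tilde, local.beta_hat,
                                   atol=1e-6)

    def test_identical_copy_sites_recover_pooled(self, rng):
        base = random_site(rng, n=30, p=2, site_id="s0")
        sites = [fc.SiteData(f"s{j}", base.times, base.events, base.X)
                 for j in range(4)]
        pooled = fc.fit_pooled_stratified(sites)
        est, _, _ = fc.run_odach(sites)
        np.testing.assert_allclose(est.beta_tilde, pooled.beta_hat,
                                   atol=1e-6)

    def test_quadratic_harness_closed_form(self):
        """With an exactly quadratic lead likelihood the surrogate is the
        global quadratic, whose maximiser has a closed form."""
        rng = np.random.default_rng(7)
        A1 = -np.eye(2) * 2.0
        b1 = np.array([0.5, -0.2])
        AG = np.array([[-3.0, 0.5], [0.5, -2.0]])
        bG = np.array([0.3, 0.4])
        bb = np.array([0.1, -0.3])

        class QuadLead:
            site_id = "q"
            n = 10
            n_events = 5
            p = 2

        prob = fc.SurrogateProblem.__new__(fc.SurrogateProblem)
        prob.lead_data = QuadLead()
        prob.beta_bar = bb
        # global quadratic: L(b) = bG'b + 1/2 b'AG b
        prob.global_grad = bG + AG @ bb
        prob.global_hess = AG
        prob.lead_grad = b1 + A1 @ bb
        prob.lead_hess = A1
        # surrogate's own L1 terms, made exactly quadratic
        prob.loglik = lambda b: float(
            b1 @ b + 0.5 * np.asarray(b) @ A1 @ np.asarray(b)
            + (prob.global_grad - prob.lead_grad) @ np.asarray(b)
            + 0.5 * (np.asarray(b) - bb) @ (AG - A1) @ (np.asarray(b) - bb))
        prob.grad = lambda b: (
            b1 + A1 @ np.asarray(b)
            + (prob.global_grad - prob.lead_grad)
            + (AG - A1) @ (np.asarray(b) - bb))
        prob.hess = lambda b: AG
        est = fc.fit_surrogate(prob, total_n=10)
        np.testing.assert_allclose(est.beta_tilde,
                                   np.linalg.solve(-AG, bG), atol=1e-10)

    def test_anchor_at_pooled_fixes_point(self, rng):
        """Feeding the pooled estimate as anchor leaves the surrogate
        maximiser at the pooled estimate."""
        sites = [random_site(rng, n=25, p=2, site_id=f"s{j}")
                 for j in range(3)]
        pooled = fc.fit_pooled_stratified(sites)
        bb = pooled.beta_hat
        msgs = [fc.make_deriv_message(s, bb) for s in sites]
        g, H = fc.aggregate_derivatives(msgs)
        prob = fc.build_surrogate(sites[0], bb, g, H)
        est = fc.fit_surrogate(prob, total_n=sum(s.n for s in sites))
        assert np.max(np.abs(est.beta_tilde - bb)) < 1e-8


class TestMultiLeadSynthesis:
    def test_single_estimate_identity(self):
        e = fc.OdachEstimate(np.array([0.4]), np.array([[0.2]]), "a", True)
        out = fc.multi_lead_synthesize([e])
        np.testing.assert_allclose(out.beta_tilde, [0.4])
        np.testing.assert_allclose(out.vcov, [[0.2]])

    def test_equal_vcov_gives_mean(self):
        v = np.eye(2) * 0.5
        e1 = fc.OdachEstimate(np.array([0.0, 1.0]), v, "a", True)
        e2 = fc.OdachEstimate(np.array([1.0, 3.0]), v, "b", True)
        out = fc.multi_lead_synthesize([e1, e2])
        np.testing.assert_allclose(out.beta_tilde, [0.5, 2.0])

    def test_none_converged_errors(self):
        e = fc.OdachEstimate(np.array([0.4]), None, "a", False)
        with pytest.raises(ValueError):
            fc.multi_lead_synthesize([e])

    def test_identical_copy_sites_synthesis(self, rng):
        base = random_site(rng, n=30, p=2, site_id="s0")
        sites = [fc.SiteData(f"s{j}", base.times, base.events, base.X)
                 for j in range(3)]
        init = [fc.make_init_message(s) for s in sites]
        bb, _ = fc.meta_combine(init)
        msgs = [fc.make_deriv_message(s, bb) for s in sites]
        g, H = fc.aggregate_derivatives(msgs)
        ests = [fc.fit_surrogate(fc.build_surrogate(s, bb, g, H),
                                 total_n=sum(x.n for x in sites))
                for s in sites]
        out = fc.multi_lead_synthesize(ests)
        np.testing.assert_allclose(out.beta_tilde, ests[0].beta_tilde,
                                   atol=1e-8)


class TestProtocolDriver:
    def test_lead_defaults_to_largest_site_with_events(self, rng,
                                                       all_censored_site):
        big_censored = fc.SiteData("big", np.tile(all_censored_site.times, 20),
                                   np.tile(all_censored_site.events, 20),
                                   np.tile(all_censored_site.X, (20, 1)))
        small = random_site(rng, n=10, p=1, site_id="small")
        assert choose_lead_site([big_censored, small]) == 1

    def test_surrogate_improves_on_meta(self, rng):
        """The one-shot correction moves the estimate much closer to the
        pooled fit than the meta-analysis anchor in nearly all draws."""
        cfg = fc.SimulationConfig(n_sites=4, n_per_site=150,
                                  event_rate_target=0.2, n_reps=30, seed=5)
        res = fc.run_benchmark(cfg)
        d_odach = np.abs(res.odach - res.pooled).max(axis=1)
        d_meta = np.abs(res.meta - res.pooled).max(axis=1)
        assert np.mean(d_odach < d_meta) >= 0.95
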