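"""One-shot federated protocol for the stratified Cox model (ODACH).

The protocol has three steps and exactly two rounds of communication:

1. *Initialize* — every site fits a local Cox model and transmits only
   ``(beta_hat_j, V_hat_j)``.  The coordinator forms the inverse-variance
   weighted anchor ``beta_bar`` (which is also the plain meta-analysis
   estimator used as a comparator).
2. *Derive* — every site evaluates its local gradient and Hessian at
   ``beta_bar`` and transmits them.  The global derivatives of the
   stratified likelihood are the n_j-weighted averages of the local ones.
3. *Estimate* — the lead site, which keeps its patient-level data, builds
   the surrogate likelihood

       Lt(b) = L1(b) + <gL(bb) - gL1(bb), b>
               + 1/2 (b - bb)' [HL(bb) - HL1(bb)] (b - bb)

   and maximises it.  At ``beta_bar`` the surrogate's gradient and Hessian
   equal the pooled stratified ones exactly, so the maximiser tracks the
   pooled estimate far better than meta-analysis when site-level fits are
   unstable (rare events, small sites).

Every transmitted object carries only O(p^2) aggregates; subject-level
fields never leave a site.  Derivative messages echo the anchor they were
evaluated at, and aggregation refuses mixed anchors ("stale derivatives").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cox_core import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    CoxFitResult,
    NoEventsError,
    SiteData,
    _newton,
    fit_local_cox,
    hessian,
    log_partial_likelihood,
    score,
)

__all__ = [
    "SiteInitMessage",
    "SiteDerivMessage",
    "SurrogateProblem",
    "OdachEstimate",
    "StaleDerivativesError",
    "make_init_message",
    "make_deriv_message",
    "meta_combine",
    "aggregate_derivatives",
    "build_surrogate",
    "fit_surrogate",
    "multi_lead_synthesize",
    "run_odach",
    "choose_lead_site",
]


class StaleDerivativesError(ValueError):
    """Derivative messages were evaluated at different anchor points."""


@dataclass
class SiteInitMessage:
    """Round-1 message: local estimate and variance, or a failure flag."""

    site_id: str
    n: int
    beta_hat: np.ndarray | None
    vcov: np.ndarray | None
    fit_ok: bool

    def __post_init__(self):
        if self.fit_ok and (self.beta_hat is None or self.vcov is None):
            raise ValueError("fit_ok message must carry beta_hat and vcov")
        if not self.fit_ok:
            self.beta_hat = None
            self.vcov = None


@dataclass
class SiteDerivMessage:
    """Round-2 message: local gradient/Hessian at the shared anchor."""

    site_id: str
    n: int
    grad: np.ndarray
    hess: np.ndarray
    beta_bar_used: np.ndarray

    def __post_init__(self):
        self.grad = np.asarray(self.grad, dtype=float).ravel()
        self.hess = np.asarray(self.hess, dtype=float)
        self.beta_bar_used = np.asarray(self.beta_bar_used,
                                        dtype=float).ravel()


@dataclass
class SurrogateProblem:
    """Lead-site data plus global derivatives: defines the surrogate Lt."""

    lead_data: SiteData
    beta_bar: np.ndarray
    global_grad: np.ndarray
    global_hess: np.ndarray
    lead_grad: np.ndarray
    lead_hess: np.ndarray

    def loglik(self, beta) -> float:
        beta = np.asarray(beta, dtype=float).ravel()
        d = beta - self.beta_bar
        dg = self.global_grad - self.lead_grad
        dH = self.global_hess - self.lead_hess
        return (log_partial_likelihood(self.lead_data, beta)
                + float(dg @ beta) + 0.5 * float(d @ dH @ d))

    def grad(self, beta) -> np.ndarray:
        beta = np.asarray(beta, dtype=float).ravel()
        return (score(self.lead_data, beta)
                + (self.global_grad - self.lead_grad)
                + (self.global_hess - self.lead_hess) @ (beta - self.beta_bar))

    def hess(self, beta) -> np.ndarray:
        return (hessian(self.lead_data, np.asarray(beta, dtype=float))
                + (self.global_hess - self.lead_hess))


@dataclass
class OdachEstimate:
    """Surrogate-likelihood estimate from one lead site."""

    beta_tilde: np.ndarray
    vcov: np.ndarray | None
    lead_site_id: str
    converged: bool
    n_iter: int = 0


def make_init_message(data: SiteData, tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER) -> SiteInitMessage:
    """Run the local fit and package the round-1 aggregates."""
    try:
        fit = fit_local_cox(data, tol=tol, max_iter=max_iter)
    except NoEventsError:
        return SiteInitMessage(data.site_id, data.n, None, None, False)
    if not fit.converged or fit.vcov is None:
        return SiteInitMessage(data.site_id, data.n, None, None, False)
    return SiteInitMessage(data.site_id, data.n, fit.beta_hat, fit.vcov, True)


def make_deriv_message(data: SiteData, beta_bar) -> SiteDerivMessage:
    """Evaluate local derivatives at the anchor (needs no local MLE)."""
    beta_bar = np.asarray(beta_bar, dtype=float).ravel()
    return SiteDerivMessage(data.site_id, data.n,
                            score(data, beta_bar), hessian(data, beta_bar),
                            beta_bar)


def meta_combine(messages: Sequence[SiteInitMessage]):
    """Inverse-variance weighted combination of local estimates.

    Returns ``(beta_bar, vcov)`` with
    ``beta_bar = (sum V_j^-1)^-1 sum V_j^-1 beta_j`` over usable messages.
    This is both the protocol's anchor and the fixed-effect meta-analysis
    estimator.  Messages without a converged fit, or with a singular
    variance, are excluded with a warning.
    """
    wsum = None
    wbsum = None
    used = 0
    for m in messages:
        if not m.fit_ok:
            warnings.warn(f"site {m.site_id!r} excluded from combination "
                          "(local fit failed)")
            continue
        try:
            w = np.linalg.inv(np.asarray(m.vcov, dtype=float))
        except np.linalg.LinAlgError:
            warnings.warn(f"site {m.site_id!r} excluded from combination "
                          "(singular variance)")
            continue
        b = np.asarray(m.beta_hat, dtype=float).ravel()
        wsum = w if wsum is None else wsum + w
        wbsum = w @ b if wbsum is None else wbsum + w @ b
        used += 1
    if used == 0:
        raise ValueError("no usable init messages to combine")
    vcov = np.linalg.inv(wsum)
    vcov = (vcov + vcov.T) / 2.0
    return vcov @ wbsum, vcov


def aggregate_derivatives(messages: Sequence[SiteDerivMessage]):
    """n_j-weighted average of local gradients/Hessians at a shared anchor.

    Reproduces the pooled stratified score and Hessian at ``beta_bar``
    exactly, because the stratified likelihood is itself the n_j-weighted
    average of site likelihoods.
    """
    messages = list(messages)
    if not messages:
        raise ValueError("no derivative messages")
    bb = messages[0].beta_bar_used
    for m in messages[1:]:
        if m.beta_bar_used.shape != bb.shape or not np.array_equal(
                m.beta_bar_used, bb):
            raise StaleDerivativesError(
                f"site {m.site_id!r} evaluated derivatives at a different "
                "anchor than the rest of the round")
    N = sum(m.n for m in messages)
    g = sum(m.n * m.grad for m in messages) / N
    H = sum(m.n * m.hess for m in messages) / N
    return g, H


def build_surrogate(lead: SiteData, beta_bar, global_grad,
                    global_hess) -> SurrogateProblem:
    """Assemble the surrogate likelihood around the anchor point."""
    if lead.n_events == 0:
        raise NoEventsError(
            f"lead site {lead.site_id!r} has no events; its likelihood "
            "cannot anchor the surrogate")
    beta_bar = np.asarray(beta_bar, dtype=float).ravel()
    global_grad = np.asarray(global_grad, dtype=float).ravel()
    global_hess = np.asarray(global_hess, dtype=float)
    if beta_bar.shape[0] != lead.p or global_grad.shape[0] != lead.p:
        raise ValueError("dimension mismatch between lead data and anchors")
    return SurrogateProblem(
        lead_data=lead, beta_bar=beta_bar,
        global_grad=global_grad, global_hess=global_hess,
        lead_grad=score(lead, beta_bar), lead_hess=hessian(lead, beta_bar))


def fit_surrogate(problem: SurrogateProblem, tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER,
                  total_n: int | None = None) -> OdachEstimate:
    """Maximise the surrogate likelihood by Newton-Raphson from the anchor.

    The variance treats the surrogate as the full-data likelihood:
    ``vcov = [-N * hess_Lt(beta_tilde)]^{-1}`` with ``N`` the total sample
    size across all sites (defaults to the lead-site n when unknown; pass
    ``total_n`` from the protocol driver for the federation-wide scale).
    This is approximate — see the methods note.
    """
    N = total_n if total_n is not None else problem.lead_data.n
    fit = _newton(problem.loglik, problem.grad, problem.hess,
                  info_scale=N, init=problem.beta_bar,
                  tol=tol, max_iter=max_iter)
    return OdachEstimate(beta_tilde=fit.beta_hat, vcov=fit.vcov,
                         lead_site_id=problem.lead_data.site_id,
                         converged=fit.converged, n_iter=fit.n_iter)


def multi_lead_synthesize(
        estimates: Sequence[OdachEstimate]) -> OdachEstimate:
    """Combine per-lead surrogate estimates by inverse-variance weighting.

    When every site has the shared derivatives it can act as its own lead;
    the per-lead estimates are then synthesised with the same
    inverse-variance formula as the anchor.
    """
    usable = [e for e in estimates if e.converged and e.vcov is not None]
    if not usable:
        raise ValueError("no converged surrogate estimates to synthesize")
    wsum = sum(np.linalg.inv(e.vcov) for e in usable)
    wbsum = sum(np.linalg.inv(e.vcov) @ e.beta_tilde for e in usable)
    vcov = np.linalg.inv(wsum)
    vcov = (vcov + vcov.T) / 2.0
    lead_ids = ",".join(e.lead_site_id for e in usable)
    return OdachEstimate(beta_tilde=vcov @ wbsum, vcov=vcov,
                         lead_site_id=lead_ids, converged=True)


def choose_lead_site(sites: Sequence[SiteData]) -> int:
    """Default lead: the largest site, among sites with at least one event.

    A lead without events has a degenerate likelihood and cannot anchor
    the surrogate; ties in size are broken by event count, then order.
    """
    eligible = [(s.n, s.n_events, -i) for i, s in enumerate(sites)
                if s.n_events > 0]
    if not eligible:
        raise NoEventsError("no site has any events")
    n, ev, neg_i = max(eligible)
    return -neg_i


def run_odach(sites: Sequence[SiteData], lead_index: int | None = None,
              tol: float = DEFAULT_TOL,
              max_iter: int = DEFAULT_MAX_ITER):
    """End-to-end in-memory protocol driver.

    Runs the two communication rounds and the lead-site estimate; the
    structure makes a third round impossible.  Returns
    ``(estimate, beta_bar, meta_vcov)`` so callers get the meta-analysis
    comparator for free.
    """
    sites = list(sites)
    if lead_index is None:
        lead_index = choose_lead_site(sites)
    init_msgs = [make_init_message(s, tol=tol, max_iter=max_iter)
                 for s in sites]
    beta_bar, meta_vcov = meta_combine(init_msgs)
    deriv_msgs = [make_deriv_message(s, beta_bar) for s in sites]
    global_grad, global_hess = aggregate_derivatives(deriv_msgs)
    problem = build_surrogate(sites[lead_index], beta_bar,
                              global_grad, global_hess)
    est = fit_surrogate(problem, tol=tol, max_iter=max_iter,
                        total_n=sum(s.n for s in sites))
    return est, beta_bar, meta_vcov
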