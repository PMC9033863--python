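"""Exact numerics of the stratified Cox partial likelihood.

Each site holds subjects ``(T, delta, x)`` with observed follow-up time
``T > 0``, event indicator ``delta`` (1 = event, 0 = censored) and a
p-vector of covariates ``x``.  The site-level log partial likelihood is

    L_j(beta) = (1/n_j) * sum_i delta_i * [beta'x_i - log S0(beta, T_i)]

with ``S0(beta, t) = sum_{s: T_s >= t} exp(beta'x_s)`` the risk-set sum.
Ties are handled with the Breslow convention: the denominator at a tied
event time includes every subject whose time is >= that time (so a subject
censored exactly at an event time is still at risk), and each tied event
contributes its own term.

The stratified (pooled) likelihood is the n_j-weighted average of the
site likelihoods; risk sets never cross sites, so each site keeps its own
unspecified baseline hazard while the log hazard ratios ``beta`` are
shared.

Fitting is damped Newton-Raphson on the concave partial likelihood.  The
reported variance is the inverse observed information on the unnormalised
likelihood scale, ``[-n_j * hessian]^{-1}``, which matches what a standard
Cox fit reports and is what inverse-variance combination downstream needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectRecord",
    "SiteData",
    "RiskSetSums",
    "CoxFitResult",
    "NoEventsError",
    "log_partial_likelihood",
    "score",
    "hessian",
    "fit_local_cox",
    "fit_pooled_stratified",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
_MAX_HALVINGS = 20


class NoEventsError(ValueError):
    """Raised when a fit is requested on data with no observed events."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: observed time, event indicator and covariate vector."""

    time: float
    event: int
    covariates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "covariates",
                           np.asarray(self.covariates, dtype=float).ravel())
        if not self.time > 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class SiteData:
    """A single site's subjects; never crosses the site boundary.

    Internally stores column arrays ``times`` (n,), ``events`` (n,) and
    ``X`` (n, p) for vectorised likelihood evaluation.
    """

    site_id: str
    times: np.ndarray
    events: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.events = np.asarray(self.events, dtype=int).ravel()
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X = X
        n = self.times.shape[0]
        if n == 0:
            raise ValueError("site must contain at least one record")
        if self.events.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("times, events and X must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("all times must be positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0/1")

    @classmethod
    def from_records(cls, site_id: str,
                     records: Sequence[SubjectRecord]) -> "SiteData":
        return cls(
            site_id=site_id,
            times=np.array([r.time for r in records]),
            events=np.array([r.event for r in records]),
            X=np.vstack([r.covariates for r in records]),
        )

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def records(self) -> list[SubjectRecord]:
        return [SubjectRecord(t, int(d), x)
                for t, d, x in zip(self.times, self.events, self.X)]


@dataclass(frozen=True)
class RiskSetSums:
    """Risk-set sums S0, S1, S2 at one event time.

    S0 = sum exp(beta'x), S1 = sum x exp(beta'x), S2 = sum xx' exp(beta'x),
    each over subjects still at risk.  S2 - S1 S1'/S0 is the (scaled)
    covariance of x over the risk set, hence positive semidefinite.
    """

    s0: float
    s1: np.ndarray
    s2: np.ndarray


@dataclass
class CoxFitResult:
    """Maximum partial-likelihood fit: estimate, variance, diagnostics."""

    beta_hat: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)


def _check_beta(data: SiteData, beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.p:
        raise ValueError(
            f"beta has length {beta.shape[0]}, expected p={data.p}")
    return beta


def _event_risk_sums(data: SiteData, beta: np.ndarray):
    """Risk-set sums S0/S1/S2 evaluated at every event time.

    Sorting once ascending in time, suffix sums give
    S(t) = total - prefix(T < t); searchsorted with side='left' puts all
    subjects with T >= t (Breslow ties included) into the risk set.
    Returns (eta_ev, x_ev, s0, s1, s2) over the event subjects.
    """
    order = np.argsort(data.times, kind="stable")
    ts = data.times[order]
    Xs = data.X[order]
    eta_s = Xs @ beta
    # guard against overflow for extreme beta during line searches
    w = np.exp(np.clip(eta_s, -700, 700))

    c0 = np.concatenate([[0.0], np.cumsum(w)])
    c1 = np.concatenate([np.zeros((1, data.p)),
                         np.cumsum(w[:, None] * Xs, axis=0)])
    outer = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    c2 = np.concatenate([np.zeros((1, data.p, data.p)),
                         np.cumsum(outer, axis=0)])

    ev = data.events == 1
    t_ev = data.times[ev]
    idx = np.searchsorted(ts, t_ev, side="left")
    s0 = c0[-1] - c0[idx]
    s1 = c1[-1] - c1[idx]
    s2 = c2[-1] - c2[idx]
    eta_ev = data.X[ev] @ beta
    return eta_ev, data.X[ev], s0, s1, s2


def log_partial_likelihood(data: SiteData, beta) -> float:
    """Site log partial likelihood, normalised by site size.

    All-censored data contribute an empty sum and return 0.0.
    """
    beta = _check_beta(data, beta)
    if data.n_events == 0:
        return 0.0
    eta_ev, _, s0, _, _ = _event_risk_sums(data, beta)
    return float(np.sum(eta_ev - np.log(s0)) / data.n)


def score(data: SiteData, beta) -> np.ndarray:
    """Gradient of the normalised site log partial likelihood."""
    beta = _check_beta(data, beta)
    if data.n_events == 0:
        return np.zeros(data.p)
    _, x_ev, s0, s1, _ = _event_risk_sums(data, beta)
    return np.sum(x_ev - s1 / s0[:, None], axis=0) / data.n


def hessian(data: SiteData, beta) -> np.ndarray:
    """Hessian of the normalised site log partial likelihood.

    Equals minus the average over events of the risk-set covariance of x,
    so it is symmetric negative semidefinite at every beta.
    """
    beta = _check_beta(data, beta)
    if data.n_events == 0:
        return np.zeros((data.p, data.p))
    _, _, s0, s1, s2 = _event_risk_sums(data, beta)
    xbar = s1 / s0[:, None]
    V = s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    H = -np.sum(V, axis=0) / data.n
    return (H + H.T) / 2.0


def _newton(loglik_fn, grad_fn, hess_fn, info_scale: float, init,
            tol: float, max_iter: int) -> CoxFitResult:
    """Damped Newton-Raphson shared by local, pooled and surrogate fits.

    ``info_scale`` converts the normalised Hessian into observed
    information (n_j for a site, N for pooled), used for the variance.
    """
    beta = np.asarray(init, dtype=float).copy()
    ll = loglik_fn(beta)
    msgs: list[str] = []
    converged = False
    step_tol = max(np.sqrt(tol), 10 * tol)
    it = 0
    for it in range(1, max_iter + 1):
        g = grad_fn(beta)
        H = hess_fn(beta)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            msgs.append("singular information matrix")
            break
        # a regular maximum needs both a flat gradient and a vanishing
        # Newton increment; under monotone likelihood (separation) the
        # gradient decays along the divergence path but the increment
        # stays large, so the increment check catches it
        if np.max(np.abs(g)) <= tol and np.max(np.abs(step)) <= step_tol:
            converged = True
            it -= 1
            break
        # step-halving keeps the concave objective non-decreasing
        alpha = 1.0
        for _ in range(_MAX_HALVINGS):
            cand = beta + alpha * step
            ll_new = loglik_fn(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-14:
                break
            alpha *= 0.5
        else:
            msgs.append("step-halving failed to improve the likelihood")
            break
        beta = beta + alpha * step
        ll = ll_new

    vcov = None
    if converged:
        H = hess_fn(beta)
        info = -info_scale * H
        try:
            vcov = np.linalg.inv(info)
            vcov = (vcov + vcov.T) / 2.0
            if not np.all(np.linalg.eigvalsh(vcov) > 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            vcov = None
            converged = False
            msgs.append("observed information not positive definite")
    if not converged and not msgs:
        msgs.append("Newton-Raphson did not converge "
                    "(possible monotone likelihood)")
    return CoxFitResult(beta_hat=beta, vcov=vcov, loglik=loglik_fn(beta),
                        converged=converged, n_iter=it, warnings=msgs)


def fit_local_cox(data: SiteData, init=None, tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER) -> CoxFitResult:
    """Maximum partial-likelihood fit on a single site.

    Raises :class:`NoEventsError` if the site has no events (the partial
    likelihood is identically zero and beta is unidentified).
    """
    if data.n_events == 0:
        raise NoEventsError(f"site {data.site_id!r} has no events")
    if init is None:
        init = np.zeros(data.p)
    return _newton(lambda b: log_partial_likelihood(data, b),
                   lambda b: score(data, b),
                   lambda b: hessian(data, b),
                   info_scale=data.n, init=init, tol=tol, max_iter=max_iter)


def fit_pooled_stratified(sites: Sequence[SiteData], init=None,
                          tol: float = DEFAULT_TOL,
                          max_iter: int = DEFAULT_MAX_ITER) -> CoxFitResult:
    """Stratified fit on pooled patient-level data (the gold standard).

    Maximises the n_j-weighted average of site log partial likelihoods;
    every site is its own stratum, so baseline hazards stay site specific.
    Sites without events contribute zero and are harmless.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites provided")
    p = sites[0].p
    if any(s.p != p for s in sites):
        raise ValueError("all sites must share the same covariate dimension")
    if all(s.n_events == 0 for s in sites):
        raise NoEventsError("no events in any site")
    N = sum(s.n for s in sites)
    if init is None:
        init = np.zeros(p)

    def ll(b):
        return sum(s.n * log_partial_likelihood(s, b) for s in sites) / N

    def gr(b):
        return sum(s.n * score(s, b) for s in sites) / N

    def he(b):
        return sum(s.n * hessian(s, b) for s in sites) / N

    return _newton(ll, gr, he, info_scale=N, init=init, tol=tol,
                   max_iter=max_iter)
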