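"""File formats for per-site data and protocol messages.

Site data travel as CSV with header ``id,time,event,x1,...,xp``.  Protocol
messages are JSON: ``init_<site>.json`` carries the local estimate and
variance, ``deriv_<site>.json`` the gradient/Hessian at the anchor, and
``control.json`` the coordinator state (anchor, lead site, round).  JSON
floats are serialised with Python's shortest round-trip repr, so a write/
read cycle is bit-faithful.

Message schemas are closed: a serialised message may contain only the
whitelisted aggregate fields, which is the module-level enforcement of
the privacy contract (no subject-level values ever enter a message).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cox_core import SiteData
from .protocol import OdachEstimate, SiteDerivMessage, SiteInitMessage

__all__ = [
    "ProtocolState",
    "read_site_csv",
    "write_site_csv",
    "write_init_message",
    "read_init_message",
    "write_deriv_message",
    "read_deriv_message",
    "write_control",
    "read_control",
    "write_estimate",
]

_ROUNDS = ("init", "derive", "estimate")

INIT_FIELDS = {"site_id", "n", "beta_hat", "vcov", "fit_ok"}
DERIV_FIELDS = {"site_id", "n", "grad", "hess", "beta_bar_used"}


@dataclass
class ProtocolState:
    """Coordinator state written to ``control.json``; rounds only advance."""

    round: str
    p: int
    covariate_names: list[str]
    lead_site: str
    beta_bar: list[float] | None = None

    def __post_init__(self):
        if self.round not in _ROUNDS:
            raise ValueError(f"unknown round {self.round!r}")
        if (self.beta_bar is None) != (self.round == "init"):
            raise ValueError("beta_bar must be present exactly when the "
                             "round is past initialization")


def read_site_csv(path) -> SiteData:
    """Parse a site CSV ``id,time,event,x1..xp``; errors cite the row."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    xcols = [c for c in cols if c.startswith("x")]
    expected = ["id", "time", "event"] + xcols
    if cols[:3] != ["id", "time", "event"] or not xcols or cols != expected:
        raise ValueError(
            f"{path.name}: header must be id,time,event,x1,...,xp "
            f"(got {','.join(cols)})")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path.name}: missing value on row {row}")
    try:
        times = df["time"].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric time ({exc})") from exc
    events_raw = df["event"].astype(float).to_numpy()
    X = df[xcols].astype(float).to_numpy()
    for i, (t, d) in enumerate(zip(times, events_raw), start=1):
        if not t > 0:
            raise ValueError(f"{path.name}: non-positive time on row {i}")
        if d not in (0.0, 1.0):
            raise ValueError(f"{path.name}: event must be 0/1 on row {i}")
    return SiteData(site_id=path.stem, times=times,
                    events=events_raw.astype(int), X=X)


def write_site_csv(data: SiteData, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"id": np.arange(1, data.n + 1),
                       "time": [repr(float(t)) for t in data.times],
                       "event": data.events})
    for k in range(data.p):
        df[f"x{k + 1}"] = [repr(float(v)) for v in data.X[:, k]]
    df.to_csv(path, index=False)


def _dump(obj: dict, path, allowed: set[str] | None = None) -> None:
    if allowed is not None:
        extra = set(obj) - allowed
        if extra:
            raise ValueError(
                f"refusing to serialize non-aggregate fields: {extra}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load(path) -> dict:
    return json.loads(Path(path).read_text())


def write_init_message(msg: SiteInitMessage, path) -> None:
    obj = {"site_id": msg.site_id, "n": int(msg.n), "fit_ok": msg.fit_ok,
           "beta_hat": None if msg.beta_hat is None
           else np.asarray(msg.beta_hat, float).tolist(),
           "vcov": None if msg.vcov is None
           else np.asarray(msg.vcov, float).tolist()}
    _dump(obj, path, INIT_FIELDS)


def read_init_message(path) -> SiteInitMessage:
    o = _load(path)
    return SiteInitMessage(
        site_id=o["site_id"], n=int(o["n"]), fit_ok=bool(o["fit_ok"]),
        beta_hat=None if o["beta_hat"] is None else np.asarray(o["beta_hat"]),
        vcov=None if o["vcov"] is None else np.asarray(o["vcov"]))


def write_deriv_message(msg: SiteDerivMessage, path) -> None:
    obj = {"site_id": msg.site_id, "n": int(msg.n),
           "grad": msg.grad.tolist(), "hess": msg.hess.tolist(),
           "beta_bar_used": msg.beta_bar_used.tolist()}
    _dump(obj, path, DERIV_FIELDS)


def read_deriv_message(path) -> SiteDerivMessage:
    o = _load(path)
    return SiteDerivMessage(site_id=o["site_id"], n=int(o["n"]),
                            grad=np.asarray(o["grad"]),
                            hess=np.asarray(o["hess"]),
                            beta_bar_used=np.asarray(o["beta_bar_used"]))


def write_control(state: ProtocolState, path) -> None:
    _dump({"round": state.round, "p": state.p,
           "covariate_names": state.covariate_names,
           "lead_site": state.lead_site,
           "beta_bar": state.beta_bar}, path)


def read_control(path) -> ProtocolState:
    o = _load(path)
    return ProtocolState(round=o["round"], p=int(o["p"]),
                         covariate_names=list(o["covariate_names"]),
                         lead_site=o["lead_site"],
                         beta_bar=o["beta_bar"])


def write_estimate(est: OdachEstimate, path, covariate_names=None,
                   provenance: dict | None = None) -> None:
    p = len(est.beta_tilde)
    names = covariate_names or [f"x{k + 1}" for k in range(p)]
    se = (np.sqrt(np.diag(est.vcov)) if est.vcov is not None
          else np.full(p, np.nan))
    obj = {
        "lead_site": est.lead_site_id,
        "converged": est.converged,
        "beta_tilde": np.asarray(est.beta_tilde, float).tolist(),
        "vcov": None if est.vcov is None else np.asarray(est.vcov).tolist(),
        "log_hr": {
            name: {"estimate": float(b), "se": float(s),
                   "ci95": [float(b - 1.959963984540054 * s),
                            float(b + 1.959963984540054 * s)]}
            for name, b, s in zip(names, est.beta_tilde, se)},
        "provenance": provenance or {},
    }
    _dump(obj, path)
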