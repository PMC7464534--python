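"""Brownian-motion comparative methods: REML/ML rate estimation via
independent contrasts, ancestral state reconstruction, per-clade rates,
and tip rates.

The trait x evolves by Brownian motion with rate sigma2 (trait units
squared per My).  The REML estimator is the closed form from Felsenstein's
standardized contrasts, sigma2 = sum(u_i^2) / (n - 1), whose restricted
log-likelihood equals that of the zero-mean multivariate normal of any
(n-1)-dimensional contrast basis; the test suite verifies this against
dense matrix algebra.  Ancestral estimates are the GLS/ML values obtained
by a linear-time up-down message-passing sweep, equal to
mu_hat + C_k C^{-1} (x - mu_hat 1) from the covariance matrix.

All tip-facing functions accept the trait as a mapping or pandas Series
keyed by tip label; internally everything is vectorised over trait
columns, so calibration simulations can fit thousands of replicates in a
single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core import PhyloTree, Node, prune_to, resolve_polytomies

__all__ = ["BMFit", "TipRate", "independent_contrasts", "fit_bm",
           "ancestral_states", "tip_rates", "rates_by_group"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class BMFit:
    """A fitted single-rate Brownian-motion model."""

    sigma2: float
    root_state: float
    loglik: float
    node_estimates: dict[Node, float]
    method: str  # "REML" or "ML"
    units: str = ""

    def __post_init__(self):
        assert self.sigma2 >= 0


@dataclass(frozen=True)
class TipRate:
    """Recent per-lineage rate: (tip value - parent ancestral estimate)
    divided by the terminal branch length, in trait units per My."""

    species: str
    rate: float
    parent_estimate: float
    branch_length: float


def _trait_matrix(tree: PhyloTree, x) -> np.ndarray:
    """Align trait input (mapping/Series keyed by tip label, or array in
    tip order) to the tree's tips; returns (n_tips, k)."""
    labels = tree.tip_labels
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, dict):
        missing = [t for t in labels if t not in x or pd.isna(x[t])]
        if missing:
            raise ValueError(f"missing trait values for species: {missing}")
        arr = np.asarray([x[t] for t in labels], dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.shape[0] != len(labels):
            raise ValueError(
                f"trait vector length {arr.shape[0]} != {len(labels)} tips")
        if np.isnan(arr).any():
            bad = [labels[i] for i in np.nonzero(np.isnan(arr).reshape(arr.shape[0], -1).any(axis=1))[0]]
            raise ValueError(f"missing trait values for species: {bad}")
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _binary(tree: PhyloTree) -> PhyloTree:
    return tree if tree.is_bifurcating() else resolve_polytomies(tree)


def _contrasts_sweep(tree: PhyloTree, X: np.ndarray):
    """Felsenstein pruning pass.

    Returns (U_raw (n-1, k) raw contrasts, v (n-1,) contrast variances,
    node_value (dict node -> (k,) conditional value), v_root, order of
    internal nodes).  Branch-length units carry through: v is in My.
    """
    tips = tree.tips()
    tip_index = {t: i for i, t in enumerate(tips)}
    k = X.shape[1]
    value: dict[Node, np.ndarray] = {}
    extra: dict[Node, float] = {}  # extra variance accumulated above node
    U = []
    v = []
    for node in tree.postorder():
        if node.is_tip:
            value[node] = X[tip_index[node]]
            extra[node] = 0.0
            continue
        if len(node.children) != 2:
            raise ValueError("contrasts require a bifurcating tree; "
                             "resolve polytomies first")
        c1, c2 = node.children
        t1 = (c1.length or 0.0) + extra[c1]
        t2 = (c2.length or 0.0) + extra[c2]
        vt = t1 + t2
        if vt <= 0:
            raise ValueError("zero-variance contrast: sister branches both "
                             "have zero adjusted length")
        U.append(value[c1] - value[c2])
        v.append(vt)
        value[node] = (value[c1] * t2 + value[c2] * t1) / vt
        extra[node] = t1 * t2 / vt
    return np.asarray(U), np.asarray(v), value, extra[tree.root]


def independent_contrasts(tree: PhyloTree, x):
    """Standardized independent contrasts and their variances.

    Returns (u (n-1,) standardized contrasts, v (n-1,) variances in My).
    Under BM the u_i are i.i.d. Normal(0, sigma2).
    """
    work = _binary(tree)
    X = _trait_matrix(work, x)
    U, v, _, _ = _contrasts_sweep(work, X)
    u = U / np.sqrt(v)[:, None]
    if X.shape[1] == 1:
        return u[:, 0], v
    return u, v


def fit_bm(tree: PhyloTree, x, method: str = "REML", units: str = "") -> BMFit:
    """Fit a single-rate BM model.

    REML: sigma2 = sum u_i^2 / (n-1) with the restricted log-likelihood;
    ML: sigma2 = Q/n with the root profiled out analytically.  Both are
    closed-form (no iterative optimiser).
    """
    work = _binary(tree)
    X = _trait_matrix(work, x)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 tips to fit BM")
    sig2, mu, ll = _fit_bm_columns(work, X, method)
    anc, _, _ = _ancestral_sweep(work, X)
    node_estimates = {n: float(val[0]) for n, val in anc.items()}
    fit = BMFit(sigma2=float(sig2[0]), root_state=float(mu[0]),
                loglik=float(ll[0]), node_estimates=node_estimates,
                method=method, units=units)
    return fit


def _fit_bm_columns(tree: PhyloTree, X: np.ndarray, method: str = "REML"):
    """Vectorised closed-form fit per trait column; tree must be binary."""
    n = X.shape[0]
    U, v, value, v_root = _contrasts_sweep(tree, X)
    Q = (U ** 2 / v[:, None]).sum(axis=0)  # (k,) = (x-mu)' C^-1 (x-mu)
    mu = value[tree.postorder()[-1]]  # root conditional value == GLS mean
    sum_log_v = float(np.log(v).sum())
    if method == "REML":
        sig2 = Q / (n - 1)
        # restricted loglik at the optimum, contrast form
        with np.errstate(divide="ignore"):
            ll = -0.5 * ((n - 1) * _LOG2PI + (n - 1) * _safe_log(sig2)
                         + sum_log_v + _safe_div(Q, sig2))
    elif method == "ML":
        sig2 = Q / n
        # log|C| = sum log v_i + log v_root  (verified against dense algebra)
        log_det_C = sum_log_v + math.log(v_root)
        with np.errstate(divide="ignore"):
            ll = -0.5 * (n * _LOG2PI + n * _safe_log(sig2)
                         + log_det_C + _safe_div(Q, sig2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return sig2, mu, ll


def _safe_log(x):
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    pos = x > 0
    out[pos] = np.log(x[pos])
    return out


def _safe_div(q, s):
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    out = np.zeros(np.broadcast(q, s).shape)
    pos = s > 0
    out[pos] = (q / np.where(pos, s, 1.0))[pos]
    return out


def reml_loglik(tree: PhyloTree, x, sigma2: float) -> float:
    """Restricted log-likelihood of a given sigma2 (contrast form)."""
    work = _binary(tree)
    X = _trait_matrix(work, x)
    n = X.shape[0]
    U, v, _, _ = _contrasts_sweep(work, X)
    Q = float((U[:, 0] ** 2 / v).sum())
    if sigma2 <= 0:
        return float(-np.inf) if Q > 0 else float(np.inf)
    return -0.5 * ((n - 1) * (_LOG2PI + math.log(sigma2))
                   + float(np.log(v).sum()) + Q / sigma2)


def _ancestral_sweep(tree: PhyloTree, X: np.ndarray):
    """GLS ancestral estimates at every internal node by up-down message
    passing; works on an arbitrary (possibly multifurcating) tree.

    Returns (estimates, down_m, down_v); the downward messages give, for
    each node, the GLS estimate of its parent's state from all data
    *outside* the node's subtree (used by leave-one-out tip rates).
    """
    tips = tree.tips()
    tip_index = {t: i for i, t in enumerate(tips)}
    up_m: dict[Node, np.ndarray] = {}
    up_v: dict[Node, float] = {}
    post = tree.postorder()
    for node in post:
        if node.is_tip:
            up_m[node] = X[tip_index[node]]
            up_v[node] = 0.0
        else:
            prec = 0.0
            mean = 0.0
            for c in node.children:
                t = (c.length or 0.0) + up_v[c]
                if t <= 0:
                    # zero-length child with exact value: infinite precision
                    prec = np.inf
                    mean = up_m[c]
                    break
                prec += 1.0 / t
                mean = mean + up_m[c] / t
            if prec is np.inf or prec == np.inf:
                up_m[node] = mean if isinstance(mean, np.ndarray) else mean
                up_v[node] = 0.0
            else:
                up_m[node] = mean / prec
                up_v[node] = 1.0 / prec
    # downward messages
    down_m: dict[Node, np.ndarray] = {}
    down_v: dict[Node, float] = {}
    estimates: dict[Node, np.ndarray] = {}
    root = post[-1]
    estimates[root] = up_m[root]
    down_m[root] = None  # root has no above-message
    down_v[root] = np.inf
    for node in tree.preorder():
        if node.is_tip:
            continue
        for c in node.children:
            # combine node's down message with siblings' up messages
            prec = 0.0
            mean = 0.0
            if down_v[node] != np.inf:
                prec += 1.0 / down_v[node]
                mean = mean + down_m[node] / down_v[node]
            for s in node.children:
                if s is c:
                    continue
                t = (s.length or 0.0) + up_v[s]
                if t <= 0:
                    t = 1e-12
                prec += 1.0 / t
                mean = mean + up_m[s] / t
            if prec == 0.0:
                down_m[c] = None
                down_v[c] = np.inf
            else:
                down_m[c] = mean / prec
                down_v[c] = 1.0 / prec + (c.length or 0.0)
            if not c.is_tip:
                if down_v[c] == np.inf:
                    estimates[c] = up_m[c]
                elif up_v[c] == 0.0:
                    estimates[c] = up_m[c]
                else:
                    pu = 1.0 / up_v[c]
                    pd_ = 1.0 / down_v[c]
                    estimates[c] = (up_m[c] * pu + down_m[c] * pd_) / (pu + pd_)
    return estimates, down_m, down_v


def ancestral_states(tree: PhyloTree, x, fit: BMFit | None = None,
                     ) -> dict[str | int, dict]:
    """Ancestral state estimates (and variances when a fit is supplied) at
    every internal node.  Estimates are invariant to rescaling sigma2; only
    the variances scale.  Keys are postorder node ids."""
    work = _binary(tree)
    X = _trait_matrix(work, x)
    est, _, _ = _ancestral_sweep(work, X)
    out = {}
    for node, val in est.items():
        out[node.id] = {"estimate": float(val[0])}
    return out


def tip_rates(tree: PhyloTree, x, leave_one_out: bool = False) -> list[TipRate]:
    """Per-tip recent rate of change.

    The ancestral estimate at each tip's parent node comes from the joint
    GLS over all data (so the focal tip contributes to it); with
    ``leave_one_out`` the focal tip's contribution is removed, using the
    downward message alone.  Terminal branches must be strictly positive.
    """
    work = _binary(tree)
    X = _trait_matrix(work, x)
    zero_tips = [t.label for t in work.tips() if not t.length]
    if zero_tips:
        raise ValueError(f"zero-length terminal branches for: {zero_tips}")
    est, down_m, down_v = _ancestral_sweep(work, X)
    tips = work.tips()
    tip_index = {t: i for i, t in enumerate(tips)}
    out = []
    for t in tips:
        if leave_one_out:
            if down_m[t] is None:
                raise ValueError(f"no leave-one-out estimate for {t.label}")
            parent_est = float(down_m[t][0])
        else:
            parent_est = float(est[t.parent][0])
        xv = float(X[tip_index[t], 0])
        out.append(TipRate(
            species=t.label,
            rate=(xv - parent_est) / t.length,
            parent_estimate=parent_est,
            branch_length=t.length,
        ))
    return out


def rates_by_group(tree: PhyloTree, x, group_labels: dict[str, str],
                   min_n: int = 10, method: str = "REML",
                   units: str = "") -> dict[str, BMFit]:
    """Per-group BM fits on the induced subtree of each group's members.

    Groups with fewer than ``min_n`` members are skipped.  The stem branch
    of each group is excluded (the induced subtree keeps no root edge), so
    each estimate is strictly within-group.
    """
    if isinstance(x, pd.Series):
        x = x.to_dict()
    labels = tree.tip_labels
    missing = [t for t in labels if t not in group_labels]
    if missing:
        raise ValueError(f"missing group labels for: {missing}")
    groups: dict[str, list[str]] = {}
    for t in labels:
        groups.setdefault(group_labels[t], []).append(t)
    out: dict[str, BMFit] = {}
    for g, members in sorted(groups.items()):
        if len(members) < min_n:
            continue
        if len(members) == len(labels):
            sub = tree
        else:
            sub = prune_to(tree, members)
        xg = {t: x[t] for t in members} if isinstance(x, dict) else x
        out[g] = fit_bm(sub, xg, method=method, units=units)
    return out
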