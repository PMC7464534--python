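"""Two-state Markov (Mk) model with asymmetric rates, and stochastic
character mapping.

State 0 is holocentric, state 1 monocentric by convention; q01 and q10 are
the transition rates (events per My) in each direction.  Likelihoods use
Felsenstein pruning with the closed-form 2x2 transition matrix

    P(t) = Pi + exp(-(q01+q10) t) (I - Pi),   Pi = rows of (pi0, pi1),

where pi = (q10, q01)/(q01+q10) is the stationary distribution.  Branch
histories are sampled exactly, conditional on endpoint states, by
uniformization; ancestral node states are drawn from their joint
conditional distribution root-downwards, so a sampled map is a draw from
the posterior of full histories given the tip data and rates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .phylo_core import PhyloTree, Node, write_newick

__all__ = ["MkFit", "StochasticMap", "mk_loglik", "fit_mk_ard",
           "sample_stochastic_map", "write_simmap", "read_simmap"]

STATES = (0, 1)
STATE_NAMES = {0: "holocentric", 1: "monocentric"}


@dataclass
class MkFit:
    q01: float
    q10: float
    loglik: float
    root_prior: str = "flat"  # flat | stationary | fixed
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self):
        assert self.q01 >= 0 and self.q10 >= 0


@dataclass
class StochasticMap:
    """A full sampled history: for every non-root node, the ordered
    (state, duration) segments along the branch above it, parent to child.
    """

    tree: PhyloTree
    segments: dict[Node, list[tuple[int, float]]]
    node_states: dict[Node, int]

    def validate(self, tol: float = 1e-9) -> None:
        for node in self.tree.postorder():
            if node is self.tree.root:
                continue
            segs = self.segments[node]
            total = sum(d for _, d in segs)
            assert abs(total - (node.length or 0.0)) <= tol, \
                f"segment durations {total} != branch length {node.length}"
            assert segs[0][0] == self.node_states[node.parent]
            assert segs[-1][0] == self.node_states[node]
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                assert s1 != s2, "adjacent segments share a state"

    def time_in_state(self, state: int) -> float:
        return sum(d for segs in self.segments.values()
                   for s, d in segs if s == state)

    def n_changes(self) -> int:
        return sum(len(segs) - 1 for segs in self.segments.values())

    def branch_durations(self) -> dict[Node, tuple[float, float]]:
        """Per-branch (time in state 0, time in state 1)."""
        out = {}
        for node, segs in self.segments.items():
            d0 = sum(d for s, d in segs if s == 0)
            d1 = sum(d for s, d in segs if s == 1)
            out[node] = (d0, d1)
        return out


def _transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    q = q01 + q10
    if q == 0 or t == 0:
        return np.eye(2)
    pi1 = q01 / q
    pi0 = q10 / q
    e = math.exp(-q * t)
    return np.array([
        [pi0 + pi1 * e, pi1 * (1 - e)],
        [pi0 * (1 - e), pi1 + pi0 * e],
    ])


def _root_prior_vec(root_prior, q01: float, q10: float) -> np.ndarray:
    if isinstance(root_prior, (tuple, list, np.ndarray)):
        p = np.asarray(root_prior, dtype=float)
        return p / p.sum()
    if root_prior == "flat":
        return np.array([0.5, 0.5])
    if root_prior == "stationary":
        q = q01 + q10
        if q == 0:
            return np.array([0.5, 0.5])
        return np.array([q10 / q, q01 / q])
    raise ValueError(f"unknown root prior {root_prior!r}")


def _tip_partial(state) -> np.ndarray:
    """Missing/ambiguous tip states get partial likelihood 1 in both states."""
    if state is None or (isinstance(state, float) and math.isnan(state)):
        return np.ones(2)
    s = int(state)
    if s not in (0, 1):
        raise ValueError(f"tip state must be 0/1/missing, got {state!r}")
    out = np.zeros(2)
    out[s] = 1.0
    return out


def _partials(tree: PhyloTree, tip_states: dict, q01: float, q10: float):
    """Pruning pass; returns (partials dict node -> (2,), log scaling)."""
    partial: dict[Node, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            partial[node] = _tip_partial(tip_states.get(node.label))
        else:
            lk = np.ones(2)
            for c in node.children:
                P = _transition_matrix(q01, q10, c.length or 0.0)
                lk = lk * (P @ partial[c])
            mx = lk.max()
            if mx <= 0:
                return None, -np.inf  # impossible data under these rates
            partial[node] = lk / mx
            log_scale += math.log(mx)
    return partial, log_scale


def mk_loglik(tree: PhyloTree, tip_states: dict, q01: float, q10: float,
              root_prior="flat") -> float:
    """Log-likelihood of the 2-state Mk model by pruning.

    ``tip_states`` maps tip labels to 0/1; missing labels (or NaN) are
    ambiguous and contribute partial likelihood 1.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("transition rates must be non-negative")
    partial, log_scale = _partials(tree, tip_states, q01, q10)
    if partial is None:
        return float(-np.inf)
    root = tree.postorder()[-1]
    prior = _root_prior_vec(root_prior, q01, q10)
    lk = float(prior @ partial[root])
    if lk <= 0:
        return float(-np.inf)
    return math.log(lk) + log_scale


def fit_mk_ard(tree: PhyloTree, tip_states: dict, root_prior="flat") -> MkFit:
    """Maximum-likelihood all-rates-different fit by bounded quasi-Newton
    search over log-rates from several starting points."""
    states = [v for v in (tip_states.get(t) for t in tree.tip_labels)
              if v is not None and not (isinstance(v, float) and math.isnan(v))]
    observed = set(int(s) for s in states)
    depth = max(tree.depths().values()) or 1.0
    if len(observed) < 2:
        # boundary: no variation, ML rates collapse to zero
        ll = mk_loglik(tree, tip_states, 0.0, 0.0, root_prior)
        return MkFit(0.0, 0.0, ll, root_prior if isinstance(root_prior, str)
                     else "fixed", converged=True, degenerate=True)

    def nll(logq):
        return -mk_loglik(tree, tip_states, math.exp(logq[0]),
                          math.exp(logq[1]), root_prior)

    base = math.log(1.0 / depth)
    starts = [(base, base), (base + 1.5, base - 1.5), (base - 1.5, base + 1.5),
              (base - 3, base - 3)]
    best = None
    ok = False
    bounds = [(base - 12, base + 8)] * 2
    for s0 in starts:
        res = minimize(nll, np.array(s0), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    q01, q10 = (float(math.exp(v)) for v in best.x)
    return MkFit(q01, q10, -float(best.fun),
                 root_prior if isinstance(root_prior, str) else "fixed",
                 converged=ok, degenerate=False)


# -- stochastic mapping -----------------------------------------------------

def _sample_branch_path(a: int, b: int, t: float, q01: float, q10: float,
                        rng: np.random.Generator, max_jumps: int = 10000,
                        ) -> list[tuple[int, float]]:
    """Exact conditional path a -> b over duration t by uniformization.

    Returns (state, duration) segments, collapsed so adjacent segments
    differ in state; first segment state == a, last == b.
    """
    Q = np.array([[-q01, q01], [q10, -q10]])
    omega = max(q01, q10)
    if omega == 0 or t == 0:
        if a != b:
            raise ValueError("endpoint change impossible with zero rates")
        return [(a, t)]
    R = np.eye(2) + Q / omega
    P_ab = _transition_matrix(q01, q10, t)[a, b]
    # sample number of virtual jumps N | endpoints
    u = rng.random() * P_ab
    pois_log = -omega * t
    Rpow = [np.eye(2)]
    acc = math.exp(pois_log) * (1.0 if a == b else 0.0)
    n = 0
    log_fact = 0.0
    while acc < u and n < max_jumps:
        n += 1
        log_fact += math.log(n)
        Rpow.append(Rpow[-1] @ R)
        term = math.exp(pois_log + n * math.log(omega * t) - log_fact)
        acc += term * Rpow[n][a, b]
    # sample the embedded chain states at the n jump times
    states = [a]
    for k in range(1, n):
        prev = states[-1]
        w = R[prev, :] * Rpow[n - k][:, b]
        w = w / w.sum()
        states.append(int(rng.random() < w[1]))
    if n >= 1:
        states.append(b)
    times = np.sort(rng.random(n)) * t
    # build segments, dropping virtual (self) jumps
    segs: list[tuple[int, float]] = []
    prev_time = 0.0
    cur = a
    for k in range(n):
        if states[k + 1] != cur:
            segs.append((cur, times[k] - prev_time))
            prev_time = float(times[k])
            cur = states[k + 1]
    segs.append((cur, t - prev_time))
    if cur != b:  # truncation guard; astronomically unlikely
        raise RuntimeError("uniformization failed to reach endpoint state")
    return segs


def sample_stochastic_map(tree: PhyloTree, tip_states: dict, fit: MkFit,
                          rng: np.random.Generator,
                          root_prior=None) -> StochasticMap:
    """Draw one stochastic map from the joint conditional distribution of
    histories given tips and fitted rates.

    Node states are sampled root-down (root from prior x partials, each
    child from P(t) weighted by its subtree partial), then each branch's
    internal history is filled in conditional on its endpoints by
    uniformization.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    q01, q10 = fit.q01, fit.q10
    prior_spec = root_prior if root_prior is not None else fit.root_prior
    partial, _ = _partials(tree, tip_states, q01, q10)
    if partial is None:
        raise ValueError("data impossible under the supplied rates")
    prior = _root_prior_vec(prior_spec, q01, q10)
    post = tree.postorder()
    root = post[-1]
    node_states: dict[Node, int] = {}
    w = prior * partial[root]
    w = w / w.sum()
    node_states[root] = int(rng.random() < w[1])
    segments: dict[Node, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        for c in node.children:
            P = _transition_matrix(q01, q10, c.length or 0.0)
            w = P[node_states[node], :] * partial[c]
            w = w / w.sum()
            s = int(rng.random() < w[1])
            node_states[c] = s
            segments[c] = _sample_branch_path(
                node_states[node], s, c.length or 0.0, q01, q10, rng)
    smap = StochasticMap(tree=tree, segments=segments, node_states=node_states)
    return smap


def expected_changes_conditional(a: int, b: int, t: float, q01: float,
                                 q10: float, tol: float = 1e-12) -> float:
    """Analytic conditional expectation of the number of true state changes
    on a branch of length t given endpoints a -> b, by uniformization
    series truncation.  Serves as the oracle for the path sampler."""
    Q = np.array([[-q01, q01], [q10, -q10]])
    omega = max(q01, q10)
    if omega == 0:
        return 0.0
    R = np.eye(2) + Q / omega
    P_ab = _transition_matrix(q01, q10, t)[a, b]
    total = 0.0
    pois = math.exp(-omega * t)
    Rpow = [np.eye(2)]
    n = 0
    while True:
        if n >= 1:
            # E[# real changes | n virtual jumps, a->b]
            num = 0.0
            for k in range(1, n + 1):
                for i in range(2):
                    j = 1 - i  # real change i -> j
                    num += Rpow[k - 1][a, i] * R[i, j] * Rpow[n - k][j, b]
            if Rpow[n][a, b] > 0:
                total += pois * num
        n += 1
        pois *= omega * t / n
        Rpow.append(Rpow[-1] @ R)
        if pois < tol and n > omega * t + 10:
            break
    return total / P_ab


# -- SIMMAP-style serialisation --------------------------------------------

def write_simmap(smap: StochasticMap, path: str | None = None) -> str:
    """Serialise a map in the SIMMAP annotated-Newick dialect: each branch
    is written as ``:{state,dur:state,dur:...}`` with segments ordered
    parent to child."""

    def render(node: Node) -> str:
        if node.is_tip:
            body = node.label.replace(" ", "_")
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        if node in smap.segments:
            segs = ":".join(f"{s},{d:.12g}" for s, d in smap.segments[node])
            body += ":{" + segs + "}"
        return body

    text = render(smap.tree.root) + ";\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_simmap(text: str) -> StochasticMap:
    """Parse the SIMMAP dialect written by :func:`write_simmap`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("simmap string must end with ';'")
    pos = 0

    def parse_node() -> tuple[Node, list]:
        nonlocal pos
        node = Node()
        entries = []
        if text[pos] == "(":
            pos += 1
            while True:
                child, sub = parse_node()
                node.add_child(child)
                entries.extend(sub)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^(),:;{}]*", text[pos:])
        label = m.group(0)
        pos += len(label)
        if label:
            node.label = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            if text[pos] != "{":
                raise ValueError(f"expected '{{' at position {pos}")
            end = text.index("}", pos)
            ann = text[pos + 1: end]
            pos = end + 1
            segs = []
            for part in ann.split(":"):
                state_s, dur_s = part.split(",")
                segs.append((int(state_s), float(dur_s)))
            node.length = sum(d for _, d in segs)
            entries.append((node, segs))
        return node, entries

    root, entries = parse_node()
    if text[pos] != ";":
        raise ValueError(f"trailing characters at position {pos}")
    tree = PhyloTree(root)
    segments = dict(entries)
    node_states = {n: segs[-1][0] for n, segs in segments.items()}
    node_states[root] = (segments[root.children[0]][0][0]
                         if root.children else 0)
    return StochasticMap(tree=tree, segments=segments, node_states=node_states)
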