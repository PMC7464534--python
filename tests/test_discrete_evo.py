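"""Mk model and stochastic mapping: pruning vs enumeration, ML fitting,
exact conditional path sampling, and SIMMAP serialisation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from msatphylo.phylo_core import read_newick
from msatphylo.discrete_evo import (mk_loglik, fit_mk_ard,
                                    sample_stochastic_map,
                                    expected_changes_conditional,
                                    _sample_branch_path, _transition_matrix,
                                    write_simmap, read_simmap, MkFit)
from msatphylo.synthetic_data import simulate_bd_tree, simulate_mk


def brute_force_loglik(tree, tip_states, q01, q10, prior=(0.5, 0.5)):
    """Sum over all 2^n_internal ancestral-state assignments."""
    post = tree.postorder()
    internal = [n for n in post if not n.is_tip]
    root = post[-1]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        st = dict(zip(internal, assign))
        lk = prior[st[root]]
        for n in post:
            if n is root:
                continue
            P = _transition_matrix(q01, q10, n.length or 0.0)
            s = tip_states[n.label] if n.is_tip else st[n]
            lk *= P[st[n.parent], s]
        total += lk
    return math.log(total)


def test_no_change_probability_closed_form():
    # symmetric rates q on one branch: P(same state) = (1 + e^{-2qt})/2
    q, t = 0.3, 1.7
    P = _transition_matrix(q, q, t)
    assert P[0, 0] == pytest.approx((1 + math.exp(-2 * q * t)) / 2)
    assert P[1, 1] == pytest.approx(P[0, 0])


def test_mk_loglik_limit_no_rates(cherry):
    # q -> 0 with both tips in state 0: likelihood -> prior of state 0
    ll = mk_loglik(cherry, {"A": 0, "B": 0}, 1e-12, 1e-12, "flat")
    assert ll == pytest.approx(math.log(0.5), abs=1e-6)


def test_mk_loglik_cherry_hand_enumeration(cherry):
    q = 0.5
    ll = mk_loglik(cherry, {"A": 0, "B": 1}, q, q, "flat")
    P = _transition_matrix(q, q, 1.0)
    by_hand = 0.5 * (P[0, 0] * P[0, 1] + P[1, 0] * P[1, 1])
    assert ll == pytest.approx(math.log(by_hand), abs=1e-12)


def test_mk_pruning_equals_enumeration():
    rng = np.random.default_rng(31)
    for _ in range(10):
        tree = simulate_bd_tree(int(rng.integers(4, 10)), 0.05, 0.0, rng)
        ts = {t: int(rng.integers(2)) for t in tree.tip_labels}
        q01, q10 = rng.uniform(0.001, 0.05, 2)
        assert mk_loglik(tree, ts, q01, q10) == pytest.approx(
            brute_force_loglik(tree, ts, q01, q10), abs=1e-10)


def test_mk_missing_states_are_ambiguous(bd_tree_64):
    rng = np.random.default_rng(32)
    ts, _ = simulate_mk(bd_tree_64, 0.01, 0.01, 0, rng)
    full = mk_loglik(bd_tree_64, ts, 0.01, 0.02)
    partial_states = dict(ts)
    dropped = bd_tree_64.tip_labels[0]
    del partial_states[dropped]
    part = mk_loglik(bd_tree_64, partial_states, 0.01, 0.02)
    assert part > full  # marginalising can only increase the likelihood


def test_fit_mk_symmetric_data():
    # mirrored tip states on a symmetric tree: fitted rates nearly equal
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")[0]
    fit = fit_mk_ard(tree, {"A": 0, "B": 1, "C": 1, "D": 0})
    assert fit.q01 == pytest.approx(fit.q10, rel=0.05)


def test_fit_mk_loglik_at_optimum_beats_truth(bd_tree_128):
    rng = np.random.default_rng(33)
    q01, q10 = 0.02, 0.005
    for _ in range(5):
        ts, _ = simulate_mk(bd_tree_128, q01, q10, 0, rng)
        if len(set(ts.values())) < 2:
            continue
        fit = fit_mk_ard(bd_tree_128, ts)
        ll_truth = mk_loglik(bd_tree_128, ts, q01, q10)
        assert fit.loglik >= ll_truth - 1e-6


def test_fit_mk_parameter_recovery():
    """Median ARD estimates within a factor of 2 of truth on 128-tip trees."""
    rng = np.random.default_rng(34)
    q01, q10 = 0.02, 0.005
    est01, est10 = [], []
    n_rep = 30
    tree = simulate_bd_tree(128, 0.05, 0.01, rng)
    for _ in range(n_rep):
        ts, _ = simulate_mk(tree, q01, q10, 0, rng)
        if len(set(ts.values())) < 2:
            continue
        fit = fit_mk_ard(tree, ts)
        est01.append(fit.q01)
        est10.append(fit.q10)
    assert q01 / 2 <= np.median(est01) <= q01 * 2
    assert q10 / 2 <= np.median(est10) <= q10 * 2


def test_fit_mk_degenerate_boundary(bd_tree_64):
    ts = {t: 0 for t in bd_tree_64.tip_labels}
    fit = fit_mk_ard(bd_tree_64, ts)
    assert fit.degenerate
    assert fit.q01 == 0.0 and fit.q10 == 0.0


def test_map_zero_rates_monomorphic(bd_tree_64):
    ts = {t: 0 for t in bd_tree_64.tip_labels}
    fit = MkFit(0.0, 0.0, 0.0)
    rng = np.random.default_rng(35)
    smap = sample_stochastic_map(bd_tree_64, ts, fit, rng)
    smap.validate()
    assert smap.n_changes() == 0
    assert smap.time_in_state(1) == 0.0


def test_sampled_map_invariants(bd_tree_64):
    rng = np.random.default_rng(36)
    ts, _ = simulate_mk(bd_tree_64, 0.01, 0.02, 0, rng)
    fit = fit_mk_ard(bd_tree_64, ts)
    for _ in range(5):
        smap = sample_stochastic_map(bd_tree_64, ts, fit, rng)
        smap.validate()
        # tip-adjacent segment states equal observed states
        for tip in bd_tree_64.tips():
            assert smap.segments[tip][-1][0] == ts[tip.label]


def test_branch_sampler_mean_changes_matches_analytic():
    q01, q10, t = 0.7, 0.4, 1.0
    rng = np.random.default_rng(37)
    n_draw = 20000
    for a, b in [(0, 0), (0, 1), (1, 1)]:
        counts = np.array([len(_sample_branch_path(a, b, t, q01, q10, rng)) - 1
                           for _ in range(n_draw)])
        analytic = expected_changes_conditional(a, b, t, q01, q10)
        se = counts.std() / math.sqrt(n_draw)
        assert abs(counts.mean() - analytic) < 4 * se + 1e-3


def _change_count_distribution(a, b, t, q01, q10, m_max, tol=1e-12):
    """P(# true changes = m | a -> b, t) by uniformization truncation,
    via dynamic programming over (state, change count)."""
    Q = np.array([[-q01, q01], [q10, -q10]])
    omega = max(q01, q10)
    R = np.eye(2) + Q / omega
    P_ab = _transition_matrix(q01, q10, t)[a, b]
    probs = np.zeros(m_max + 1)
    pois = math.exp(-omega * t)
    # dp[state, m]: probability of being in state with m real changes
    n = 0
    dp = np.zeros((2, m_max + 2))
    dp[a, 0] = 1.0
    while True:
        probs += pois * dp[b, :m_max + 1]
        n += 1
        pois *= omega * t / n
        new = np.zeros_like(dp)
        for s in range(2):
            new[s, :] += dp[s, :] * R[s, s]
            o = 1 - s
            new[o, 1:] += dp[s, :-1] * R[s, o]
        dp = new
        if pois < tol and n > omega * t + 10:
            break
    return probs / P_ab


def test_branch_sampler_distribution_chisquare():
    """Change-count distribution of the uniformization sampler matches the
    truncated analytic distribution (chi-square GOF at alpha = 0.01)."""
    q01, q10, t = 0.8, 0.5, 1.2
    a, b = 0, 0
    rng = np.random.default_rng(38)
    n_draw = 20000
    counts = np.array([len(_sample_branch_path(a, b, t, q01, q10, rng)) - 1
                       for _ in range(n_draw)])
    m_max = 8
    expected = _change_count_distribution(a, b, t, q01, q10, m_max)
    obs = np.bincount(np.minimum(counts, m_max), minlength=m_max + 1)
    exp = expected * n_draw
    exp[m_max] += n_draw * max(0.0, 1 - expected.sum())
    # pool rare bins (< 5 expected)
    keep = exp >= 5
    obs_p = np.append(obs[keep], obs[~keep].sum())
    exp_p = np.append(exp[keep], exp[~keep].sum())
    if exp_p[-1] == 0:
        obs_p, exp_p = obs_p[:-1], exp_p[:-1]
    chi2 = ((obs_p - exp_p) ** 2 / exp_p).sum()
    crit = stats.chi2.ppf(0.99, df=len(exp_p) - 1)
    assert chi2 < crit


def test_map_time_in_state_consistent_with_truth(bd_tree_64):
    """Posterior maps spend about as much time in state 1 as the true
    simulated histories do (MC agreement, not exactness)."""
    rng = np.random.default_rng(39)
    q01 = q10 = 0.01
    true_frac = []
    map_frac = []
    for _ in range(20):
        ts, true_map = simulate_mk(bd_tree_64, q01, q10, 0, rng)
        total = true_map.time_in_state(0) + true_map.time_in_state(1)
        true_frac.append(true_map.time_in_state(1) / total)
        fit = MkFit(q01, q10, 0.0)  # true rates; isolates the sampler
        smap = sample_stochastic_map(bd_tree_64, ts, fit, rng)
        map_frac.append(smap.time_in_state(1) / total)
    assert np.mean(map_frac) == pytest.approx(np.mean(true_frac), abs=0.12)


def test_simmap_round_trip(bd_tree_64):
    rng = np.random.default_rng(40)
    ts, smap = simulate_mk(bd_tree_64, 0.02, 0.01, 0, rng)
    text = write_simmap(smap)
    back = read_simmap(text)
    back.validate()
    assert back.tree.tip_labels == smap.tree.tip_labels
    assert back.n_changes() == smap.n_changes()
    assert back.time_in_state(1) == pytest.approx(smap.time_in_state(1),
                                                  rel=1e-9)


def test_negative_rates_rejected(cherry):
    with pytest.raises(ValueError):
        mk_loglik(cherry, {"A": 0, "B": 1}, -0.1, 0.1)
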