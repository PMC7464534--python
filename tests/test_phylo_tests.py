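"""Hypothesis-test procedures: phylogenetic ANOVA, censored two-rate test,
and PGLS — reductions to classical counterparts, nesting invariants, and
seeded reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msatphylo.phylo_core import read_newick
from msatphylo.bm_comparative import fit_bm
from msatphylo.phylo_tests import (phylo_anova, censored_rate_test,
                                   censored_over_maps, phylo_lm,
                                   lm_over_trees)
from msatphylo.synthetic_data import (simulate_bd_tree, simulate_bm,
                                      simulate_mk, simulate_bm_two_rate)


def _tipvals(sim):
    return {k: v for k, v in sim.items() if not k.startswith("node")}


def _star(n, length=1.0):
    return read_newick(
        "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");")[0]


# -- phylogenetic ANOVA -----------------------------------------------------

def test_anova_identical_groups_f_zero(bd_tree_64):
    labels = bd_tree_64.tip_labels
    groups = {t: ("a" if i % 2 else "b") for i, t in enumerate(labels)}
    # identical values within and between groups
    y = {t: 1.0 for t in labels}
    rng = np.random.default_rng(50)
    res = phylo_anova(bd_tree_64, y, groups, n_sim=99, rng=rng)
    assert res.f_obs == 0.0
    assert res.p_phylo == 1.0


def test_anova_small_group_rejected(bd_tree_64):
    labels = bd_tree_64.tip_labels
    groups = {t: "a" for t in labels}
    groups[labels[0]] = "solo"
    with pytest.raises(ValueError, match="solo"):
        phylo_anova(bd_tree_64, {t: 1.0 for t in labels}, groups,
                    rng=np.random.default_rng(0))


def test_anova_star_tree_matches_classical():
    """On a star tree BM tip values are i.i.d. normal, so the simulation
    p-value converges to the classical ANOVA p."""
    rng = np.random.default_rng(51)
    star = _star(40)
    y = dict(zip(star.tip_labels, rng.standard_normal(40)))
    groups = {t: f"g{i % 2}" for i, t in enumerate(star.tip_labels)}
    res = phylo_anova(star, y, groups, n_sim=5000, rng=rng)
    assert res.p_phylo == pytest.approx(res.p_standard, abs=0.02)


def test_anova_seeded_reproducibility(bd_tree_64):
    rng_a = np.random.default_rng(52)
    rng_b = np.random.default_rng(52)
    y = _tipvals(simulate_bm(bd_tree_64, 1.0, 0.0, np.random.default_rng(1)))
    groups = {t: f"g{i % 2}" for i, t in enumerate(bd_tree_64.tip_labels)}
    r1 = phylo_anova(bd_tree_64, y, groups, n_sim=100, rng=rng_a)
    r2 = phylo_anova(bd_tree_64, y, groups, n_sim=100, rng=rng_b)
    assert r1.p_phylo == r2.p_phylo and r1.f_obs == r2.f_obs


# -- censored two-rate test -------------------------------------------------

def test_censored_single_state_degenerate(bd_tree_64):
    rng = np.random.default_rng(53)
    ts, smap = simulate_mk(bd_tree_64, 0.0, 0.0, 0, rng)
    x = _tipvals(simulate_bm(bd_tree_64, 1.0, 0.0, rng))
    res = censored_rate_test(smap, x)
    assert res.degenerate
    assert res.lrt_stat == 0.0
    assert res.favored == "one_rate"
    assert res.sigma2_by_state[0] == res.sigma2_single


def test_censored_nesting_invariant(bd_tree_64):
    """Two-rate restricted loglik >= one-rate on every input."""
    rng = np.random.default_rng(54)
    for _ in range(10):
        ts, smap = simulate_mk(bd_tree_64, 0.01, 0.01, 0, rng)
        x = _tipvals(simulate_bm(bd_tree_64, 1.0, 0.0, rng))
        res = censored_rate_test(smap, x)
        assert res.loglik_two >= res.loglik_single - 1e-8
        assert res.lrt_stat >= 0.0


def test_censored_recovers_rate_ratio(bd_tree_128):
    rng = np.random.default_rng(55)
    ts, smap = simulate_mk(bd_tree_128, 0.01, 0.01, 0, rng)
    x = simulate_bm_two_rate(smap, (1.0, 10.0), 0.0, rng)
    res = censored_rate_test(smap, x)
    assert res.favored == "two_rate"
    assert res.sigma2_by_state[1] > res.sigma2_by_state[0]
    ratio = res.sigma2_by_state[1] / res.sigma2_by_state[0]
    assert 3 < ratio < 35


def test_censored_over_maps_tally(bd_tree_64):
    rng = np.random.default_rng(56)
    ts, smap = simulate_mk(bd_tree_64, 0.01, 0.01, 0, rng)
    x = simulate_bm_two_rate(smap, (1.0, 10.0), 0.0, rng)
    single = censored_rate_test(smap, x)
    summary = censored_over_maps([smap], x)
    assert summary["n_maps"] == 1
    assert summary["n_two_rate"] == (1 if single.favored == "two_rate" else 0)
    assert summary["results"][0].lrt_stat == single.lrt_stat
    # identical maps give identical per-map results
    rep = censored_over_maps([smap, smap, smap], x)
    stats_ = [r.lrt_stat for r in rep["results"]]
    assert stats_[0] == stats_[1] == stats_[2]


def test_censored_over_sampled_maps_power(bd_tree_128):
    """Maps sampled from a fitted Mk model (not the true history) still
    detect a 10x rate contrast in a clear majority of maps."""
    from msatphylo.discrete_evo import fit_mk_ard, sample_stochastic_map
    rng = np.random.default_rng(62)
    ts, true_map = simulate_mk(bd_tree_128, 0.01, 0.01, 0, rng)
    x = simulate_bm_two_rate(true_map, (1.0, 10.0), 0.0, rng)
    fit = fit_mk_ard(bd_tree_128, ts)
    maps = [sample_stochastic_map(bd_tree_128, ts, fit, rng)
            for _ in range(20)]
    summary = censored_over_maps(maps, x)
    assert summary["n_two_rate"] >= 16  # >= 80%
    assert summary["n_state1_higher"] >= 16


# -- phylogenetic linear models ---------------------------------------------

def test_phylo_lm_star_equals_ols():
    rng = np.random.default_rng(57)
    star = _star(50)
    x = rng.standard_normal(50)
    y = 2.0 + 0.5 * x + rng.standard_normal(50)
    X = pd.DataFrame({"x": x}, index=star.tip_labels)
    res = phylo_lm(star, dict(zip(star.tip_labels, y)), X, n_boot=10, rng=rng)
    ols = np.linalg.lstsq(np.column_stack([np.ones(50), x]), y, rcond=None)[0]
    assert np.allclose(res.coefficients, ols, atol=1e-8)
    # classical t-test comparison
    lr = stats.linregress(x, y)
    assert res.p_values[1] == pytest.approx(lr.pvalue, rel=1e-6)


def test_phylo_lm_intercept_only_is_gls_mean(bd_tree_64):
    rng = np.random.default_rng(58)
    y = _tipvals(simulate_bm(bd_tree_64, 1.0, 5.0, rng))
    res = phylo_lm(bd_tree_64, y, np.empty((64, 0)), n_boot=0)
    C, labels = bd_tree_64.vcv()
    yv = np.array([y[l] for l in labels])
    Ci = np.linalg.inv(C)
    one = np.ones(64)
    gls_mean = one @ Ci @ yv / (one @ Ci @ one)
    assert res.coefficients[0] == pytest.approx(gls_mean, abs=1e-8)
    # and it equals the BM root state
    assert res.coefficients[0] == pytest.approx(
        fit_bm(bd_tree_64, y).root_state, abs=1e-8)


def test_phylo_lm_rank_deficient(bd_tree_64):
    rng = np.random.default_rng(59)
    x = rng.standard_normal(64)
    X = pd.DataFrame({"a": x, "b": 2 * x}, index=bd_tree_64.tip_labels)
    y = {t: 0.0 for t in bd_tree_64.tip_labels}
    with pytest.raises(ValueError, match="rank"):
        phylo_lm(bd_tree_64, y, X, n_boot=0)


def test_phylo_lm_slope_recovery(bd_tree_64):
    """y = 2 + 0.5 x + BM noise: mean slope near truth over replicates."""
    rng = np.random.default_rng(60)
    C, labels = bd_tree_64.vcv()
    L = np.linalg.cholesky(C + 1e-10 * np.eye(64))
    x = rng.standard_normal(64) * 10
    X = pd.DataFrame({"x": x}, index=labels)
    slopes = []
    for _ in range(100):
        noise = L @ rng.standard_normal(64)
        y = dict(zip(labels, 2.0 + 0.5 * x + noise))
        res = phylo_lm(bd_tree_64, y, X, n_boot=0)
        slopes.append(res.coefficients[1])
    se = np.std(slopes) / math.sqrt(len(slopes))
    assert abs(np.mean(slopes) - 0.5) < 3 * se + 1e-3


def test_lm_over_trees_single_tree_and_tallies(bd_tree_64):
    rng = np.random.default_rng(61)
    x = rng.standard_normal(64)
    C, labels = bd_tree_64.vcv()
    L = np.linalg.cholesky(C + 1e-10 * np.eye(64))
    y = dict(zip(labels, 3.0 + 2.0 * x + 0.05 * (L @ rng.standard_normal(64))))
    X = pd.DataFrame({"x": x}, index=labels)
    single = phylo_lm(bd_tree_64, y, X, n_boot=10,
                      rng=np.random.default_rng(7))
    multi = lm_over_trees([bd_tree_64], y, X, n_boot=10,
                          rng=np.random.default_rng(7))
    assert multi["n_trees"] == 1
    assert multi["slopes"][0] == single.coefficients[1]
    # strong effect: every tree significant with a positive slope
    trees = [bd_tree_64] * 5
    res = lm_over_trees(trees, y, X, n_boot=10, rng=rng)
    assert res["n_significant"] == 5
    assert res["n_positive_slope"] == 5


def test_lm_over_trees_tip_mismatch(bd_tree_64):
    other = simulate_bd_tree(8, 0.05, 0.01, np.random.default_rng(99))
    y = {t: 1.0 for t in other.tip_labels}
    X = pd.DataFrame({"x": np.arange(8)}, index=other.tip_labels)
    with pytest.raises(ValueError, match="missing"):
        lm_over_trees([bd_tree_64], y, X, n_boot=0,
                      rng=np.random.default_rng(0))
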