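"""Ground-truth generators: distributional checks against closed forms and
structural invariants of everything they emit."""

import math

import numpy as np
import pytest

from msatphylo.phylo_core import read_newick, is_ultrametric
from msatphylo.discrete_evo import _transition_matrix
from msatphylo.msat_scan import ScanParams, scan_sequence, summarize_genome
from msatphylo.synthetic_data import (SimConfig, PlantSpec, simulate_bd_tree,
                                      perturb_node_ages, simulate_bm,
                                      simulate_bm_two_rate, simulate_mk,
                                      synth_genome, simulate_study,
                                      generate_genomes, _random_plant_specs)


def test_bd_tree_basic_invariants():
    rng = np.random.default_rng(70)
    t = simulate_bd_tree(3, 0.05, 0.01, rng)
    assert t.n_tips == 3
    assert sum(1 for n in t.postorder() if not n.is_tip) == 2
    assert is_ultrametric(t, 1e-8)
    for n in t.postorder():
        if n is not t.root:
            assert n.length > 0


def test_bd_tree_rejects_bad_rates():
    rng = np.random.default_rng(71)
    with pytest.raises(ValueError):
        simulate_bd_tree(5, 0.01, 0.02, rng)


def test_yule_growth_expectation():
    """Pure birth: the k-lineage phase lasts Exp(k b), so the expected root
    depth (first split to present, cut before the next event) is
    sum_{k=2}^{n-1} 1/(k b) + 1/(n b)."""
    rng = np.random.default_rng(72)
    b, n = 0.1, 8
    depths = []
    for _ in range(400):
        t = simulate_bd_tree(n, b, 0.0, rng)
        depths.append(max(t.depths().values()))
    expected = sum(1.0 / (k * b) for k in range(2, n)) + 1.0 / (n * b)
    se = np.std(depths) / math.sqrt(len(depths))
    assert abs(np.mean(depths) - expected) < 4 * se


def test_perturb_node_ages_posterior_like(bd_tree_64):
    """Age jitter keeps topology and ultrametricity, changes node depths,
    and keeps all branch lengths positive."""
    rng = np.random.default_rng(95)
    pert = perturb_node_ages(bd_tree_64, 0.1, rng)
    assert pert.tip_labels == bd_tree_64.tip_labels
    assert is_ultrametric(pert, 1e-6)
    for n in pert.postorder():
        if n is not pert.root:
            assert n.length > 0
    d0 = max(bd_tree_64.depths().values())
    d1 = max(pert.depths().values())
    assert d0 != d1  # jitter actually moved the root age


def test_simulate_bm_zero_rate(bd_tree_64):
    rng = np.random.default_rng(73)
    sim = simulate_bm(bd_tree_64, 0.0, 7.0, rng)
    assert all(v == 7.0 for v in sim.values())


def test_simulate_bm_cherry_variance(cherry):
    rng = np.random.default_rng(74)
    s2 = 2.5
    diffs = []
    for _ in range(5000):
        sim = simulate_bm(cherry, s2, 0.0, rng)
        diffs.append(sim["A"] - sim["B"])
    # Var(xA - xB) = 2 sigma2 t with t = 1
    assert np.var(diffs) == pytest.approx(2 * s2, rel=0.1)


def test_simulate_bm_covariance_matches_vcv():
    tree = read_newick("(((A:1,B:1):1,(C:1.5,D:0.5):0.5):1,(E:2,F:2):1);")[0]
    rng = np.random.default_rng(75)
    C, labels = tree.vcv()
    sims = [simulate_bm(tree, 1.0, 0.0, rng) for _ in range(5000)]
    draws = np.array([[s[l] for l in labels] for s in sims])
    emp = np.cov(draws.T)
    assert np.allclose(emp, C, atol=0.35)


def test_two_rate_equal_rates_matches_single(bd_tree_64):
    rng = np.random.default_rng(76)
    from msatphylo.synthetic_data import simulate_mk as smk
    _, smap = smk(bd_tree_64, 0.01, 0.01, 0, rng)
    tip = bd_tree_64.tip_labels[0]
    a = [simulate_bm_two_rate(smap, (2.0, 2.0), 0.0, rng)[tip]
         for _ in range(2000)]
    b = [simulate_bm(bd_tree_64, 2.0, 0.0, rng)[tip] for _ in range(2000)]
    from scipy.stats import ks_2samp
    assert ks_2samp(a, b).pvalue > 0.001


def test_two_rate_zero_state_accrues_nothing(bd_tree_64):
    rng = np.random.default_rng(77)
    _, smap = simulate_mk(bd_tree_64, 0.0, 0.0, 1, rng)  # all state 1
    sim = simulate_bm_two_rate(smap, (5.0, 0.0), 3.0, rng)
    assert all(v == 3.0 for v in sim.values())


def test_mixed_branch_variance_closed_form():
    """Variance over a branch equals the segment-weighted rate sum."""
    tree = read_newick("(A:4,B:4);")[0]
    rng = np.random.default_rng(78)
    from msatphylo.discrete_evo import StochasticMap
    tipA, tipB = tree.tips()
    segments = {tipA: [(0, 1.0), (1, 3.0)], tipB: [(0, 4.0)]}
    node_states = {tree.root: 0, tipA: 1, tipB: 0}
    smap = StochasticMap(tree, segments, node_states)
    smap.validate()
    s2 = (2.0, 6.0)
    draws = np.array([simulate_bm_two_rate(smap, s2, 0.0, rng)["A"]
                      for _ in range(5000)])
    expected_var = 2.0 * 1.0 + 6.0 * 3.0
    assert np.var(draws) == pytest.approx(expected_var, rel=0.1)


def test_simulate_mk_zero_rates(bd_tree_64):
    rng = np.random.default_rng(79)
    ts, smap = simulate_mk(bd_tree_64, 0.0, 0.0, 1, rng)
    assert set(ts.values()) == {1}
    assert smap.n_changes() == 0
    smap.validate()


def test_simulate_mk_single_branch_transition_probability():
    tree = read_newick("(A:10,B:10);")[0]
    q01, q10 = 0.08, 0.05
    rng = np.random.default_rng(80)
    flips = [simulate_mk(tree, q01, q10, 0, rng)[0]["A"] for _ in range(20000)]
    p_change = _transition_matrix(q01, q10, 10.0)[0, 1]
    se = math.sqrt(p_change * (1 - p_change) / 20000)
    assert abs(np.mean(flips) - p_change) < 4 * se


def test_simulate_mk_stationary_frequency():
    rng = np.random.default_rng(81)
    q01, q10 = 0.05, 0.02
    tree = simulate_bd_tree(100, 0.02, 0.0, rng)
    fracs = []
    for _ in range(20):
        ts, _ = simulate_mk(tree, q01, q10, 0, rng)
        fracs.append(np.mean(list(ts.values())))
    assert np.mean(fracs) == pytest.approx(q01 / (q01 + q10), abs=0.12)


def test_synth_genome_consistency_and_plants():
    rng = np.random.default_rng(82)
    # zero plants: scanner equals oracle truth by construction
    fasta, truth, placements = synth_genome(2000, [], 0.5, rng)
    seq = "".join(fasta.split("\n")[1:])
    assert scan_sequence("chr1", seq) == truth
    assert placements == []
    # one (AC)8 plant: a period-2 locus of >= 16 bp at the planted site
    fasta, truth, placements = synth_genome(
        2000, [PlantSpec("AC", 8)], 0.5, rng)
    seq = "".join(fasta.split("\n")[1:])
    (start, spec) = placements[0]
    hits = [l for l in truth if l.period == 2 and l.start == start]
    assert hits and hits[0].end - hits[0].start >= 16
    assert scan_sequence("chr1", seq) == truth


def test_synth_genome_many_plants_oracle_identity():
    rng = np.random.default_rng(83)
    params = ScanParams()
    specs = _random_plant_specs(30, rng, params)
    fasta, truth, placements = synth_genome(100_000, specs, 0.4, rng,
                                            params=params)
    seq = "".join(fasta.split("\n")[1:])
    loci = scan_sequence("chr1", seq, params)
    assert loci == truth
    # every at-threshold plant is recovered exactly at its coordinates
    for start, spec in placements:
        p = len(spec.motif)
        if spec.copies >= params.min_copies_by_period[p]:
            match = [l for l in truth
                     if l.start == start and l.period == p
                     and l.end == start + p * spec.copies]
            assert match, f"plant at {start} ({spec}) not recovered exactly"
        else:
            assert not any(l.start == start and l.period == p for l in truth)
    # totals flow through the per-genome summary
    prof = summarize_genome("sp", loci, len(seq))
    assert prof.total_bp == sum(l.end - l.start for l in truth)


def test_synth_genome_overlap_error():
    rng = np.random.default_rng(84)
    with pytest.raises(ValueError):
        synth_genome(100, [PlantSpec("ACG", 20)] * 3, 0.5, rng)


def test_simulate_study_deterministic_and_complete():
    config = SimConfig(n_taxa=24, n_trees=3, n_low_busco=3, seed=5)
    s1 = simulate_study(config)
    s2 = simulate_study(config)
    assert s1.traits.equals(s2.traits)
    assert len(s1.trees) == 3
    from msatphylo.phylo_core import write_newick
    assert write_newick(s1.trees) == write_newick(s2.trees)
    # structural expectations
    assert set(s1.traits.columns) >= {
        "species", "content_per_mbp", "total_bp", "centromere_type",
        "chromosome_number", "genome_size_mbp", "busco_score", "order_label"}
    assert (s1.traits["busco_score"] < 0.90).sum() == 3
    assert set(s1.traits["species"]) == set(s1.trees[0].tip_labels)
    s1.true_map.validate()
    # content is positive and centromere states match the true history
    assert (s1.traits["content_per_mbp"] > 0).all()
    mono = s1.traits.set_index("species")["centromere_type"] == "monocentric"
    for sp, is_mono in mono.items():
        assert s1.tip_states[sp] == int(is_mono)


def test_generate_genomes_scan_matches_truth():
    config = SimConfig(n_taxa=6, n_trees=1, genome_length=30_000,
                       n_low_busco=1, seed=9)
    study = simulate_study(config)
    generate_genomes(study, config)
    assert set(study.genomes) == set(study.traits["species"])
    for sp, fasta in study.genomes.items():
        seq = "".join(fasta.split("\n")[1:])
        loci = scan_sequence(sp, seq)
        assert loci == study.truth_loci[sp]
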