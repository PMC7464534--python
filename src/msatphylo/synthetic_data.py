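"""Synthetic study generator: birth-death trees, BM traits (single- and
two-rate), Mk histories, and genomes with planted perfect repeats.

Every generator takes an explicit numpy Generator and is deterministic
given (parameters, seed).  Genome truth tables are defined by running the
brute-force oracle scanner over the finished sequence, so repeats arising
spontaneously in the background (or fusing with a planted repeat) are
part of the ground truth rather than noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core import PhyloTree, Node, is_ultrametric, normalize_label
from .discrete_evo import StochasticMap
from .msat_scan import ScanParams, RepeatLocus, oracle_scan_sequence

__all__ = ["SimConfig", "simulate_bd_tree", "perturb_node_ages",
           "simulate_bm", "simulate_bm_two_rate", "simulate_mk",
           "synth_genome", "simulate_study", "StudyData"]


@dataclass
class SimConfig:
    """Study-scale simulation parameters.

    Defaults emulate the shape of the real study at desk scale: an
    ultrametric insect-like phylogeny a few hundred My deep, a slowly
    switching binary centromere character, microsatellite content evolving
    by BM with a monocentric/holocentric rate contrast, and small
    assemblies with planted repeats.
    """

    n_taxa: int = 64
    birth: float = 0.03          # lineages per My
    death: float = 0.01
    sigma2: float = 1.0          # single-rate BM, (trait units)^2 / My
    sigma2_by_state: tuple[float, float] = (1.0, 10.0)  # (holo, mono)
    q01: float = 0.01            # holocentric -> monocentric per My
    q10: float = 0.01
    genome_length: int = 200_000
    gc_content: float = 0.38     # insect-like AT-rich background
    n_planted: int = 40
    content_slope_genome_size: float = 0.0  # bp/Mbp content per Mbp size
    n_trees: int = 10
    n_low_busco: int = 4
    seed: int = 0

    def __post_init__(self):
        assert self.n_taxa >= 3
        assert self.birth > self.death >= 0
        assert 0 < self.gc_content < 1
        assert all(r >= 0 for r in (self.sigma2, self.q01, self.q10))


# -- trees ------------------------------------------------------------------

def simulate_bd_tree(n_taxa: int, birth: float, death: float,
                     rng: np.random.Generator,
                     label_fmt: str = "t{}") -> PhyloTree:
    """Ultrametric birth-death tree with ``n_taxa`` extant tips.

    Forward Gillespie simulation from a single lineage, restarted on total
    extinction; the process stops the instant the n-th lineage appears, so
    the tree is conditioned on reaching n survivors (rejection-style, not
    the exactly conditioned process).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if death >= birth:
        raise ValueError("birth rate must exceed death rate")
    while True:
        # each living lineage: (birth_time, parent_record_index)
        # records: (parent_idx, start_time, end_time or None, children idx)
        parents: list[int] = [-1]
        starts: list[float] = [0.0]
        ends: list[float | None] = [None]
        alive = [0]
        t = 0.0
        while alive and len(alive) < n_taxa:
            total = len(alive) * (birth + death)
            t += rng.exponential(1.0 / total)
            k = alive[rng.integers(len(alive))]
            if rng.random() < birth / (birth + death):
                for _ in range(2):
                    parents.append(k)
                    starts.append(t)
                    ends.append(None)
                    alive.append(len(parents) - 1)
                ends[k] = t
                alive.remove(k)
            else:
                ends[k] = t
                alive.remove(k)
        if not alive:
            continue  # clade died; rerun
        # advance to just before the next event so the newborn pair gets a
        # positive terminal branch; the process is cut there ("present")
        t += rng.exponential(1.0 / (len(alive) * (birth + death)))
        for k in alive:
            ends[k] = t
        # build node objects for the reconstructed (extant-only) tree
        n_rec = len(parents)
        children: list[list[int]] = [[] for _ in range(n_rec)]
        for i, p in enumerate(parents):
            if p >= 0:
                children[p].append(i)
        extant = set(alive)

        def build(i: int) -> Node | None:
            if not children[i]:
                if i not in extant:
                    return None
                return Node(None, ends[i] - starts[i])
            subs = [build(c) for c in children[i]]
            subs = [s for s in subs if s is not None]
            if not subs:
                return None
            if len(subs) == 1:
                only = subs[0]
                only.length = (only.length or 0.0) + (ends[i] - starts[i])
                return only
            node = Node(None, ends[i] - starts[i])
            for s in subs:
                node.add_child(s)
            return node

        root = build(0)
        if root is None or root.is_tip:
            continue
        root.length = None
        # label tips before constructing the validated tree
        tips: list[Node] = []
        stack = [root]
        while stack:
            nd = stack.pop()
            if nd.is_tip:
                tips.append(nd)
            stack.extend(reversed(nd.children))
        if len(tips) != n_taxa:
            continue
        for i, tip in enumerate(tips):
            tip.label = label_fmt.format(i + 1)
        tree = PhyloTree(root)
        assert is_ultrametric(tree, 1e-8)
        return tree


def perturb_node_ages(tree: PhyloTree, rel_sd: float,
                      rng: np.random.Generator) -> PhyloTree:
    """A posterior-like variant of an ultrametric tree: same topology, each
    internal node's age jittered by a lognormal factor exp(N(0, rel_sd^2)),
    constrained so every parent stays older than its children.  Tips remain
    at the present, so the result is ultrametric."""
    work = tree.copy()
    depths = work.depths()
    max_depth = max(depths[t] for t in work.tips())
    new_age: dict[Node, float] = {}
    for node in work.postorder():
        if node.is_tip:
            new_age[node] = 0.0
            continue
        age = max_depth - depths[node]
        jittered = age * math.exp(rng.normal(0.0, rel_sd))
        floor = max(new_age[c] for c in node.children) + 1e-6 * max_depth
        new_age[node] = max(jittered, floor)
    for node in work.postorder():
        if node is not work.root:
            node.length = new_age[node.parent] - new_age[node]
    work.invalidate()
    return PhyloTree(work.root)


# -- continuous traits ------------------------------------------------------

def simulate_bm(tree: PhyloTree, sigma2: float, root_value: float,
                rng: np.random.Generator) -> dict[str, float]:
    """Simulate BM along the tree; returns values for every node (tips
    keyed by label, internal nodes by postorder id)."""
    values: dict[Node, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            values[node] = root_value
        else:
            sd = math.sqrt(sigma2 * (node.length or 0.0))
            values[node] = values[node.parent] + rng.standard_normal() * sd
    out: dict[str, float] = {}
    for node in tree.postorder():
        key = node.label if node.is_tip else f"node{node.id}"
        out[key] = values[node]
    return out


def simulate_bm_two_rate(smap: StochasticMap, sigma2_by_state,
                         root_value: float, rng: np.random.Generator,
                         ) -> dict[str, float]:
    """BM with state-dependent rates: each branch accrues variance
    sum(sigma2[state] * duration) over the map's segments."""
    s2 = dict(enumerate(sigma2_by_state)) if not isinstance(
        sigma2_by_state, dict) else sigma2_by_state
    tree = smap.tree
    values: dict[Node, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            values[node] = root_value
        else:
            var = sum(s2[s] * d for s, d in smap.segments[node])
            values[node] = values[node.parent] + \
                rng.standard_normal() * math.sqrt(var)
    return {t.label: values[t] for t in tree.tips()}


# -- discrete trait ---------------------------------------------------------

def simulate_mk(tree: PhyloTree, q01: float, q10: float, root_state: int,
                rng: np.random.Generator) -> tuple[dict[str, int], StochasticMap]:
    """Exact Gillespie simulation of the 2-state Markov chain along every
    branch.  Returns tip states and the true history as a StochasticMap."""
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rates = {0: q01, 1: q10}
    node_states: dict[Node, int] = {}
    segments: dict[Node, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        if node is tree.root:
            node_states[node] = int(root_state)
            continue
        state = node_states[node.parent]
        remaining = node.length or 0.0
        segs: list[tuple[int, float]] = []
        elapsed_in_state = 0.0
        while True:
            rate = rates[state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if wait >= remaining:
                segs.append((state, elapsed_in_state + remaining))
                break
            segs.append((state, elapsed_in_state + wait))
            remaining -= wait
            elapsed_in_state = 0.0
            state = 1 - state
        segments[node] = segs
        node_states[node] = state
    smap = StochasticMap(tree=tree, segments=segments,
                         node_states=node_states)
    tip_states = {t.label: node_states[t] for t in tree.tips()}
    return tip_states, smap


# -- genomes ----------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    motif: str
    copies: int


def _random_plant_specs(n: int, rng: np.random.Generator,
                        params: ScanParams) -> list[PlantSpec]:
    """Random motifs/copy numbers; roughly 80% at or above threshold and
    the rest deliberately sub-threshold."""
    specs = []
    periods = sorted(params.periods)
    for _ in range(n):
        p = periods[rng.integers(len(periods))]
        while True:
            motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=p))
            if _primitive(motif):
                break
        minc = params.min_copies_by_period[p]
        if rng.random() < 0.8:
            copies = int(minc + rng.integers(0, 10))
        else:
            copies = int(max(2, minc - 1))
        specs.append(PlantSpec(motif=motif, copies=copies))
    return specs


def _primitive(motif: str) -> bool:
    p = len(motif)
    return not any(motif == motif[:d] * (p // d)
                   for d in range(1, p) if p % d == 0)


def synth_genome(length: int, planted: list[PlantSpec], gc: float,
                 rng: np.random.Generator, sequence_id: str = "chr1",
                 params: ScanParams | None = None,
                 ) -> tuple[str, list[RepeatLocus], list[tuple[int, PlantSpec]]]:
    """A single-record genome: i.i.d. background with the given GC content
    plus planted perfect repeats at recorded, non-overlapping positions.

    Returns (fasta_text, truth_loci, placements).  The truth table is the
    oracle scan of the finished sequence, so it captures background
    repeats and any interaction with plant edges exactly.  Each plant's
    periodic continuation is broken at both flanks so the planted run is
    maximal at exactly the recorded coordinates.
    """
    if params is None:
        params = ScanParams()
    p_bases = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = np.array(list("ACGT"))[rng.choice(4, size=length, p=p_bases)]
    total_plant = sum(len(s.motif) * s.copies for s in planted)
    if total_plant > length:
        raise ValueError("planted repeats exceed genome length")
    taken: list[tuple[int, int]] = []
    placements: list[tuple[int, PlantSpec]] = []
    for spec in sorted(planted, key=lambda s: -len(s.motif) * s.copies):
        size = len(spec.motif) * spec.copies
        placed = False
        for _ in range(2000):
            start = int(rng.integers(1, length - size))
            end = start + size
            # margin keeps plants from abutting or fusing with each other
            if all(end + 12 <= a or b + 12 <= start for a, b in taken):
                taken.append((start, end))
                placements.append((start, spec))
                seq[start:end] = list(spec.motif * spec.copies)
                p = len(spec.motif)
                # break the periodic continuation at both flanks
                if seq[start - 1] == seq[start - 1 + p]:
                    seq[start - 1] = _other_base(seq[start - 1], rng)
                if end + 0 < length and seq[end] == seq[end - p]:
                    seq[end] = _other_base(seq[end], rng)
                placed = True
                break
        if not placed:
            raise ValueError("could not place planted repeats without overlap")
    text = "".join(seq)
    truth = oracle_scan_sequence(sequence_id, text, params)
    fasta = f">{sequence_id}\n" + "\n".join(
        text[i:i + 70] for i in range(0, length, 70)) + "\n"
    return fasta, truth, sorted(placements, key=lambda t: t[0])


def _other_base(base: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != base]
    return options[rng.integers(3)]


# -- whole study ------------------------------------------------------------

@dataclass
class StudyData:
    trees: list[PhyloTree]
    traits: pd.DataFrame
    true_map: StochasticMap
    tip_states: dict[str, int]
    genomes: dict[str, str] = field(default_factory=dict)  # species -> fasta
    truth_loci: dict[str, list[RepeatLocus]] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def _assign_orders(tree: PhyloTree, min_size: int = 8) -> dict[str, str]:
    """Carve the tree into contiguous clades of at least ``min_size`` tips
    and label them order_1, order_2, ... (a stand-in for taxonomic orders)."""
    labels: dict[str, str] = {}
    counter = [0]

    # greedy: postorder, emit a clade once it reaches min_size
    def carve(node: Node) -> list[str]:
        if node.is_tip:
            return [node.label]
        pend: list[str] = []
        for c in node.children:
            pend.extend(carve(c))
        if len(pend) >= min_size and node is not tree.root:
            counter[0] += 1
            name = f"order_{counter[0]}"
            for t in pend:
                labels[t] = name
            return []
        return pend

    leftovers = carve(tree.root)
    counter[0] += 1
    for t in leftovers:
        labels[t] = f"order_{counter[0]}"
    return labels


def simulate_study(config: SimConfig) -> StudyData:
    """Generate the full synthetic study: a posterior-like tree set, a
    trait table (content, centromere state, chromosome number, genome
    size, BUSCO score, order label), the true centromere history, and
    optionally small genomes whose planted microsatellite content matches
    the simulated trait.

    Microsatellite content per Mbp evolves by state-dependent BM on the
    first ("true") tree with an optional linear dependence on genome size;
    the remaining trees are age-jittered variants of it, emulating a
    Bayesian posterior sample (correlated trees, shared topology).
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_bd_tree(config.n_taxa, config.birth, config.death, rng)
    # posterior-like tree set: shared topology, jittered divergence times
    trees = [tree] + [perturb_node_ages(tree, 0.1, rng)
                      for _ in range(config.n_trees - 1)]
    species = tree.tip_labels

    tip_states, true_map = simulate_mk(tree, config.q01, config.q10,
                                       root_state=0, rng=rng)
    base_content = 2000.0  # bp/Mbp at the root; keeps content positive
    content = simulate_bm_two_rate(true_map, config.sigma2_by_state,
                                   base_content, rng)

    # genome sizes: lognormal BM around ~400 Mbp, insect-like spread
    log_gs = simulate_bm(tree, sigma2=2e-4, root_value=math.log(400.0),
                         rng=rng)
    genome_size = {s: math.exp(log_gs[s]) for s in species}
    if config.content_slope_genome_size:
        for s in species:
            content[s] += config.content_slope_genome_size * \
                (genome_size[s] - 400.0)
    content = {s: max(v, 50.0) for s, v in content.items()}

    # chromosome number is phylogenetically conserved: BM on the haploid
    # count, rounded and clipped to a plausible insect range
    chrom_bm = simulate_bm(tree, sigma2=0.05, root_value=14.0, rng=rng)
    chrom = {s: int(2 * min(max(round(chrom_bm[s]), 3), 60))
             for s in species}
    busco = {s: float(np.clip(rng.normal(0.965, 0.02), 0.5, 1.0))
             for s in species}
    low = rng.choice(len(species), size=config.n_low_busco, replace=False)
    for i in low:
        busco[species[i]] = float(rng.uniform(0.3, 0.899))
    orders = _assign_orders(tree)

    traits = pd.DataFrame({
        "species": species,
        "content_per_mbp": [content[s] for s in species],
        "total_bp": [content[s] * genome_size[s] for s in species],
        "centromere_type": ["monocentric" if tip_states[s] else "holocentric"
                            for s in species],
        "chromosome_number": [chrom[s] for s in species],
        "genome_size_mbp": [genome_size[s] for s in species],
        "busco_score": [busco[s] for s in species],
        "order_label": [orders[s] for s in species],
    })

    truth = {
        "config": config,
        "tip_states": tip_states,
        "content": content,
        "genome_size": genome_size,
        "low_busco_species": [species[i] for i in low],
    }
    return StudyData(trees=trees, traits=traits, true_map=true_map,
                     tip_states=tip_states, truth=truth)


def generate_genomes(study: StudyData, config: SimConfig,
                     rng: np.random.Generator | None = None,
                     params: ScanParams | None = None) -> None:
    """Attach small FASTA genomes to a study: each species gets a genome of
    ``config.genome_length`` bp whose planted repeat content approximates
    its simulated content_per_mbp (scaled to the toy genome length).
    Truth tables come from the oracle scanner."""
    if params is None:
        params = ScanParams()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    for _, row in study.traits.iterrows():
        target_bp = row.content_per_mbp * (L / 1e6)
        specs: list[PlantSpec] = []
        acc = 0.0
        while acc < target_bp:
            p = int(rng.integers(2, 7))
            while True:
                motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=p))
                if _primitive(motif):
                    break
            copies = int(params.min_copies_by_period[p] + rng.integers(0, 8))
            specs.append(PlantSpec(motif=motif, copies=copies))
            acc += p * copies
        fasta, truth, _ = synth_genome(L, specs, config.gc_content, rng,
                                       sequence_id=row.species, params=params)
        study.genomes[row.species] = fasta
        study.truth_loci[row.species] = truth
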