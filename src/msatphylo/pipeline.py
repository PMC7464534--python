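"""End-to-end study orchestration: scan genomes, apply the assembly-quality
filter, join traits to the tree set, and run every comparative analysis.

The study design mirrors a comparative survey of microsatellite content:
genomes are profiled, assemblies with BUSCO completeness below 0.90 are
discarded, Brownian-motion rates are fit globally and per order on
content per Mbp, tip rates are computed on total bp, centromere type is
tested by phylogenetic ANOVA and by a censored two-rate test over
stochastic maps, and chromosome number and genome size are tested as
predictors with phylogenetic linear models across the tree set.

Randomness: every stage draws from a named child of the master seed
(`numpy.random.SeedSequence.spawn`), so reruns with the same config are
bit-identical and stages are insensitive to each other's draw counts.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import msat_scan
from .phylo_core import PhyloTree, prune_to, read_newick, read_trait_table, \
    normalize_label
from .bm_comparative import fit_bm, tip_rates, rates_by_group
from .discrete_evo import fit_mk_ard, sample_stochastic_map
from .phylo_tests import (phylo_anova, censored_over_maps, lm_over_trees)

logger = logging.getLogger("msatphylo")

__all__ = ["StudyConfig", "filter_assemblies", "run_study"]

_STAGES = ["scan", "anova", "maps", "censored", "lm"]


@dataclass
class StudyConfig:
    """Configuration for a full study run (paths may be None when the
    corresponding inputs are passed in memory)."""

    fasta_dir: str | None = None
    newick_file: str | None = None
    trait_file: str | None = None
    output_dir: str = "msatphylo_out"
    busco_min: float = 0.90
    min_group_n: int = 10
    n_sim: int = 100
    n_maps: int = 100
    n_boot: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        assert 0 <= self.busco_min <= 1
        assert 0 < self.alpha < 1
        for k in ("min_group_n", "n_sim", "n_maps", "n_boot"):
            assert getattr(self, k) >= 1, f"{k} must be >= 1"

    def stage_rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: np.random.default_rng(c)
                for name, c in zip(_STAGES, children)}


def filter_assemblies(traits: pd.DataFrame, busco_min: float = 0.90,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain records with busco_score >= busco_min (boundary inclusive);
    records without a score are discarded with a logged reason."""
    has_score = traits["busco_score"].notna()
    keep = has_score & (traits["busco_score"] >= busco_min)
    retained = traits[keep].reset_index(drop=True)
    discarded = traits[~keep].reset_index(drop=True)
    n_unscored = int((~has_score).sum())
    if n_unscored:
        logger.info("discarded %d records with no BUSCO score", n_unscored)
    logger.info("BUSCO filter (>= %.2f): retained %d, discarded %d",
                busco_min, len(retained), len(discarded))
    return retained, discarded


def _complete_subset(tree: PhyloTree, traits: pd.DataFrame,
                     columns: list[str]) -> tuple[PhyloTree, pd.DataFrame]:
    """Prune tree and table to species with complete data in ``columns``;
    species missing a field are excluded only from analyses needing it."""
    ok = traits.dropna(subset=columns)
    tips = set(tree.tip_labels)
    keep = [s for s in ok["species"] if s in tips]
    dropped = len(tips) - len(keep)
    if dropped:
        logger.info("dropping %d species without complete %s", dropped, columns)
    sub = prune_to(tree, keep) if len(keep) < len(tips) else tree
    return sub, ok[ok["species"].isin(keep)].set_index("species")


def run_study(config: StudyConfig,
              trees: list[PhyloTree] | None = None,
              traits: pd.DataFrame | None = None,
              genomes: dict[str, str] | None = None) -> dict:
    """Run the whole study; returns the report dict (also written to
    ``output_dir/report.json`` when output_dir is set).

    Inputs may be given in memory (``trees``, ``traits``, and optionally
    ``genomes`` as species -> FASTA text) or via the config paths.
    """
    rngs = config.stage_rngs()
    report: dict = {"config": {k: v for k, v in asdict(config).items()},
                    "stages": {}}

    # ---- load inputs ----
    if trees is None:
        if not config.newick_file:
            raise ValueError("stage load: no trees supplied")
        trees = read_newick(config.newick_file)
    if traits is None:
        if config.trait_file:
            traits = read_trait_table(config.trait_file)
        elif genomes is None and config.fasta_dir is None:
            raise ValueError("stage load: no traits or genomes supplied")

    # ---- stage 1: scan genomes ----
    profiles: list[msat_scan.GenomeMsatProfile] = []
    loci_tables: dict[str, list] = {}
    if genomes or config.fasta_dir:
        params = msat_scan.ScanParams()
        if genomes:
            items = sorted(genomes.items())
        else:
            files = sorted(f for f in os.listdir(config.fasta_dir)
                           if f.endswith((".fa", ".fasta", ".fa.gz",
                                          ".fasta.gz")))
            items = [(f.split(".")[0], os.path.join(config.fasta_dir, f))
                     for f in files]
        for species, src in items:
            try:
                if genomes:
                    total = 0
                    loci = []
                    # in-memory fasta text
                    for rec_id, seq in _iter_fasta_text(src):
                        total += len(seq)
                        loci.extend(msat_scan.scan_sequence(rec_id, seq, params))
                    prof = msat_scan.summarize_genome(species, loci, total)
                else:
                    prof, loci = msat_scan.scan_fasta(src, params, species)
            except Exception as exc:
                raise RuntimeError(
                    f"stage scan failed for species {species!r}: {exc}") from exc
            profiles.append(prof)
            loci_tables[species] = msat_scan.loci_to_rows(loci)
        scanned = pd.DataFrame(
            [msat_scan.profile_to_row(p) for p in profiles],
            columns=msat_scan.PROFILE_COLUMNS)
        scanned["species"] = scanned["species"].map(normalize_label)
        if traits is not None:
            dup = [c for c in scanned.columns
                   if c != "species" and c in traits.columns]
            traits = traits.drop(columns=dup).merge(scanned, on="species",
                                                    how="left")
        else:
            traits = scanned
        report["stages"]["scan"] = {"n_genomes": len(profiles)}
    if traits is None:
        raise ValueError("stage load: no trait data available")

    # ---- stage 2: quality filter ----
    if "busco_score" in traits.columns:
        retained, discarded = filter_assemblies(traits, config.busco_min)
    else:
        retained, discarded = traits, traits.iloc[0:0]
    report["stages"]["filter"] = {
        "n_retained": len(retained), "n_discarded": len(discarded),
        "discarded_species": discarded["species"].tolist(),
    }

    # restrict the tree set to retained species
    kept_species = [s for s in trees[0].tip_labels
                    if s in set(retained["species"])]
    if len(kept_species) < 3:
        raise RuntimeError("stage filter: fewer than 3 species retained")
    pruned_trees = []
    for i, t in enumerate(trees):
        missing = set(kept_species) - set(t.tip_labels)
        if missing:
            raise RuntimeError(
                f"stage trees: tree {i} lacks species {sorted(missing)}")
        pruned_trees.append(prune_to(t, kept_species)
                            if set(t.tip_labels) != set(kept_species) else t)
    tree = pruned_trees[0]
    tab = retained.set_index("species")

    # ---- stage 3: BM rates ----
    content = tab.loc[kept_species, "content_per_mbp"].to_dict()
    total_bp = tab.loc[kept_species, "total_bp"].to_dict()
    global_fit = fit_bm(tree, content, method="REML",
                        units="(bp/Mbp)^2 per My")
    order_fits = {}
    if "order_label" in tab.columns:
        order_fits = rates_by_group(
            tree, content, tab.loc[kept_species, "order_label"].to_dict(),
            min_n=config.min_group_n, units="(bp/Mbp)^2 per My")
    rates = tip_rates(tree, total_bp)
    report["stages"]["bm"] = {
        "global_sigma2": global_fit.sigma2,
        "global_loglik": global_fit.loglik,
        "order_sigma2": {g: f.sigma2 for g, f in order_fits.items()},
        "tip_rates": {r.species: r.rate for r in rates},
        "tip_rate_mean": float(np.mean([r.rate for r in rates])),
    }

    # ---- stage 4: centromere-type phylogenetic ANOVA ----
    anova_out = {}
    if "centromere_type" in tab.columns:
        sub_tree, sub = _complete_subset(tree, retained, ["centromere_type"])
        groups = sub.loc[sub_tree.tip_labels, "centromere_type"].to_dict()
        counts = pd.Series(list(groups.values())).value_counts()
        if len(counts) == 2 and counts.min() >= 2:
            responses = {"content_per_mbp": content, "total_bp": total_bp}
            if "proportion" in tab.columns:
                responses["proportion"] = tab["proportion"].to_dict()
            for p in range(2, 7):
                col = f"bp_{p}mer"
                if col in tab.columns:
                    responses[col] = tab[col].to_dict()
            rng = rngs["anova"]
            for name, resp in responses.items():
                vals = {s: resp[s] for s in sub_tree.tip_labels}
                res = phylo_anova(sub_tree, vals, groups,
                                  n_sim=config.n_sim, rng=rng)
                anova_out[name] = {"f_obs": res.f_obs,
                                   "p_phylo": res.p_phylo,
                                   "p_standard": res.p_standard}
    report["stages"]["anova"] = anova_out

    # ---- stage 5: Mk fit, stochastic maps, censored test ----
    censored_out = {}
    if "centromere_type" in tab.columns:
        sub_tree, sub = _complete_subset(tree, retained, ["centromere_type"])
        states = {s: 1 if v == "monocentric" else 0
                  for s, v in sub["centromere_type"].items()}
        if len(set(states.values())) == 2:
            mk = fit_mk_ard(sub_tree, states)
            rng = rngs["maps"]
            maps = [sample_stochastic_map(sub_tree, states, mk, rng)
                    for _ in range(config.n_maps)]
            vals = {s: content[s] for s in sub_tree.tip_labels}
            summary = censored_over_maps(maps, vals, alpha=config.alpha)
            censored_out = {
                "mk_q01": mk.q01, "mk_q10": mk.q10, "mk_loglik": mk.loglik,
                "n_maps": summary["n_maps"],
                "n_two_rate": summary["n_two_rate"],
                "n_monocentric_higher": summary["n_state1_higher"],
                "mean_sigma2_holocentric": float(np.mean(summary["sigma2_state0"])),
                "mean_sigma2_monocentric": float(np.mean(summary["sigma2_state1"])),
            }
    report["stages"]["censored"] = censored_out

    # ---- stage 6: chromosome number and genome size models ----
    lm_out = {}
    rng = rngs["lm"]
    tip_rate_map = {r.species: r.rate for r in rates}
    for predictor in ("chromosome_number", "genome_size_mbp"):
        if predictor not in tab.columns:
            continue
        for response_name, resp in (("content_per_mbp", content),
                                    ("tip_rate", tip_rate_map)):
            sub_tree, sub = _complete_subset(tree, retained, [predictor])
            y = {s: resp[s] for s in sub_tree.tip_labels}
            X = sub.loc[sub_tree.tip_labels, [predictor]]
            sub_trees = [prune_to(t, sub_tree.tip_labels)
                         if set(t.tip_labels) != set(sub_tree.tip_labels)
                         else t for t in pruned_trees]
            res = lm_over_trees(sub_trees, y, X, n_boot=config.n_boot,
                                rng=rng, alpha=config.alpha)
            lm_out[f"{response_name}~{predictor}"] = {
                "n_trees": res["n_trees"],
                "n_significant": res["n_significant"],
                "n_positive_slope": res["n_positive_slope"],
                "n_negative_slope": res["n_negative_slope"],
                "mean_slope": float(np.mean(res["slopes"])),
            }
    report["stages"]["lm"] = lm_out

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if profiles:
            scanned.to_csv(os.path.join(config.output_dir, "profiles.tsv"),
                           sep="\t", index=False)
    return report


def _iter_fasta_text(text: str):
    rec_id = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if rec_id is not None:
                yield rec_id, "".join(chunks)
            rec_id = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if rec_id is not None:
        yield rec_id, "".join(chunks)
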