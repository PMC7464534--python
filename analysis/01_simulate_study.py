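#!/usr/bin/env python
"""Generate the synthetic study: a 48-taxon time-calibrated tree with a
20-tree posterior-like set, centromere-type history with a 10x
monocentric/holocentric rate contrast in microsatellite content, a
content-on-genome-size slope, per-species traits, and small genome
assemblies with planted repeats.

Writes results/study/{trees.nwk, traits.tsv, genomes/*.fasta,
truth.json}.  Everything downstream (02-05) reads from there.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from study_config import OUT, STUDY_CONFIG

from msatphylo.phylo_core import write_newick
from msatphylo.synthetic_data import simulate_study, generate_genomes


def main():
    os.makedirs(os.path.join(OUT, "genomes"), exist_ok=True)
    study = simulate_study(STUDY_CONFIG)
    generate_genomes(study, STUDY_CONFIG)

    write_newick(study.trees, os.path.join(OUT, "trees.nwk"))
    study.traits.to_csv(os.path.join(OUT, "traits.tsv"), sep="\t",
                        index=False)
    for sp, fasta in study.genomes.items():
        with open(os.path.join(OUT, "genomes", f"{sp}.fasta"), "w") as fh:
            fh.write(fasta)
    truth = {
        "low_busco_species": study.truth["low_busco_species"],
        "tip_states": study.tip_states,
        "planted_total_bp": {sp: sum(l.end - l.start for l in loci)
                             for sp, loci in study.truth_loci.items()},
    }
    with open(os.path.join(OUT, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    n_mono = sum(study.tip_states.values())
    print(f"simulated {STUDY_CONFIG.n_taxa} species on "
          f"{STUDY_CONFIG.n_trees} posterior-like trees")
    print(f"  {n_mono} monocentric / {STUDY_CONFIG.n_taxa - n_mono} "
          f"holocentric species (true history recorded)")
    print(f"  {STUDY_CONFIG.n_low_busco} species given BUSCO < 0.90 to "
          f"exercise the quality filter")
    print(f"  genomes: {STUDY_CONFIG.genome_length // 1000} kb each, "
          f"planted repeat content matching the simulated trait")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
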