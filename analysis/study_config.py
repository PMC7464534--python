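"""Shared configuration for the numbered analysis scripts.

One synthetic study at desk scale: 48 taxa, 20 posterior-like trees, a
10x monocentric/holocentric rate contrast, and a positive
content-on-genome-size slope, all with known ground truth (seed 7).
"""

import os

from msatphylo.synthetic_data import SimConfig

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study")

# Microsatellite *density* (bp/Mbp) carries the centromere-type rate
# contrast and is independent of genome size; *total* content (Mbp) is
# density x genome size and therefore scales with genome size, which is
# the coupling the genome-size regression targets.  Chromosome number is
# a pure null predictor.
STUDY_CONFIG = SimConfig(
    n_taxa=48,
    n_trees=20,
    sigma2_by_state=(50.0, 500.0),  # holocentric, monocentric (bp/Mbp)^2/My
    q01=0.01, q10=0.01,             # centromere-type transitions per My
    content_slope_genome_size=0.0,  # density does not depend on genome size
    genome_length=60_000,
    n_low_busco=4,
    seed=7,
)

ANALYSIS_SEED = 7
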