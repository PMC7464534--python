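# Methods

`msatphylo` reimplements, as a tested pipeline, a comparative analysis of
microsatellite content across a phylogeny: exact detection of perfect
2–6-mer tandem repeats in assemblies, Brownian-motion (BM) inference of
the tempo of content evolution, and three hypothesis tests relating
content and its rate to centromere type, chromosome number, and genome
size.  Every stage is exercised end to end on synthetic data with known
ground truth.

## Repeat detection

A microsatellite is a perfect tandem repeat of a 2–6 bp motif.  The
scanner reports maximal perfect runs: a run at position `i` with period
`p` extends right while `s[j] == s[j+p]`.  Copy-number thresholds are
applied to complete copies (`floor(length/p)`) and default to the
micRocounter settings used for insect assemblies: 6 copies for 2-mers,
4 for 3-mers, 3 for 4–6-mers.  Semantics fixed by design:

* **Primitive period.** Each run is classified by the smallest period of
  its motif; `(AT)7` is a 2-mer run, never a 4- or 6-mer.  Homopolymers
  are never reported (period 1 is outside the range, and an `AA` motif is
  non-primitive).
* **Extent vs count.** A locus's extent includes partial trailing copies
  (maximality makes output unique); the threshold counts complete copies.
* **Overlap resolution.** Left to right, the longest qualifying run wins;
  ties prefer the smaller period; scanning resumes after the reported
  locus.  Output is therefore non-overlapping and deterministic.
* **Ambiguity and case.** Input is case-folded (assemblies are used
  unmasked; soft-masking must not delete content); any non-ACGT character
  never matches, so it terminates runs.
* **Coordinates** are 0-based half-open (BED convention).  Motifs are
  canonicalised by rotation only; a `fold_strands` flag also folds
  reverse complements.  The bp totals used by all downstream analyses are
  strand-invariant.

Two independent implementations exist: a vectorised production scanner
(match arrays + run-length extension; ~0.15 s/Mbp) and a pure-Python
character-by-character oracle.  The oracle defines ground truth for
synthetic genomes and the two are held set-identical by tests.  One
documented caveat: when two qualifying runs of different motifs abut or
overlap (compound repeats), the left-to-right rule decides the boundary,
so scanning a reverse complement can shift a junction by up to one motif
length; with isolated repeats the mirror identity is exact.

## Brownian-motion machinery

Branch lengths are in millions of years (My); a trait with rate
`sigma2` accrues Normal(0, sigma2·t) change along a branch of length t.

* **REML rate.** Felsenstein's standardized contrasts give the closed
  form `sigma2 = sum(u_i^2)/(n-1)`; the restricted log-likelihood in
  contrast form is checked against dense restricted-MVN matrix algebra to
  1e-8.  An ML variant (divide by n, root profiled analytically) exists
  for cross-checks.  No iterative optimiser is involved.
* **Ancestral states** are GLS/ML estimates from a linear-time up–down
  message-passing sweep, equal to `mu + C_k C^{-1} (x - mu)`; estimates
  are invariant to the sigma2 scale.
* **Tip rates** are `(x_tip - a_parent)/t_tip` where `a_parent` is the
  parent node's ancestral estimate from the joint GLS over *all* data
  (the focal tip contributes); a leave-one-out variant uses only the
  downward message.  Under BM, tip rates are centered on zero but
  *heteroscedastic* (variance grows as terminal branches shrink) — see
  Limitations.
* **Mixed units, deliberately.** Order-level and global rates are fit on
  content density (bp per Mbp of assembly, rate units (bp/Mbp)²/My); tip
  rates are computed on total bp (bp/My).  Both columns are first-class
  in the trait table.
* Polytomies are resolved arbitrarily with zero-length branches;
  likelihoods and ancestral estimates are invariant to the resolution
  (tested).  Zero-length terminal branches are rejected by tip rates.

## Centromere type: Mk model and stochastic maps

Centromere type (holocentric = 0, monocentric = 1) evolves by a 2-state
Markov model with asymmetric rates (q01, q10), fit by L-BFGS-B over
log-rates from four starts; the likelihood uses pruning with the
closed-form 2×2 transition matrix.  The root prior defaults to flat
(stationary and fixed are options).  Missing states are ambiguous
(partial likelihood 1) and receive sampled states in maps.

Stochastic maps are exact draws from the posterior of full histories:
node states sampled root-down from their joint conditional distribution,
then each branch's internal history sampled conditional on its endpoints
by uniformization (number of virtual jumps by inverse-CDF against the
Poisson–R^n series, embedded chain by backward products, jump times as
uniform order statistics).  The sampler's conditional change-count
distribution is tested against the truncated analytic series (χ² GOF)
and its conditional mean against the analytic expectation.

## Hypothesis tests

* **Phylogenetic ANOVA.** The classical one-way F on tip values is
  compared to F values from `n_sim` single-rate BM traits simulated on
  the tree (sigma2 = REML estimate from the observed trait, group
  structure ignored under the null; group labels fixed).  Empirical
  p-values use the plus-one correction `(#{F_sim >= F_obs}+1)/(n_sim+1)`.
  On a star tree this converges to the classical ANOVA p (tested at
  n_sim = 5000).
* **Censored two-rate test.** Given a map, each branch's effective length
  is `sigma2_0·d_0 + sigma2_1·d_1` over its state segments.  Writing
  `sigma2_1 = r·sigma2_0`, the scale has the usual REML closed form and
  only log r is optimised (bounded 1-D search, |log r| ≤ 12).  The
  one-rate model is the global REML fit — exactly the r = 1 profile
  point, so nesting holds by construction.  Significance: LRT against
  χ²(1) at α = 0.05; ΔAIC is also reported.  Degenerate maps (a state
  absent) return the one-rate result flagged.
* **PGLS.** `beta = (X'C^{-1}X)^{-1} X'C^{-1} y` with ML sigma2 for the
  likelihood and the residual-df (n−p) variance estimate for t-tests (a
  standard small-sample convention).  Confidence intervals come from a
  parametric bootstrap (simulate `y* = X·beta + BM noise`, refit,
  percentile CI) — residual resampling is not exchangeable under
  phylogenetic covariance.  On a star tree the fit reduces to OLS to
  1e-8.  `lm_over_trees` tallies per-tree significance and slope signs
  across a posterior tree set rather than averaging statistics.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given (parameters, seed).

* **Trees.** Forward Gillespie birth–death simulation (default birth
  0.03, death 0.01 per My), restarted on extinction and stopped the
  moment the n-th lineage appears (then advanced by one inter-event time
  so the newborn pair has positive branches).  This is rejection-style
  conditioning on n survivors, not the exactly conditioned process —
  adequate at desk scale.  Posterior-like tree sets are age-jittered
  variants of one base tree (lognormal factor, rel. SD 0.1, parents kept
  older than children): correlated trees with a shared topology, as a
  Bayesian posterior sample is.  Earlier designs using independent
  topologies per "posterior" tree misstate the per-tree analyses.
* **Traits.** Content density (bp/Mbp) evolves by state-dependent BM
  (defaults: root 2000 bp/Mbp, holocentric 1 and monocentric 10
  (bp/Mbp)²/My — a 10× contrast; floor at 50 bp/Mbp keeps densities
  positive).  Genome size is lognormal-BM around ~400 Mbp; *total*
  content (bp) is density × size, so it scales with genome size
  mechanically, which is what the genome-size regression targets; an
  optional direct density-on-size slope also exists.  Chromosome number
  is BM on the haploid count (root 14, sigma2 0.05/My), rounded and
  clipped — phylogenetically conserved, as real karyotypes are.  BUSCO
  scores are ~N(0.965, 0.02) with a configurable number of records
  forced below 0.90 to exercise the quality filter.  "Orders" are
  contiguous clades of ≥ 8 tips.
* **Genomes.** I.i.d. background at a given GC (default 0.38, AT-rich)
  with planted perfect repeats at recorded non-overlapping positions;
  each plant's periodic continuation is broken at both flanks so it is
  maximal at exactly the recorded coordinates.  The truth table is the
  *oracle scan of the finished sequence*, so background-arising repeats
  are truth, not noise.
* **Not emulated:** substitution processes, indels, repeat-length
  mutation dynamics (slippage), assembly error, GC heterogeneity along
  the genome, and any correlation between centromere type and genome
  size.  Passing tests therefore demonstrate correctness of the
  *inference machinery* under its own model, not robustness to real
  assembly artefacts.

## Pipeline

`run_study` wires the stages: scan (or accept a trait table), BUSCO
≥ 0.90 retention (boundary inclusive; unscored records dropped with a
log line), tree pruning to retained species, global/per-order REML rates
on density (orders need ≥ 10 species by default), tip rates on total bp,
phylogenetic ANOVA of content by centromere type, Mk fit + stochastic
maps + censored tally, and PGLS tallies for chromosome number and genome
size over the tree set.  Species missing a field are excluded only from
analyses needing that field.  Every stage draws from a named child of
the master seed (`SeedSequence.spawn`), so reports are bit-identical
given a config and insensitive to another stage's draw count.

## Problem sizes

Test-suite calibrations use the sizes their checks state (1000 random
sequences for oracle equivalence; 50 × 1 Mb genomes for planted
recovery; 1000 replicates for sigma2 recovery and ANOVA type-I; 500 for
censored type-I/power at 128 tips; 200 for bootstrap coverage at 200
tips).  `scripts/acceptance.py` recomputes the same quantities at
same-order sizes chosen for a single CPU (300 sequences, 10 genomes,
300–500 replicates, and two 64-taxon studies with a 100-map censored
tally and a 100-tree regression tally); both finish in minutes.  The
numbered analysis scripts use one 48-taxon, 20-tree study with 60 kb
genomes.

## Known limitations

* The censored LRT's χ²(1) reference is asymptotic; its finite-sample
  type-I error varies by tree and map (roughly 0.03–0.09 across trees at
  128 tips, ~0.05 on average).
* PGLS with a *tip-rate* response is anticonservative in principle: tip
  rates violate the assumed BM covariance (variance inflates on short
  terminal branches).  The pipeline mirrors the published procedure and
  reports it as such; treat small p-values from tip-rate regressions
  with caution.  Similarly, PGLS with an i.i.d. (non-phylogenetic)
  predictor is anticonservative when the response's true rates are
  state-dependent; the generator's phylogenetically structured
  chromosome numbers restore calibration.
* Per-tree significance tallies over a correlated posterior are
  all-or-nothing for a single dataset: the 100 trees are near-replicas,
  so a dataset in the null's 5% tail yields ~100/100 significant trees,
  not 5/100.  Calibration statements apply across datasets.
* Compound-repeat boundaries depend on the declared left-to-right rule;
  other scanners may partition junctions differently, so bp totals can
  differ in the last few bp per junction.
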