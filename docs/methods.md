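# Methods

`mitorates` re-implements, as a tested library, a comparative analysis of
molecular evolutionary rates: do mitochondrion-related genes (mitochondrial
OXPHOS subunits, their nuclear-encoded partners, mitochondrial ribosomal
proteins) evolve faster in haplodiploid arthropod lineages than in diploid
ones, while mitochondrion-unrelated nuclear genes do not?  The package
covers the full chain from ortholog catalogues to statistics — category
assignment, alignment trimming, concatenation, maximum-likelihood branch
lengths on a fixed chronogram topology, per-species rates, nonparametric
group tests and correlations, and gene-family copy-number analysis — plus a
synthetic-study generator with known truth so every stage is verifiable
without external data.

## Synthetic chronograms

Trees are generated by a Yule (pure-birth) process rescaled to a fixed root
age (default 500 MY); the analysis needs an ultrametric chronogram, not a
realistic diversification model.  Haplodiploid clades are then grafted onto
the diploid backbone: one multi-species clade labelled "hymenoptera"
(default ~30% of species, split at its crown into bees/ants and
sawflies/wasps) and singleton lineages for the remaining origins, mirroring
a study system with one densely sampled haplodiploid order and a few
isolated haplodiploid species.  Clade stems attach at 2–10% of the root age
below the root.  This placement is a deliberate design choice: the rate
shift associated with each haplodiploid origin then acts over essentially
the whole root-to-tip path of the affected species, so a clade rate
multiplier *m* is recoverable from root-to-tip rate ratios (the expected
ratio is `m − (m−1)·d/R` for a stem attaching at depth *d*; with d/R ≤ 0.1
the dilution is under 7%).  Ultrametry is exact by construction (nodes are
stored as depths) and is asserted to 1e-9 relative on every round trip.

## Sequence simulation

Sequences evolve site-independently from a root draw at the model's
equilibrium frequencies.  A branch's expected substitutions/site are
`duration (MY) × site rate (AA/site/MY) × ∏ clade multipliers ×
lineage factor`, where:

* a branch belongs to a clade iff every tip below it is a clade member —
  this includes the clade's stem branch, i.e. the shift happens at the
  origin of haplodiploidy;
* each site is assigned one of the model's discrete-gamma categories
  uniformly at random — the *same* discretisation the estimator uses, so
  generator and estimator agree about what "gamma heterogeneity" means;
* the lineage factor is an independent mean-1 lognormal draw per branch
  (`lineage_sd`, default 0.2 log-sd; an uncorrelated relaxed clock), drawn
  independently per category.  Real lineages vary in rate for reasons
  unrelated to the factor under study; without this term the only
  across-species rate variation in an unshifted category is estimation
  noise, which is phylogenetically correlated and makes rank-based null
  behaviour unrealistic (see "Rate comparisons" below).

Default category settings follow the study design they emulate: gene
counts 13 (mtOXPHOS), 65 (nucOXPHOS, 4 flagged complex-2), 74 (nucMTRP),
77 (nucCRP), 150 (nucControlSingle) and 5746 (nucControl); base rates near
the observed all-species medians (0.0018, 0.0012, 0.0015, 0.00084, 0.00118,
0.00136 AA/site/MY respectively); mitochondrion-related categories
accelerated 2.5× in every haplodiploid clade, controls unshifted; gamma
shape 0.7 with 4 categories.  Gene lengths are Poisson around 350 aa and
depend only on the category name, so different master seeds give
identically shaped outputs.  Optional per-species×gene dropout emits all-gap
sequences (counted as absent by the catalogue), and optional duplication
emits a second, slightly perturbed paralog copy.

Copy numbers evolve per family by a linear birth–death process (per-copy
rates per MY, default 1e-4 each — most families keep their ancestral count
over 500 MY, matching the copy-number conservation the analysis assumes).
Biased families additionally impose group-conditional counts (e.g. two
copies in sawflies/wasps, one in bees/ants), each species escaping the
override with probability 0.05 so the contrast holds in most but not all
species.

What the generator does **not** emulate: indels and alignment error (data
are emitted aligned; the trimmer is exercised on constructed cases), codon
structure and selection, rearrangements, correlated (autocorrelated)
clocks, empirical amino-acid exchangeabilities (the default is the Poisson
model; empirical matrices load from PAML files), and non-ultrametric input
error.  Passing tests therefore demonstrate the correctness and calibration
of the estimators and tests under the model's assumptions — not robustness
to alignment artefacts or model misspecification on real data.

## Likelihood engine

`log_likelihood` implements Felsenstein pruning over compressed site
patterns under a reversible model `Q = S·diag(π)` normalised to one
expected substitution per site per unit length, with discrete-gamma site
rates (equal-probability categories, category rate = interval mean of the
mean-1 gamma, k = 4 by default; the category mean is exactly 1 by
construction).  Gap `-` and missing `X` contribute partial likelihood 1 to
every state.  Partial likelihoods are rescaled per site when their maximum
drops below 1e-240, with log scale factors carried separately, so deep
trees cannot underflow.  Transition matrices come from the symmetrised
eigendecomposition of Q; tiny negative round-off entries are clipped at 0.

`optimize_branch_lengths` performs coordinate-wise maximisation: a
depth-first sweep maintains exact inside ("below") and outside ("above")
partials at the current edge, so each one-dimensional problem only needs
the two endpoint partials.  These are projected into the eigenbasis once
per edge, making each Brent evaluation an exp-weighted inner product.
Branches are bounded to [1e-8, 20] substitutions/site; rounds repeat until
the log-likelihood gain falls below `tol` (default 1e-6) or `max_rounds`
(default 20).  The gamma shape, when optimized, uses the same bounded
scalar search on log-α in [0.02, 50], interleaved between branch rounds.

**Root edges.** Under a reversible model only the *sum* of the two branches
incident to a bifurcating root is identifiable.  The optimizer treats that
sum as one parameter and splits it between the two edges in proportion to
their starting values (by default proportional to the chronogram
durations).  Root-to-tip sums are unaffected; the split only matters if the
two basal lineages truly differ in rate, in which case their individual
root-edge lengths are unknowable from reversible-model data anyway.

`select_model` fits every candidate (branch lengths and α) and returns the
highest log-likelihood, ties broken by candidate order.  By default each
candidate's frequencies are replaced by those observed in the alignment
with a 0.5 pseudocount (the "+F" convention); the shipped candidate is the
Poisson model, and empirical matrices can be supplied as PAML-format files.

## Rates

All rates are amino-acid substitutions per site per million years.  The
*terminal rate* divides the terminal branch length by the terminal branch
duration (the parent-node age) — numerator and denominator cover the same
tree segment, which is the only unit-consistent reading of "branch length
divided by divergence time"; the alternative (stem age of a sampled clade)
is noted but not used.  The *root-to-tip rate* divides the root-to-tip path
sum by the root age.

## Rate comparisons

Group comparisons use the Kruskal–Wallis test (tie-corrected H, χ²
approximation with k−1 df; all-equal input is defined as H=0, p=1) followed
by the Siegel–Castellan all-pairs procedure on mean ranks
(`|R_i − R_j| ≥ z_{1−α/(k(k−1))}·√(N(N+1)/12·(1/n_i+1/n_j))`, α default
0.05); decisions, not adjusted p-values, are the primary output.  Spearman
correlations use average ranks and the t-approximation with n−2 df;
constant input is an explicit error.

Root-to-tip rates of related species share internal branches: both their
estimation errors and any lineage rate effects are correlated within
clades, which makes rank tests on them anticonservative (in simulation with
a flat control category, a root-to-tip omnibus rejected in ~45% of runs at
nominal 5%).  The pipeline therefore reports omnibus tests for both rate
types and treats the terminal-rate test (disjoint branches; calibrated in
the same simulation) as the inferential one, with root-to-tip comparisons
as the descriptive whole-history view.  Between-category correlations
default to root-to-tip rates (matching the headline analysis) with the rate
type exposed as a parameter; the same non-independence caveat applies and
is flagged in the documentation and examples.

Two subsampling designs are provided.  The hymenopteran subsample re-runs
estimation once per hymenopteran on that species plus all
non-hymenopterans, keeping divergence times constant across subsamples and
removing the dense-sampling advantage of the focal order.  Matched control
subsampling draws control-gene sets matching a target category's gene count
and gene-family-size profile; family size is proxied by species-presence
count, binned into pool deciles (the exact binning is not prescribed
anywhere, so deciles are the package's choice), with documented relaxation
to the nearest bins when a bin is exhausted; the default is 1000
replicates.

## Gene families

Ancestral copy numbers are reconstructed per family by Sankoff dynamic
programming over integer states 0..max_count (default max tip count + 2)
with linear cost |child − parent| and no branch-length weighting (a
duration-weighted cost is available but off by default, matching
parsimony-style reconstruction on a time tree).  Ties are broken toward the
smallest count at the root and at every traceback step, making the
reconstruction unique and tip-order invariant.  Per-branch deltas are
classed expansion/contraction/stable and tallied per branch and species
group.

Discriminative families are selected by a shadow-feature procedure: per
iteration, every family column is permuted into a shadow, a random forest
(500 trees by default, mean-decrease-in-impurity importance) is fitted on
real+shadow features, and a family scores a hit when it beats the best
shadow.  After n iterations (default 30, minimum 20) each family gets a
two-sided binomial test of hits vs 0.5, Bonferroni-corrected across
families at the family-wise level (default 0.01); undecided families are
resolved by the rough fix — confirmed iff their median importance exceeds
the median per-iteration shadow maximum.  The three study contrasts
(haplodiploid vs diploid, hymenoptera vs diploid, other-haplodiploid vs
diploid) plus bees/ants vs sawflies/wasps run with shared settings; a
contrast with fewer than two species in a class is skipped with a warning.

Caveat: with phylogenetically structured copy numbers, a family whose
neutral drift happens to track a clade is indistinguishable from a real
group effect — the selection controls the family-wise error against
label-independent noise, not against phylogenetic autocorrelation.

## Numerical and degenerate-input conventions

Column coordinates are 0-based half-open everywhere.  Missing species
blocks in concatenation are filled with `X` (documenting intent; gaps and
missing are equivalent in the likelihood).  The background presence filter
keeps groups present in at least ⌈fraction × n_species⌉ species (76 species
at 80% → 61), computed with a 1e-9 guard against float round-off.  The
trimmer is a simplified conserved-block filter (defaults: modal residue ≥
50% of non-missing rows, blocks ≥ 6 columns, gaps allowed), idempotent by
construction, and deliberately not a bit-compatible clone of any particular
program — the analysis depends on conservative block filtering, not on one
tool's exact heuristics.  All randomness flows from per-stage children of a
single master seed (`numpy` SeedSequence spawning), and fixed seeds give
byte-identical outputs.

## Problem sizes

The test-suite and `scripts/acceptance.py` run the full machinery at
reduced scale chosen to keep each property sharply testable: 14–20 species
with 3 haplodiploid clades and ~900-column category supermatrices for
rate-recovery and power checks (20 and 10 seeded replicates respectively),
8 taxa × 5,000 sites for branch-length recovery, ≤4-tip trees for the
exhaustive likelihood and parsimony oracles (200 instances), 5,000 null
simulations for rank-test calibration, and 50-family matrices over 20
species for the feature-selection checks.  The generator's *defaults*
remain at study scale (76 species, Table-level gene counts); scaled runs
simply pass a smaller `SimulationConfig`.

## Known limitations

Branch lengths near the 1e-8 lower bound are reported as the bound, not 0;
rate tables built from them give rates that are numerically but not exactly
zero.  The optimizer is coordinate-wise and can in principle stall on
ridges (in practice the monotone sweep with exact conditional optima
converges in < 20 rounds on all tested data).  dN/dS, topology inference,
time-tree estimation, PGLS-style phylogenetic regression and GO enrichment
are out of scope.  The feature-selection and correlation analyses inherit
the phylogenetic non-independence caveats stated above.
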