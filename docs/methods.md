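# Methods

`phyloselect` implements a complete selective-pressure analysis of
protein-coding gene families: data-quality gating, long-branch-attraction
(LBA) diagnosis, codon-model selection inference, and annotation of
positively selected sites against disease-implicated residues.  This note
records the models, the numerical choices, and what the synthetic-data
suite does and does not establish.

## Sequence containers and coordinates

Codon alignments are in-frame CDS alignments over `{A,C,G,T,-,N}`; any
codon containing `N` or a partial gap is treated as fully missing in every
likelihood.  Protein alignments use the 20-letter alphabet plus `{-,X}`.
Internally all coordinates are 0-based half-open; every report, feature
table and site call uses 1-based positions matching Swiss-Prot residue
numbering.

## Alignment randomization z-score

Alignment quality is scored as the sum-of-pairs BLOSUM62 score of the
alignment (gap-vs-residue scored −8, gap-vs-gap 0) standardized against a
null built by shuffling each row's residues while freezing its gap
positions.  Freezing the gap architecture isolates the residue-order
signal: the null alignments share the observed geometry, so the z-score
measures only whether homologous residues are actually aligned.  A z-score
above 5 is taken as significant; well-aligned homologous families score in
the hundreds to thousands.  The scoring scheme is a package choice —
published randomization tests of this kind rarely state theirs — and only
the z-scale, not the raw score, is interpreted.

## Composition bias screen

Each sequence's residue (or base, for codon data pooled across the three
positions) composition is compared by chi-square against the pooled
frequencies of the whole alignment — the `+F` frequency distribution a
maximum-likelihood model would assume.  Categories whose expected count
falls below 1 are merged into the nearest-frequency category before the
statistic is formed; the degrees of freedom are the remaining categories
minus one, and a taxon passes at p ≥ 0.05.  Note that a single extremely
biased sequence also shifts the pooled expectation, so mild failures in
its companions should be read with that in mind.

## Likelihood mapping

Phylogenetic signal is quantified by likelihood mapping: for every quartet
of taxa (exhaustive when C(n,4) is small, otherwise sampled without
replacement), the three unrooted quartet topologies are fit by maximum
likelihood (branch lengths optimized per topology) and the posterior
weights `w_t = exp(lnL_t − max)/Σ` place the quartet on the probability
simplex.  A quartet is a corner when its best weight exceeds 2/3, an edge
when the worst weight is below 1/3, and center otherwise — the standard
seven-region geometry.  Signal categories: category 1 (strong) when the
corner fraction is ≥ 0.9 and the center fraction ≤ 0.05; category 3
(low/none) when the corner fraction is < 0.7; category 2 otherwise.  The
thresholds are configurable and recorded in every report; they gate the
pipeline (category 3 stops the analysis), and were chosen as round
defaults since the original gating procedure is qualitative.  Note that on
star-like data the mass moves into edge regions as much as the center:
with non-trivial terminal branches one resolution is usually weakly
preferred over exactly one alternative.

## Amino-acid likelihood engine

The engine is a standard Felsenstein pruning implementation over an
arbitrary state space with per-node rescaling and column pattern
compression.  The amino-acid model family is JTT with optional +I
(invariant class, proportion estimated), +G (discrete gamma, equal-weight
categories whose rates are conditional slice means, renormalized to mean
1), and +F (frequencies from the pooled data with a light pseudocount).
The JTT exchangeabilities are the published Jones–Taylor–Thornton values.
Eight gamma categories are used throughout so the same discretization
serves both rate inference and the slow-fast stripping scan.

Trees: starting trees are neighbor-joining on maximum-likelihood pairwise
distances (Brent per pair, distances capped at 10 substitutions/site with
a warning for saturated pairs; negative NJ branch lengths clamped to 0).
Branch lengths are optimized coordinate-wise by bounded Brent with at
least two full sweeps (convergence at ΔlnL < 1e-6 for final fits; the NNI
search uses faster 1e-4 passes for candidates and polishes the final tree
at 1e-6).  Topology search is nearest-neighbor interchange: all neighbors
are screened at current branch lengths, the two most promising are
re-scored with branch-length optimization, and a swap is accepted only
when it improves lnL by at least 1e-4.  Model choice among JTT
[+I][+G][+F] combinations is by AIC with branch lengths shared from a
JTT+G fit; the criterion is configurable.  Reports record the method as
`tree_method: ml_nni` — a deliberate design choice: every downstream
consumer (SH test, stripping, codon models) needs only a point-estimate
tree with branch lengths, so a Bayesian consensus tree would add cost
without changing any statistic computed here.

Site-rate profiles assign each column the MAP category of the 8-category
gamma posterior (`P(c|column) ∝ (1/8) P(column|rate_c)`), with ties broken
toward the slower category so stripping never removes a site on a tie;
with +I the invariant class is folded into category 1.

## Tree comparison

*Nodal RMSD.*  For each pair of shared tips the path length is counted in
edges on the unrooted tree (trees are pruned to their common taxon set
first), and the RMSD of the two path matrices is reported.  It is 0 iff
the matrices agree, symmetric, and polytomies are allowed — they simply
shorten paths.  Edge counting differs from counting internal nodes by a
constant 1 per path, which cancels in every comparison made here;
unrooted matrices are used so arbitrary rooting cannot create distance.

*SH test.*  The Shimodaira–Hasegawa test re-optimizes branch lengths per
candidate topology, forms per-site log-likelihood vectors, and bootstraps
(RELL, default 1000 resamples) the centered per-tree sums.  One-sided
p-values are computed for each tree against the best; the best tree's p is
1 by the centering convention, and the comparison is reported as `NS` when
no tree is rejected at the 0.05 level — i.e. the data cannot distinguish
gene tree from species tree.

## Slow-fast LBA scan

Site-rate categories are estimated once on the full alignment (tree by
NJ+NNI, gamma shape by ML) and frozen; deeper levels remove the fastest
categories as a contiguous suffix ({8}, {8,7}, …, never an interior
category — the slow-fast logic orders sites by rate) and re-infer the tree
per level.  Each level records the nodal RMSD against the species tree
and an SH test of {gene tree, species tree}.  The verdict rule is
explicit: LBA is called when the full-alignment tree disagrees with the
species tree (RMSD > 0) *and* some stripped level agrees (RMSD = 0, or SH
best-fit `NS`/`ideal`, i.e. the species tree is not rejected once fast
sites are gone).  Stripping below 50 remaining columns raises an error
advising coarser stripping.

The synthetic LBA scenario is a six-taxon balanced tree with short
internal branches (0.015 substitutions/site) whose two non-sister tips A
and C are lengthened 20-fold.  The attraction expresses itself through
the distance-based starting tree — neighbor joining genuinely attracts
long branches at finite sample sizes — and the flat likelihood surface
around the short internal branches lets the misresolution survive the NNI
polish; stripping the two fastest categories removes the saturated sites
that carry the attraction.  This emulates the mechanism, not any
particular gene; maximum likelihood under the generating model is far
more LBA-resistant than the parsimony and distance methods the phenomenon
was described for, so the fixture deliberately sits in the
weak-internal-signal regime where finite-sample attraction is real.

## Codon selection models

The codon model is the Goldman–Yang-style 61-state Markov process:
`q_ij = π_j · κ^[transition] · ω^[nonsynonymous]` for single-nucleotide
changes, 0 otherwise.  Codon frequencies default to F3x4 (positional
nucleotide frequencies with a 0.5 pseudocount; F1x4, F61 and equal are
available).  κ is a free parameter of every fit.  One scale factor per
model — the mixture-average substitution rate over site classes (the
background mixture for branch-site models) — converts branch lengths to
expected substitutions per codon site under the full model.

Site-class mixtures follow the standard model ladder: M0 (one ω); M1
(ω0 ∈ [0,1] estimated, ω1 = 1 — the modern parameterization; a legacy
strict ω0 = 0 toggle exists); M2 (adds ω2 ≥ 1); M3 with k = 2 or 3 free
classes; M7 (10 equal-probability beta bins, bin rate = conditional slice
mean); M8 (beta plus a free ω_s ≥ 1 class); M8a (ω_s = 1).  Bounding M8's
selected class at 1 keeps the M8-vs-M8a contrast a test of selection
against neutrality.  Branch-site Model A (classes ω0, 1, plus foreground
classes 2a/2b with ω2 ≥ 1 on marked branches), Model A-null (ω2 = 1) and
Model B (background ω0, ω1 free) use PAML-style class weights
`(p0, p1, p2·p0/(p0+p1), p2·p1/(p0+p1))`.

Fitting: parameters are transformed to unconstrained coordinates (log for
positive, logit for [0,1], stick-breaking for proportion pairs,
`1+exp` for ω ≥ 1) and optimized by Nelder–Mead, best of `n_restarts`
jittered starts (deterministic given the seed).  Branch lengths are
optimized once under M0 and then fixed for the other models (the standard
protocol; joint optimization is available by flag, and `given` accepts
the input tree's lengths as-is — the protocol used by the simulation
recovery suites, where the generating lengths are known and re-estimating
them at every replicate would only add runtime, not information).
Alternative fits warm-start from their null's estimates where a
registered nesting exists, which both accelerates convergence and
guarantees `lnL(alt) ≥ lnL(null)` up to optimizer tolerance; residual
negative LRT statistics are clamped to 0 with a warning.

LRTs use the registered nested pairs (M0/M3k2 df 2, M0/M3k3 df 4, M1/M2
df 2, M7/M8 df 2, M8a/M8 df 1, M1/ModelA df 2, ModelAnull/ModelA df 1,
M3k2/ModelB df 2) with p from the chi-square upper tail.  M8-vs-M8a is
tested against χ²(1) by default; the 50:50 boundary-mixture correction is
a documented option, not the default, matching the critical-χ² convention
of the analysis this package reproduces.  ω estimates above 900 are
clamped to the conventional 999.00 sentinel in reports only.

Positively selected sites: NEB evaluates the class posterior at the MLEs.
BEB (M8 and Model A) averages the class posterior over a uniform grid
prior on the mixture parameters (10 points per dimension by default; M8:
p0, p, q, ω_s; Model A: the two stick-breaking proportion coordinates,
ω0, ω2).  As a numerical device, per-site likelihoods as a function of ω
are precomputed on a fixed ω grid (21 points on [0,1], 12 on (1,12]) and
interpolated linearly in log-likelihood; this keeps the 10⁴-point grid
integration at a few seconds per gene with interpolation error far below
the posterior thresholds in use.  Calls are reported at 0.50/0.95/0.99
and are nested by construction.

## Site annotation and the proximity test

Selected alignment columns are mapped to 1-based ungapped positions on a
chosen reference taxon (codon columns map per codon; columns where the
reference is gapped are reported unmapped).  Genetic-code distance
between two amino acids is the minimum Hamming distance over all codon
pairs encoding them (0–3, by exhaustive enumeration).  One published
per-site summary table prints C–M = 2, but every Cys codon differs from
every Met codon at all three positions — the enumeration gives 3, and
this package reports the metric's value.

The proximity null places a single site uniformly over the eligible
region (the whole reference by default, restrictable) with the features
fixed; the per-site p-value is the null probability of landing within the
observed distance of the nearest feature.  `exact` mode enumerates all
eligible positions; Monte-Carlo mode draws placements with a seed.  A
secondary whole-set mode randomizes all sites jointly and compares the
mean nearest distance.  Distances are primary-sequence residue
separations, not 3D.  Because the null is discrete, p-values are exactly
attainable probabilities: calibration is checked against a sparse feature
set (20 features on 1464 residues) where the attainable p-grid is fine;
with very dense features the smallest attainable p can exceed 0.05 and no
site can be called significant — a property of the test, not a bug.

## Synthetic data

The simulators draw a mixture class per site, a root state from the
stationary distribution, and propagate states down the tree with the
class's (branch-specific, for marked foregrounds) transition matrices;
protein simulation draws per-site gamma rates.  Perturbations: named
branches can be scaled (the LBA scenario) and a taxon's residues can be
resampled toward a target residue at a configured fraction of sites (the
composition-bias scenario).  Alignments are generated gap-free — indels
are out of scope — with an optional uniform gap mask for I/O tests.  The
default demonstration tree is a fixed 12-taxon mammal topology (branch
lengths 0.02–0.3 substitutions/site), matching the taxon scale of the
analyses this package reproduces.

What passing tests show: the estimators recover the generating parameters
and the tests hold their nominal error rates *under the model*, i.e. with
no indels, no alignment error, no selection on synonymous sites, and
frequencies matching the generator.  They do not certify behavior under
real-data misspecification (alignment uncertainty, CpG effects,
context-dependent mutation), which is why the quality gates run first in
the pipeline.

## Problem sizes and determinism

All randomness flows from explicit integer seeds; simulators are
bit-reproducible given (recipe, seed), and the pipeline's report bundle
is byte-identical across reruns of one config.  The validation suites use
6–12 taxa and 150–800 codons (300 residues for the protein scans), with
10-seed recovery medians and 20-replicate error-rate checks — sizes chosen
so the whole suite runs on a single desktop CPU in well under half an
hour while keeping each check's statistical resolution meaningful.

## Known limitations

- No indel evolution or alignment-error modeling; alignments are inputs.
- Codon frequencies are count-based (F3x4/F1x4/F61), not ML-estimated;
  clade models and mutation–selection models are out of scope.
- The BEB grid integration uses interpolated site likelihoods (above);
  posteriors within ~1e-3 of a call threshold could in principle flip.
- The SH implementation covers the two-tree (gene vs species) use plus
  arbitrary candidate sets; KH and AU tests are not provided.
- NJ+NNI can stop in a local optimum on flat likelihood surfaces — a
  property the LBA scan deliberately exploits, but worth remembering when
  interpreting single-gene topologies.
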