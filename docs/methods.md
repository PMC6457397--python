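# Methods

This note documents the models, conventions and numerical choices behind
`caenophylo`, and what the synthetic-data generators do and do not emulate.

## Trees

Trees are rooted as written, with branch lengths in substitutions per site
and optional integer support values (0–100) on internal nodes, stored in
the Newick label position (the dialect RAxML-style bootstrap trees use).
Non-numeric internal labels are preserved but ignored by support-based
operations. Polytomies are allowed everywhere.

`collapse_low_support(tree, threshold)` contracts internal edges whose
child support is *strictly* below the threshold (a node at exactly the
threshold is kept). Edges with no support annotation are kept: an
unannotated edge carries no evidence against itself, and collapsing it
would delete signal rather than noise. The contracted edge's own length is
discarded — downstream consumers of collapsed trees (paralogy screening)
use topology only.

## Orthology screening

Selection: an orthogroup is single-copy-selected when at least
`min_present` species carry it and no species exceeds one copy, except
species in the double-allowance set, which may carry up to two. The
allowance is `count <= 2`, not `count == 2`: it exists for assemblies with
uncollapsed haplotypes and for transcriptome-only taxa, and absence or a
single copy must remain acceptable.

Paralogy screening collapses the orthogroup's gene tree at the support
threshold (default 50), then asks, for each species with two sequences,
whether those sequences *could* be monophyletic in some refinement of the
collapsed tree: they can iff every child subtree of their MRCA lies
entirely inside or entirely outside the species' leaf set. Polytomy
children are therefore mutually compatible — weakly supported conflict is
not treated as evidence of paralogy. Species whose sequences are separated
by a supported edge cause the orthogroup to be discarded. A species with
more than two sequences also causes a discard: the in-paralogue resolution
rule is defined for pairs, and three or more copies indicate a genuine
expansion rather than haplotype artefacts. Surviving in-paralogue pairs are
resolved by keeping the longer sequence; length ties break to the
lexicographically smaller sequence ID for determinism. The order is fixed:
collapse, then monophyly check, then in-paralogue resolution.

Duplication ratio: over a selected orthogroup subset, a species' total
sequence count divided by the number of those orthogroups containing it.
It is ≥ 1 by construction and equals 1 iff the species is single copy in
every counted orthogroup. The QC screen selects orthogroups present in at
least `presence_min` species with mean per-present-species count at most
`mean_count_max` (default 1.5 — "on average single copy" read with
rounding; an exact mean of 1 would force all-single-copy orthogroups and
make every ratio 1, so the knob is exposed), and excludes species with
ratio strictly greater than the threshold (default 1.2).

## Quartet supertree

The objective is the quartet score: for each 4-taxon subset, the number of
gene trees whose induced unrooted quartet matches the candidate's. Quartet
induction uses the path-disjointness criterion (ab|cd iff the a–b and c–d
paths share no node), which handles polytomies naturally: a quartet whose
four taxa meet at a single node is unresolved and counts toward no
resolution. Gene trees missing taxa simply contribute no quartets for the
missing subsets, matching summary-method semantics; the score is invariant
to gene-tree rooting.

Search is desk scale by design. Exhaustive enumeration (stepwise addition;
3, 15, 105, 945, 10,395 topologies at 4–8 taxa) guarantees the global
optimum up to 8 taxa, with ties broken by the lexicographically smallest
canonical Newick so results are deterministic. Beyond 8 taxa an NNI
hill-climb runs from a seeded random start (or a supplied tree) until no
neighbour improves; ascent is monotone. The constrained dynamic programming
of production summary methods is deliberately not reimplemented — the
objective is identical and optimality is verifiable at small n, which is
what the test suite exploits. Branch lengths and supports on the supertree
are not estimated.

## Equal-rates Mk model and stochastic mapping

Rate convention: `alpha` is the total leaving rate from any state, split
equally over the k−1 targets (Q_ij = alpha/(k−1)). For k = 2 the per-
direction rate is alpha. Transition probabilities use the closed form
P_same(t) = 1/k + (1−1/k)e^(−λt), λ = alpha·k/(k−1); no matrix
exponentials. The root prior is uniform by default and configurable.

Likelihood is Felsenstein pruning with per-node rescaling of partial
likelihoods (exact to ~1e−9 on the log scale; verified against exhaustive
enumeration over internal-state assignments on trees up to 7 leaves).
Rate fitting is bounded one-dimensional optimization of the log-likelihood
on [0, alpha_max] (default 100) with tolerance 1e−8; a monomorphic
character returns 0 with a boundary flag, and an optimum within tolerance
of either bound is flagged. Note that on small or star-like trees the ER
likelihood can increase monotonically in alpha (the data look saturated),
in which case the MLE sits at the upper bound and the flag should be
heeded; mapping functions accept an explicit rate for that reason.

Marginal node posteriors come from exact up/down passes. Stochastic maps
are sampled in two stages: node states by backward filtering / forward
sampling from the joint conditional distribution, then each branch's
history conditional on its endpoints by uniformization. Under ER the
uniformization rate equals every state's leaving rate, so the auxiliary
jump chain has zero self-transition probability: the conditional jump
count and bridge states have closed-form weights, every sampled jump is a
real state change, and segment durations (uniform order statistics)
exactly partition the branch length. Mapping is "empirical" — run at a
fixed (usually ML) rate rather than integrating over rate uncertainty — so
posterior pies can differ slightly from a fully hierarchical treatment.

Summaries across maps: node posteriors as empirical state frequencies,
expected per-state dwell times, and expected transition counts. Dwell
times sum exactly to total tree length in every map (asserted in tests).

## PGLS

Brownian covariance C[i,j] is the root-to-MRCA path length (diagonal:
root-to-leaf depth). The GLS estimator, residual variance with n−p
denominator, standard errors, t statistics and two-sided p-values (Student
t, n−p df) follow the standard formulas via a Cholesky solve. Each
predictor is fitted in its own simple regression by default — the analysis
this mirrors reports one panel per predictor — with a joint mode available.
Significance is judged at α = 0.05 two-sided without multiple-testing
correction, matching per-predictor reporting. Species with missing fitted
values (or absent from the tree) are dropped with a warning. Identities
exercised in tests rather than assumed: PGLS = OLS on equal-depth star
trees; invariance of t and p to rescaling C; scale equivariance in the
response.

## Genome structure metrics

Coordinates are 1-based inclusive (GFF3). The longest isoform is the
transcript with the maximal summed exon length (ties to the smaller ID).
intron_count = exons − 1; intron_span = Σ(next.start − prev.end − 1), so
intron_span + exon_span equals the transcript's genomic extent. Intergenic
distances are computed per scaffold between adjacent selected-isoform
spans, ignoring strand, excluding scaffold-terminal flanks, and flooring
overlapping pairs at 0 (the conventions are config-visible; flooring is
the simplest defensible default). UTR exons are included when annotated;
datasets lacking UTR annotation should be compared with UTRs excluded on
both sides. N50 is the largest L such that scaffolds ≥ L cover at least
half the span; N% counts N/n bases. Orthologue-pair tables report
log₂ ratios of intron span and intron count, computed as differences of
logs so that swapping the two species negates every value exactly; pairs
with a zero denominator are dropped and tallied.

## Gene-family analysis

Length filtering retains sequences at or above the threshold (default
700 aa — "shorter than" is strict). Duplication nodes are inferred by
species overlap: a node is a duplication iff at least two child subtrees
share a species; without losses this is exact (verified against planted
events in simulation), and with losses sensitivity degrades gracefully
(monitored in simulation, not asserted as a bound). Post-duplication rate
divergence is summarized, per child clade of the duplication node, as the
mean over tips of the path length from the duplication node to the tip
(the child's own branch included) — the reading under which "increased
substitution rates after the duplication" is a per-lineage comparison; a
mean-of-edge-lengths mode is provided as the alternative. Domain counts
(e.g. EGF-like repeats) are mapped as unordered ER states — applying the
equal-rates model directly to the observed count values; an ordered
stepwise model is out of scope. Within-species duplicate tips are flagged
(possible uncollapsed heterozygosity) but never removed automatically.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under a seed and return their ground truth
alongside the data; recovery tests consume only the data.

* Species trees are Yule (pure birth): n−1 split epochs of Exp(k·λ) plus a
  final Exp(n·λ) epoch, giving ultrametric trees with strictly positive
  pendant branches and expected height ∝ 1/λ. Default λ = 4 with ~33
  species gives root-to-tip depths of order one substitution per site,
  the scale of a genus-level protein tree. Real trees are not ultrametric
  in substitution units; none of the implemented analyses require
  ultrametricity.
* Characters evolve forward under the same ER process the inference
  assumes — so character tests probe estimator correctness, not model
  misspecification. Default alpha = 0.5 yields slow characters with a few
  transitions per tree, like presence/absence morphology.
* Traits are X·β + MVN(0, σ²C) with standard-normal predictors; the
  planted β and the Brownian residuals match the PGLS model exactly.
  Defaults (β₁ = 0.8, σ² = 25) put the effect near the detection boundary
  at 24 species.
* Gene families evolve by per-lineage duplication/loss inside the species
  tree; branch lengths follow species-tree time, so simulated families
  carry no rate heterogeneity — post-duplication rate *divergence* is
  exercised on hand-built fixtures instead. Leaves are `species__copyN`.
* Annotations pack genes left to right with Poisson exon counts/lengths
  (means: 5 exons of ~220 bp, ~70 bp introns, ~600 bp intergenic —
  nematode-like compact structure); a fraction of genes get a second,
  shorter isoform, and overlapping genes are optional. Assemblies are
  random sequence with a small N fraction. No repeats, no UTR/CDS
  distinction, no strand-dependent structure: passing tests show the
  *metrics* are computed correctly, not that real annotation pathologies
  are handled.
* Orthogroup tables plant two-copy species in a chosen fraction of
  orthogroups, giving exact expected duplication ratios (e.g. fraction
  0.3 → ratio 1.3).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the checks
exact or statistically tight: enumeration oracles on trees ≤ 7 leaves
(200 cases), 1000 stochastic maps on 6-leaf fixtures, 200 PGLS replicates
at 24 species, 100 supertree replicates at 6 taxa × 20 gene trees, 200
simulated gene families, 500-gene annotations. The demo pipeline runs 12
species end to end in seconds and is byte-reproducible under a fixed seed.

## Known limitations

* No missing/ambiguous tip states in the Mk machinery; no asymmetric or
  hidden-rate models.
* PGLS offers Brownian covariance only (no Pagel's λ or OU transforms).
* Exhaustive supertree search caps at 8 taxa; NNI offers no optimality
  guarantee (its empirical agreement with the exhaustive optimum is itself
  a tested quantity).
* Reconciliation counts duplications only; losses are not inferred.
* The GFF3 reader expects gene/mRNA/exon features with ID/Parent
  attributes; other feature graphs are out of scope.
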