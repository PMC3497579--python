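# Methods

This note documents the models, parameters, numerical choices and known
limitations of each stage, and what the synthetic-data tests do and do
not establish about behaviour on real genome annotations.

## Family attribution

Precursor stem-loops are compared by global-global (end-to-end)
alignment. The scoring scheme is structural: matches score `match`
(default +5), mismatches `mismatch` (−4), a gap of length k costs
`gap_open + (k−1)·gap_extend` (−10/−2, end gaps included), and a match
in which **both** aligned residues are seed-marked scores
`match × seed_multiplier` (default 2). Seed positions are mature
positions 2–8 of each annotated arm, implemented as an expanded
alphabet: seed residues are distinct codes (lower-case internally), and
the substitution matrix over the 10-letter alphabet {A,C,G,U,N} ×
{seed, non-seed} encodes the doubling. `N` matches nothing. The numeric
magnitudes are conventional DNA-scoring values and fully configurable;
only the structure (double weight for in-seed matching) is essential,
and a `seed_mode="either"` variant is provided. Alignment itself runs on
Biopython's `PairwiseAligner` (C implementation); tests verify its
scores against an independent exhaustive enumeration of all gapped
alignments for short sequences.

Families are connected components of the score graph at a threshold
(single-linkage), with deterministic ids (`fam_` + smallest member id).
The threshold is selected by minimising the van Dongen split-join
distance to a reference partition over all distinct observed scores,
tie-breaking toward the larger threshold (more granular partition). The
sweep is incremental: edges are inserted into a union-find in descending
score order and the distance is recomputed only when a merge changed
the partition, so the cost is O(E α(n)) unions plus at most n−1 distance
evaluations. Scores are not length-normalised; the threshold absorbs
scale.

## Profiles and genomic context

Copy number counts loci per (family, species); presence is count > 0.
A miRNA locus is intronic iff strictly contained in a protein locus span
and overlapping no exon — a 1 bp exon overlap disqualifies (exonic/UTR
hosts are a different category this analysis does not treat); nested
hosts resolve to the shortest. Host strand is not required to match
(`require_same_strand` flag available). Clusters chain loci along a
chromosome when the gap `next.start − prev.end − 1` is at most 10 000 bp
(strand-agnostic, single linkage); singletons are solo. Glyph colours:
copy 0 white, 1–9 a fixed 9-step rainbow, ≥ 10 black; the exact
bin-to-colour table is exported with every figure.

A family counts as intronic (clustered) in node statistics when more
than half of its present-day loci are.

## Dollo reconstruction

With one gain and free losses, the most parsimonious scenario is
closed-form: the gain node is the MRCA of presence leaves and the losses
are the maximal presence-free subtrees below it. A brute-force search
over all single-gain internal-state assignments confirms minimality on
random trees. Losses can only make a family look younger: the inferred
gain is always the true gain node or a descendant of it, never an
ancestor — exact when no losses occurred. Node age is the sum of branch
lengths from the root. The figure's red/blue "significant gain/loss"
colouring is presentation only: top/bottom decile of the per-node net
balance (configurable), exported alongside as numbers.

## Birth–death expansions

Family size evolves by a linear birth–death process with equal per-gene
birth and death rate λ (events per gene per unit branch length, i.e.
per substitution/site of the phylogram). Transition probability:

    P(c|s,t) = Σ_{j=0}^{min(s,c)} C(s,j) C(s+c−j−1, s−1)
               α^{s+c−2j} (1−2α)^j,      α = λt/(1+λt)

Size 0 is absorbing. **Numerics:** for λt ≤ 1 every term is
non-negative (1−2α ≥ 0) and the sum is evaluated in log-magnitude form;
for λt > 1 the alternating terms cancel catastrophically in double
precision, so the probability is taken from `expm` of the tridiagonal
generator truncated at a size cap. Consistency across the switch is
verified to 1e−8. The cap defaults to `min(max_size, 2·max_observed+10)`
(max_size 100, hard error above it); truncation sheds upward mass only
for parent sizes near the cap, and rows within a third of the cap hold a
1e−9 normalisation budget.

Likelihood: Felsenstein-style pruning over ancestral sizes with a
uniform root-size prior on 1..root_max (default: largest observed size;
configurable — calibration studies should pass the generative cap). Only
root-present families are analysed (presence MRCA = root, the Dollo
criterion); λ is maximised by bounded scalar optimisation on [0, 10]
(xatol 1e−5, snapped to 0 when the boundary is optimal). Identifiability
is of λt only: doubling all branch lengths exactly halves λ̂.

Expansion p-values are conditional Monte-Carlo: n_sim (default 1000)
families are simulated under λ̂ from the same root prior, **filtered by
the same root-presence criterion as the data**, and a family's p-value
is the add-one-corrected fraction of null families with log-likelihood
at or below its own. The null law depends only on (tree, λ̂, prior), so
one null sample serves all families. The flagged branch is the least
probable parent→child size transition along the max-product (Viterbi)
size assignment. Remaining approximation: λ̂ is plugged in, as in any
parametric bootstrap; calibration tests show KS-uniform null p-values at
the 1% level on 16-leaf trees.

## Correlated evolution

Trait pairs follow a CTMC on {00,01,10,11} (index 2a+b), double
transitions forbidden. Independent model: 4 rates (gain/loss per
trait); dependent: 8 (each transition rate conditioned on the partner's
state); the independent model is the nested special case. Root state
distribution defaults to the chain's stationary distribution
(configurable to uniform or an explicit vector). The independent
likelihood factorises into two 2-state chains with closed-form
transition matrices and is fitted per trait; the equality with 4-state
pruning is asserted by a test. The dependent model is fitted by L-BFGS-B
on log-rates in [1e−6, 100] with multi-start (default 5; one start is
the embedded independent optimum, which guarantees
lnL_dep ≥ lnL_ind up to optimiser tolerance). Fixed (all-present or
all-absent) traits are excluded; pairs with fewer than 5 presences or 5
absences are reported unfitted — associations supported by a handful of
species are uninformative.

LR = 2(lnL_dep − lnL_ind) is referred to χ²(4). On small trees
rate-boundary effects *deflate* the null LR (mean ≈ 2.3 at 16–24
leaves); the nominal mean ≈ 4 is reached around 48 leaves, where the
packaged calibration test runs. The default significance cutoff is the
χ²(4) 0.999 quantile with an optional Bonferroni mode; identical or
complementary profiles are flagged degenerate. Pairwise tests are
independent; no stepwise conditioning between pairs.

## Synteny blocks

Anchors are family-labelled loci (protein + miRNA) ordered per
species-chromosome; exact duplicates are dropped and tandem same-family
anchors collapse to one instance for detection (kept for display). The
detector finds runs pairwise between regions, both orientations, with a
deterministic greedy extension, then merges runs across region pairs by
their canonical family tuple and keeps those covering ≥ `min_regions`
regions (runs contained in a kept run as an either-direction
subsequence with no additional regions are dropped). Between consecutive
run members only **non-shared** anchors may occur (at most
`max_mismatch_anchors` of them, default 10, and at most
`max_gap_length` bp, default 10 000); skipping an anchor whose family
exists in the partner genome ends the run. Under this semantics the
greedy detector provably matches exhaustive enumeration on genomes
related by foreign insertions plus a contiguous rearranged segment
(randomised tests); on genomes shuffled by several interleaved
rearrangements it remains sound (every reported block is a valid common
run) but may not enumerate all overlapping variants. This is a
deliberate simplification of graph-based detectors: the stated
parameters keep their meaning (path dissimilarity → allowed non-shared
insertions), the graph-simplification step has no analogue here, and
genome-rearrangement history is out of scope.

Chaining merges blocks sharing a terminal anchor family when both cover
the same genome set with physically overlapping occurrence spans (the
shared anchor sits in both); it is idempotent. Blocks are classed
protein_only / mixed / mirna_only from member kinds; occurrence lengths
are reported raw and divided by genome size, with cumulative
distribution tables — normalisation makes block-length distributions
comparable between compact and expanded genomes when only intergenic
spacer scales.

## Synthetic data

One integer seed feeds a `SeedSequence`-split stream per stage; every
generator is a pure function of (config, seed). Defaults describe the
study conditions used by the analysis drivers: 10–12 species (Yule tree,
birth rate 1, ultrametric), 30–40 families, root-gain bias 0.3 with the
rest uniform over nodes, per-branch loss probability 0.1, per-site
substitution 0.05 off-seed and 0 in-seed (the constraint
in-seed ≤ off-seed is enforced — seed conservation), duplication rate
0.3 extra copies per unit path length, mean cluster size 2 families,
intra-cluster spacing 2 kb versus a 10 kb cluster threshold, fraction
intronic 0.4, 40 protein families. Precursors are uniform ACGU of
length 60–120 with one 22-nt arm; substitutions replace a site with one
of the other three bases uniformly; tandem copies share the leaf
sequence (recent duplicates). The genome layout is element-based: every
protein gene (20 kb, two 500 bp terminal exons, one large central
intron) or intergenic cluster is an element; elements sit > 2× the
cluster threshold apart, all species share the ancestral element order,
and configured inversions/translocations permute whole elements. Hence
planted clusters are exactly what the 10 kb gap rule recovers, planted
collinear blocks are the per-element anchor runs (elements are farther
apart than the detection gap), and element interiors survive
rearrangement intact. The family-size generator is a separate explicit
Gillespie simulation of the equal-rate birth–death process.

Not modelled: hairpin secondary structure (irrelevant to every
computation here), indels (gap handling is exercised on constructed
fixtures), repeat-driven family origination, genome-quality artifacts,
protein tandem arrays (so the study dataset yields no protein-only
blocks — those require adjacent protein genes within the gap
threshold). Passing tests therefore establish correctness of the
algorithms and calibration of the statistics under the stated generative
assumptions, not robustness to annotation noise or assembly artifacts in
real data.

## Problem sizes

The packaged checks run at sizes chosen to exercise each claim fully:
Dollo oracle equivalence on 500 random trees of ≤ 8 leaves; alignment
oracle on 200 random pairs of length ≤ 8; family recovery at 20 species
× 50 families; split-join metric properties on 1000 random triples of
≤ 10 elements; λ recovery with 200 families on a 16-leaf tree; p-value
calibration with 200+ families and 1000 null draws; LR null calibration
with 200 simulations at 16 leaves (tail bound) and 60 at 48 leaves
(mean); a planted co-evolving pair among 50 screened pairs at 24
species; synteny recovery on 4 genomes with ~80 anchors each. The
acceptance script reruns the same computations at these sizes from a
single command-line seed.
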