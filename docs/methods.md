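# Methods

## The reference species framework and the epoch scale

Dating in this package is *ordinal*: a duplication is placed between two
speciation events, never in absolute time. The packaged reference tree
carries 46 metazoan taxa (25 tetrapods, 5 teleost fish, 16 invertebrates)
with a fixed topology following the conventional metazoan phylogeny. The
named splits on the human root path, root→human, are: sponge, placozoan,
cnidarian (bilaterian/non-bilaterian), protostome–deuterostome,
ambulacrarian, cephalochordate, invertebrate–vertebrate (the tunicate
split; `tunicate-split` is an alias for the same node), teleost–tetrapod,
and amphibian. Branch lengths are an order-consistent set of relative
depths (root = 1.0, leaves = 0); only the ordering is load-bearing, so the
within-tetrapod and within-teleost resolution follows a standard
arrangement without affecting any dating. The hemichordates
(*Saccoglossus*, *Ptychodera*) are placed with echinoderms (Ambulacraria);
since that clade sits entirely between two adjacent named splits on the
human path, the choice cannot move any duplication between bins, but the
tree is configuration data and can be replaced wholesale
(`load_reference_taxonomy`).

Reporting bins: **B1** — older than the invertebrate–vertebrate split
(refined, where possible, by the finer named splits above it); **B2** —
vertebrate stem, i.e. younger than the invertebrate–vertebrate and older
than the teleost–tetrapod split; **B3**/**B4** — confined to the teleost /
tetrapod clade. A duplication among non-vertebrate side lineages only
(e.g. within flies) falls into an `off-path` overflow bin. Because the
sampled vertebrates are all bony fish or tetrapods, every duplication on
the human root path or inside a vertebrate subclade lands in exactly one
of B1–B4.

## Catalog and fold classification

A family's *fold* is the number of distinct target chromosomes
({1, 2, 8, 20} by default) carried by its members; chromosome tokens are
parsed from cytogenetic bands (`"1p36.13-p36.12"` → `"1"`). Members off
the target set (e.g. STK26 on X) remain in the family — they matter for
phylogenetics and are read as translocated copies — but contribute no
fold. The packaged census: 25 families, 125 genes, 3 quadruplicated
(CHRN, E2F, FAM110), 22 triplicated. The per-family "sequences included"
column sums to 1604. A companion fixture lists the four previously
analyzed families that the co-duplication figure names (MATN, EYA, HCK,
KCNS) with chromosome labels only; their member tables live in the
earlier companion study.

## Alignment handling

Input is aligned amino-acid FASTA with `species|gene|chrN` headers.
Trimming is complete deletion: a column is removed if any row holds `-`
or a non-standard letter (`X` counts as missing). The rule is mechanical;
no further "unambiguous region" masking is attempted. Trimming is
idempotent and shrinks length unless the alignment is already clean.

## Distances, neighbor joining, bootstrap, rooting

The default distance is the uncorrected p-distance; the Poisson
correction −ln(1−p) is offered as the model-corrected alternative
(saturated pairs, p = 1, are a hard error naming the pair). Pairwise
maximum-likelihood distances under empirical substitution matrices are
out of scope; topology, not branch length, drives every downstream step.

Neighbor joining is the standard Saitou–Nei agglomeration, joining the
pair minimizing Q(i,j) = (r−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k). Two
numerical policies make it fully deterministic: ties in Q resolve to the
lexicographically smallest pair index in the current matrix, and a
negative branch length is clamped to zero with the length transferred to
its sibling so the pair's span is preserved. The unrooted result has a
trifurcating pseudo-root. On additive (tree-metric) inputs the generating
topology is recovered exactly; the test suite verifies this against an
exhaustive least-squares topology search (all 3–105 unrooted topologies
for n ≤ 6, branch lengths by non-negative least squares) and
cross-checks against an independent NJ implementation.

Bootstrap support resamples alignment columns with replacement B times
(default 1000, configurable; tests use 50–200), rebuilds the NJ tree, and
annotates each internal branch of the point tree with the percentage of
replicates containing its bipartition. All resampling flows from an
explicit seed. Supports are attached to bipartitions, so they survive
rerooting unchanged.

Rooting places the root on the edge separating a designated outgroup from
the rest. A non-monophyletic outgroup falls back to the edge whose side
is purest in outgroup leaves — ties broken by the number of outgroup
leaves captured, then by preorder — with a warning. The pipeline chooses
as outgroup the sequences of the *earliest-diverging* invertebrate
lineage present (e.g. the sea anemone when sampled), not every
invertebrate: when a duplication predates parts of the invertebrate
grade, "all invertebrates" is not a clade of the true gene tree and
rooting with it is ill-posed, while the most distant sampled lineage
remains a valid outgroup.

Discordance screening formalizes the removal of sequences placed against
the conventional animal history: a leaf is flagged if deleting it
strictly decreases the number of duplication nodes dated to B1 (a
misplaced invertebrate inside a vertebrate clade manufactures exactly
such cross-divide duplications). The scan is greedy, one pass, in
deterministic label order, and only flags — the caller decides whether
to drop.

## Duplication detection and dating

An internal node is a duplication iff its child subtrees share at least
one species (for multifurcations: iff any two children share one). No
losses are inferred; this is deliberately weaker than full
reconciliation but deterministic and faithful to dating by inspection of
branching order. The younger bound of a duplication is the split at the
LCA (on the species tree) of the species of its duplicated copies; the
older bound is the LCA after adding the species of the sister subtree
above the node in the gene tree, and the gene-tree root is unbounded
above. When the bounds straddle a bin boundary the event is assigned by
its younger bound and flagged `ambiguous-interval` ("at least prior to"
semantics). The support filter keeps events with bootstrap support
strictly above the threshold (default 50%, configurable — the boundary
of "strong support" is not asserted); root events carry no bipartition
support and are retained flagged rather than discarded. Histograms report
per-family and total counts per bin, families alphabetical.

## Schematic topologies and co-duplication groups

A family qualifies for congruence analysis with ≥ 2 duplications dated to
the focal window (default B2, the proposed 2R window); others are
excluded and reported, mirroring the published selection rule. The gene
tree is restricted to human paralogs, every internal node that is not a
window duplication is collapsed (children splice upward, possibly
creating polytomies), leaves are relabeled with chromosomes, and
same-chromosome leaves under one node merge to a single leaf. A schematic
is *symmetric* iff it has the `((A,B),(C,D))` shape; all other shapes
count as asymmetric.

The translocation distance between two schematics is the minimum number
of leaf relabelings turning one into the other under the best rooted-tree
isomorphism, computed exactly by exhaustive matching (the trees are
tiny). Subtrees of different shapes never match — `((1,2),3)` vs
`((1,2),(3,4))` is incongruent (∞) — with one relaxation: when two
matched internal nodes differ in arity, the shorter child list is padded
with wildcard leaves and each surplus *leaf* absorbed at cost 1. This
reads surplus paralog leaves as extra translocated/duplicated copies
while still refusing to equate a leaf with a whole subtree. The distance
is verified against brute-force enumeration of all label substitutions.

Groups are connected components of the pairwise congruence graph
(distance ≤ allowance k). Two design choices matter. First, connected
components accept the non-transitivity of the pairwise predicate; any
intra-group pair exceeding its allowance is reported, never silently
absorbed. Second, co-duplication requires *physical linkage* as well as
topological congruence — with only three or four leaves over a shared
chromosome alphabet, unrelated families are often within two relabelings
of each other, so topology alone cannot certify joint origin. The
clustering therefore accepts an optional linkage map (family → synteny
block, taken from the catalog, never recomputed) restricting which pairs
are candidates, and the allowance may be given per block. The packaged
16-family panel encodes the published schematic types, synteny blocks and
per-block allowances (3, 2, 5, 4); the leaf labels within each family
were fixed from its chromosome locations and the published composite
types, since per-family assignments are under-determined by the composite
notation. Clustering this panel computes four groups — one symmetric,
three asymmetric — with every distance evaluated, not assumed.

## The simulator and what the tests do (and do not) show

`two_round_WGD` duplicates every family at the same two points on the
vertebrate stem (relative positions 0.35 and 0.65), giving 1 → 2 → 4
copies, i.e. three duplication nodes per family, all in B2;
`independent_SD` assigns each family an era round-robin over
{bilaterian stem, olfactores stem, vertebrate stem, teleost stem,
tetrapod stem} and draws two event times uniformly within it; `mixed`
combines both. Copies are born onto chromosomes 1, 2, 8, 20 in order;
each new copy may translocate to a random other chromosome with a
configurable probability, and lineages may be lost per event with a
configurable probability (conditioned on family survival). The preset
defaults are the clean embodiments of the two hypotheses — loss 0,
translocation 0 — because the contrast under test is between histories,
not noise levels; both knobs are exercised in unit tests. Simulations use
a 10-species panel (4 tetrapods, 2 teleosts, 4 invertebrates) spanning
every named split needed for dating; the pruned reference tree keeps
cumulative depths, so the split order is unchanged.

Sequences evolve i.i.d. per site under the equal-exchange (Poisson)
model: along a branch of length b a site differs from its ancestor with
probability (19/20)(1 − e^{−(20/19)·r·b}) (rate r = 0.3 per unit depth by
default, giving roughly 40% pairwise divergence across the deepest
splits), substitutions uniform over the other 19 residues, no indels and
no rate heterogeneity. Alignment length defaults to 1000.

Consequently the recovery experiment shows that the *inference chain* is
correct and well-calibrated under its own generative assumptions — it
does not show robustness to alignment error, rate heterogeneity across
sites or lineages, gene conversion, or hidden paralogy, all of which
affect real protein families. One known fragility is visible even in the
clean setting: when the two WGD rounds fall close together, neighbor
joining occasionally resolves the short inner branches into a caterpillar
rather than the symmetric quartet, and that family then (correctly, given
its estimated tree) fails congruence with the rest — the partition ARI
under the 2R preset averages ≈ 0.85 rather than 1.0. The published
headline tallies that depend on database-harvested ortholog sets (total
duplication counts per bin, per-family counts) are outside what synthetic
data can reproduce and are not asserted anywhere.

## Numerical and degenerate-input policies

Ragged alignments, unknown header species, non-amino-acid characters,
empty post-trim alignments, matrices that are asymmetric or have nonzero
diagonals, fewer than three taxa for NJ, saturated pairs under the
Poisson correction, outgroups equal to the full leaf set, unrooted input
to duplication detection, undated events in histograms, and unknown era
names in scenarios are all hard errors with specific messages. All
randomness (bootstrap, simulation, sequence evolution) derives from
explicit seeds; identical configuration and seed give byte-identical
trees, event tables and group reports.
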