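# Methods

## Data model

A tree is stored as a leafset plus its set of *non-trivial* splits
(`LeafTree`). Trivial splits — one leaf against the rest — are implied
by the leafset and never stored; they are materialised on demand
(`all_splits()`) where a definition needs them, notably in subsplit
mining. Stored splits must be pairwise compatible under the standard
four-intersection rule (two same-leafset splits coexist in a tree iff
one of the four pairwise side intersections is empty), and a tree on
`n` leaves carries at most `n − 3` of them, with equality exactly for
binary trees. Splits are unordered bipartitions, canonicalised by
putting the lexicographically smaller side first.

Trees with at most three leaves have empty split sets, so all distances
between same-leafset trees of ≤ 3 leaves are 0.

### Editing operations

*Contraction* removes one non-trivial split; contracting a trivial
split is rejected, because it would delete a labelled leaf rather than
an internal edge. *Pruning* removes a leaf from every split and then
discards the splits that became invalid, trivial, or duplicates of a
surviving split; each discarded non-trivial split is one *forced
contraction*, and the count always equals the drop in the non-trivial
split count. Restriction to a leafset `z` equals pruning the complement
in any order; order-independence of whole operation sequences (any
applicable reordering of a subscript yields the same tree) is a
property the test suite checks by shuffling scripts.

## Distances

**Robinson–Foulds** is the cardinality of the symmetric difference of
the non-trivial split sets and requires one common leafset.

**MAST distance.** The agreement search maximises `|x|` over
`x ⊆ L1 ∩ L2` with `T1|x = T2|x`, by memoised leaf-removal over
subsets. On free leafsets the distance is `|L1 ∪ L2| − |x*|`: every
removed leaf counts once, whether it was present in one tree or both.
This is the convention that makes the documented worked examples come
out (1 for the five/four-leaf pair, 2 for the eight-leaf pair); the
alternative of counting a doubly-removed leaf twice is deliberately not
implemented. Among maximum agreement leafsets the lexicographically
smallest is reported; the distance itself is tie-free.

**Edit distance.** The optimum never contracts a split shared by both
trees, and operation order is irrelevant, so the search can prune
first: leaves private to one tree must be pruned from it (phase 1,
`cost_p` plus charged forced contractions each). On the shared leafset
(phase 2) the minimum is either the contraction-only endgame
`cost_c · d_RF` or, for some shared leaf, pruning it *from both trees*
(`2·cost_p` plus forced contractions) and recursing. States are
memoised on the remaining leafset — at most `2^|L|` states, perfectly
adequate below ~17 leaves, which is this package's intended scale.
An optimal script is reconstructed along the argmin path. Ties prefer
the contraction-only endgame, then the lexicographically smallest leaf:
the distance is unique, the reported script is one optimum among
possibly several. Costs are compared with absolute tolerance `1e-9`;
integer-valued cost models stay exact.

**NFC** is the same recursion with the forced-contraction charge set to
zero. It is exposed as a dissimilarity, not a metric (zero cost for
forced contractions breaks the positivity argument), and nothing in the
package assumes metric axioms for it.

**p-distance / c-distance.** The pruning-only unification cost
enumerates agreement leafsets and charges `cost_p` per leaf removal
*per tree* plus `cost_c` per forced contraction; the c-distance is
`cost_c · d_RF`. The per-tree accounting mirrors the `2·cost_p` charge
of the edit recursion and is the one consistent with the documented
eight-leaf worked example (p-distance 12 at pruning cost 2). A
once-per-leaf accounting (closer to how MAST counts) would give
different values and is not provided.

## Consensus

Strict consensus intersects the split sets; majority-rule keeps splits
occurring in strictly more than half the trees (such splits are
necessarily pairwise compatible — asserted in tests). The tree edit
consensus generalises the pairwise recursion: leaves absent from at
least one tree are first pruned from every tree that carries them
(`cost_p` per carrying tree plus forced contractions); then the
minimum is taken over the contraction endgame — reduce every tree to
the strict consensus of the current restrictions, `cost_c` per
non-shared split — and over pruning one shared leaf from *all* `n`
trees (`n·cost_p` plus forced contractions) followed by recursion.
For `n = 2` this provably coincides with the edit distance, which the
tests use as the main validation, together with the limit
`cost_p → ∞` giving the strict consensus.

The tree edit consensus is not unique. The implementation returns the
tie-broken optimum (same tie-breaks as the edit distance);
`enumerate_tec_optima` lists all co-optimal unification trees. Note
that a natural-looking unification — e.g. pruning two leaves until the
trees coincide — can be strictly more expensive than the optimum that
mixes pruning and contraction; the minimal-cost definition is taken as
normative, so the returned consensus may differ from such hand-built
unifications.

## Representative splitsets

Support of a split in a profile counts *trees* in which it is a
subsplit of at least one split (trivial splits included as potential
supersplits), not the number of supersplits. Mining uses closure under
pairwise *maximal common restrictions*: for `A|B` and `C|D`, every
common subsplit is dominated by the restriction to `(A∩C)∪(B∩D)` or to
`(A∩D)∪(B∩C)`, so folding these candidate generators across the trees
and discarding dominated candidates yields exactly the maximal common
subsplits. For minsup = 100% one fold suffices; for general minsup the
fold is applied to every qualifying tree subset and the union is
re-maximalised — combinatorial, but the profiles this package targets
are small, and the implementation is checked against a brute-force
oracle that enumerates every restriction of every observed split.
`minsup` is accepted as a fraction in (0, 1] or as an absolute tree
count; an integral value passed as `int` is read as absolute.

Visualisation builds one tree per distinct member leafset `z` (from the
`z`-restrictions of all members whose leafset contains `z`) plus one
tree on the intersection of those leafsets, deduplicated when the
intersection already occurs. Above 50% support any two members are
restrictions of splits co-occurring in some tree, hence compatible;
below that the construction is refused.

The FS dissimilarity is `1 − |SFS(T1,T2)| / |S1 ⊎ S2|`, where `⊎`
collapses sub/supersplit pairs across the two full splitsets onto the
supersplit. Trivial splits count in both numerator and denominator;
dropping them would break the identity `d(T, T) = 0` for stars and the
documented worked value `1 − 6/9` for five-leaf trees sharing the
subsplit `ab|cd`.

## Simulation

Binary trees are generated by sequential uniform edge attachment
(start from the three-leaf star; attach each next leaf to a uniformly
chosen edge), which is uniform over labelled unrooted binary
topologies — verified in the tests by a 4σ frequency check over all 15
five-leaf shapes. Any exchangeable generator would satisfy the harness
contract; this one is chosen for simplicity and uniformity.
"Unconstrained" trees contract each internal edge of a binary draw
independently with probability `contraction_prob` (default 0.25 — no
canonical value exists, this gives a realistic mix of polytomies
without collapsing most trees to stars; it is an exposed parameter).
Free-leafset draws take the leaf count uniform on `[4, n_leaves]` and
sample labels from the universe.

Mutations: contraction removes `k` distinct uniformly chosen
non-trivial splits; pruning removes `k` uniformly chosen leaves (at
least four leaves must remain); NNBI (nearest non-brother interchange)
swaps the labels of a uniformly chosen pair of non-sibling leaves at
minimal topological distance — a change that one contraction per tree
or one pruning per tree can level when the swapped cousins are three
edges apart, so it probes both operation families at once while
keeping the leafset fixed (unlike using prunings as mutations, which
makes R-F inapplicable).

The distribution experiment feeds the identical pair stream to every
measure so value ranges are comparable; R-F on a pair with differing
leafsets is recorded at its maximum `|S1| + |S2|` (a reporting
convention for the free-leafset histograms, not a claim that R-F is
defined there). The dynamics experiment reports the mean distance per
mutation count `k`; under contraction mutations the unit-cost edit
distance equals `k` identically, and under pruning mutations the MAST
distance equals `k` identically — both are exercised as exact, not
merely on-average, properties.

What the generators do *not* emulate: branch lengths, non-uniform
topology distributions induced by real inference, correlated error
between trees of a profile, and taxon sampling that is biased rather
than uniform. Passing tests therefore demonstrate combinatorial
correctness and the claimed statistical behaviours under these null
models, not performance on any empirical tree collection.

## Problem sizes and budgets

The exact algorithms are exponential, so the shipped experiments and
tests run at desk scale, chosen to finish in seconds to a few minutes:
worked examples at 4–9 leaves; metric-axiom checks on 200 random
free-leafset triples at ≤ 7 leaves; brute-force cross-validation on
all pairs from the 26 five-leaf trees plus a 20-tree six-leaf sample;
distribution experiments on 1000 binary eight-leaf pairs. Beyond
roughly 17 leaves the `2^|L|` state spaces of the edit/MAST searches
become impractical; polynomial-time MAST and any faster edit-distance
algorithm are out of scope.

## Known limitations

* Exponential exact searches only (by design, see above).
* Edit scripts and consensus trees are reported for one optimum;
  co-optimal scripts are not enumerated (co-optimal TEC trees are).
* The NFC measure's metric status is unresolved; it is treated as a
  dissimilarity throughout.
* Branch lengths, rooted semantics and internal node labels are out of
  scope; Newick input discards them.
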