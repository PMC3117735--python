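# leafdist

Distance measures, consensus methods and frequent-subsplit mining for
**unrooted leaf-labelled trees on free leafsets** — trees whose leaves
carry labels (taxa, genes, languages), whose internal nodes do not, and
whose leafsets are allowed to differ between trees. Such trees arise
whenever competing evolutionary hypotheses must be compared: gene trees
with unequal taxon sampling, bootstrap replicates, alternative
reconstructions of the same family.

Classical comparison tools each see only half the picture. The
Robinson–Foulds distance counts the symmetric difference of the split
sets, `d_RF(T1, T2) = |S(T1) Δ S(T2)|`, but is undefined across
leafsets and is maximised by a single misplaced leaf. The MAST distance
counts the leaves that must be removed to reach a maximum agreement
subtree, but it ignores internal-edge disagreement and the edge
collapses that leaf removal causes.

`leafdist` centres on a **tree edit distance** built from the two
natural editing operations on leaf-labelled trees:

* **contraction** `c(s)` — removal of an internal edge, i.e. of one
  non-trivial split `s`, at cost `cost_c`;
* **pruning** `p(x)` — removal of a leaf `x`, at cost `cost_p`; splits
  that degenerate in the process (become trivial or duplicate another)
  are removed as **forced contractions** `fc(s)`, each charged at
  `cost_c`.

`E(cost_c, cost_p)(T1, T2)` is the minimal total cost of a pair of
operation sequences that transform both trees into one common tree. With
positive costs and charged forced contractions it is a metric; the
variant `NFC(cost_c, cost_p)` that charges nothing for forced
contractions is a useful dissimilarity (its response to mutations is
nearly independent of the mutation type). R-F and MAST are the limiting
behaviours: with prohibitively expensive pruning, `E` reduces to
`cost_c · d_RF`; a pruning-only search gives the p-distance analogous to
MAST with forced contractions accounted.

The package also provides:

* strict and majority-rule consensus, plus the **tree edit consensus**
  (the common tree reached by the jointly cheapest edit scripts of a
  whole profile);
* **representative splitsets**: the maximal subsplits frequent in at
  least `minsup` of the trees of a profile (trees are counted, not
  splits), their visualisation as one tree per member leafset, and the
  derived FS dissimilarity `1 − |SFS(T1,T2)| / |S1 ⊎ S2|`;
* a simulation harness (uniform random binary and multifurcating trees;
  contraction / pruning / nearest non-brother interchange mutations)
  for studying distance distributions and dynamics.

All search algorithms are exact and exponential in the leaf count
(memoised on leaf subsets); they are intended for the tens-of-leaves
scale, not for genome-scale trees.

## Worked example

Two eight-leaf caterpillars that differ only in the placement of leaf
`d` (and one internal edge) share no non-trivial split at all:

```python
from leafdist import CostModel, edit_distance, mast, rf_distance, tree_from_newick

t1 = tree_from_newick("(g,h,(f,(e,(a,(b,(c,d))))));")
t2 = tree_from_newick("(f,g,(d,(h,(e,(a,(b,c))))));")

print(rf_distance(t1, t2))                              # 10
print(mast(t1, t2).distance)                            # 2
res = edit_distance(t1, t2, CostModel(cost_c=1, cost_p=1))
print(res.distance)                                     # 6.0
print("; ".join(map(str, res.script.subscript1)))
# p(d); fc(a b e f g h|c); c(a b c e f|g h)
print("; ".join(map(str, res.script.subscript2)))
# p(d); fc(a b c e h|f g); c(a b c e h|f g)
```

R-F declares the trees maximally different (all 10 non-trivial splits
must go). The edit distance instead prunes the one noisy leaf `d` from
both trees (cost 2), absorbs the two forced contractions that this
triggers (cost 2), and contracts the two remaining differing edges
(cost 2): total 6, with the script shown above. MAST reports 2 but is
blind to the forced contractions. Raising the pruning cost re-weights
the trade-off: `E(1,2)` gives 8, and at `E(1,3)` pruning no longer pays
and the distance equals the R-F value 10.

The same computations from the shell:

```sh
leafdist dist --measure rf       tests/data/noisy_leaf_t1.txt tests/data/noisy_leaf_t2.txt   # 10
leafdist dist --measure edit     tests/data/noisy_leaf_t1.txt tests/data/noisy_leaf_t2.txt   # 6
leafdist dist --measure "E(1,2)" tests/data/noisy_leaf_t1.txt tests/data/noisy_leaf_t2.txt   # 8
```

Trees are read either as Newick (branch lengths and internal labels
ignored, polytomies fine) or as split files — one split per line, sides
separated by `|`, blank lines separating trees.

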