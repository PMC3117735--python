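"""Small worked-example trees used in the documentation and tests.

Each constant is a :class:`~leafdist.splits.LeafTree` built from an
explicit non-trivial splitset (trivial splits are implied).  The pairs
illustrate the situations where the classical distances disagree with
the edit distance: a simple refinement, a pruned leafset, two
caterpillars differing in one split, two nine-leaf trees on different
leafsets, and an eight-leaf pair where one misplaced leaf destroys
every shared split.
"""

from __future__ import annotations

from .splits import LeafTree, split_from_text


def _tree(leaves: str, *splits: str) -> LeafTree:
    return LeafTree(set(leaves), {split_from_text(s) for s in splits})


#: Five-leaf tree and its one-contraction coarsening: T2 is T1 with the
#: internal edge abe|cd removed.  R-F, MAST and unit-cost edit distance
#: all equal 1 on this pair.
REFINEMENT_T1 = _tree("abcde", "a b | c d e", "a b e | c d")
REFINEMENT_T2 = _tree("abcde", "a b | c d e")

#: REFINEMENT_T1 with leaf d pruned (the pruning forces one
#: contraction): a four-leaf tree on {a, b, c, e}.
PRUNED_QUARTET = _tree("abce", "a b | c e")

#: Two six-leaf caterpillars sharing all but their innermost split;
#: their strict consensus keeps ab|cdef and abc|def.
CATERPILLAR_T1 = _tree("abcdef", "a b | c d e f", "a b c | d e f", "a b c d | e f")
CATERPILLAR_T2 = _tree("abcdef", "a b | c d e f", "a b c | d e f", "a b c e | d f")

#: Two nine-leaf caterpillars on different leafsets (i only in the
#: first, j only in the second); their strict representative splitset
#: has twelve members on two distinct leafsets.
NINE_LEAF_T1 = _tree(
    "abcdefghi",
    "c d | a b e f g h i",
    "b c d | a e f g h i",
    "a b c d | e f g h i",
    "h i | a b c d e f g",
    "g h i | a b c d e f",
    "f g h i | a b c d e",
)
NINE_LEAF_T2 = _tree(
    "abcdefghj",
    "b c | a d e f g h j",
    "a b c | d e f g h j",
    "a b c d | e f g h j",
    "h j | a b c d e f g",
    "g h j | a b c d e f",
    "f g h j | a b c d e",
)

#: Two eight-leaf caterpillars that share no non-trivial split because
#: leaf d sits at opposite ends -- the showcase for the edit distance:
#: R-F is maximal (10) although pruning d leaves only two differing
#: splits.
NOISY_LEAF_T1 = _tree(
    "abcdefgh",
    "g h | a b c d e f",
    "f g h | a b c d e",
    "e f g h | a b c d",
    "a e f g h | b c d",
    "a b e f g h | c d",
)
NOISY_LEAF_T2 = _tree(
    "abcdefgh",
    "f g | a b c d e h",
    "d f g | a b c e h",
    "d f g h | a b c e",
    "d e f g h | a b c",
    "a d e f g h | b c",
)
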