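"""Frequent-subsplit mining and the derived dissimilarity measure.

A split ``s`` is *frequent* in a profile at minimal support ``minsup``
when it is a subsplit of at least one split (trivial splits included)
in at least ``minsup`` of the trees -- trees are counted, not splits.
The *representative splitset* keeps only the maximal frequent
subsplits: no member has a frequent proper supersplit.  ``minsup`` of
100% gives the strict representative splitset (SFS), 50% the
majority-rule one (MRFS).

Because members generally live on different leafsets, a representative
splitset is visualised as one tree per distinct member leafset (built
from the restrictions of the members covering it) plus one tree on the
intersection of those leafsets; at minsup above 50% the restricted
members are guaranteed pairwise compatible.

Mining works by closure under pairwise maximal common restrictions:
for splits ``A|B`` and ``C|D`` every common subsplit is dominated by
one of the restrictions to ``(A&C)|(B&D)`` or ``(A&D)|(B&C)``, so
folding this across trees and discarding dominated candidates yields
exactly the maximal common subsplits.  Support anti-monotonicity (a
subsplit of a frequent split is frequent) makes the fold complete for
general minsup via tree subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil

from .splits import LeafTree, Profile, Split, is_subsplit, restrict_split

__all__ = [
    "SupportedSplit",
    "RepresentativeSplitset",
    "support",
    "representative_splitset",
    "splitset_to_trees",
    "fs_dissimilarity",
]


@dataclass(frozen=True)
class SupportedSplit:
    split: Split
    support_count: int
    support_fraction: float


@dataclass(frozen=True)
class RepresentativeSplitset:
    """Maximal frequent subsplits of a profile with their supports."""

    minsup: float
    min_count: int
    n_trees: int
    splits: frozenset

    def member_splits(self) -> frozenset:
        return frozenset(m.split for m in self.splits)


def _occurs_in(s: Split, t: LeafTree) -> bool:
    if not s.leafset <= t.leafset:
        return False
    return any(is_subsplit(s, u) for u in t.all_splits())


def support(s: Split, p: Profile) -> SupportedSplit:
    """Number (and fraction) of profile trees containing ``s`` as a
    subsplit of at least one of their splits, trivial ones included."""
    count = sum(1 for t in p.trees if _occurs_in(s, t))
    return SupportedSplit(s, count, count / len(p))


def _common_candidates(s1: Split, s2: Split):
    a, b = s1.side_a, s1.side_b
    c, d = s2.side_a, s2.side_b
    for x, y in ((a & c, b & d), (a & d, b & c)):
        if x and y:
            yield Split(x, y)


def _maximalize(cands: set) -> set:
    out = set()
    for s in cands:
        if not any(c != s and is_subsplit(s, c) for c in cands):
            out.add(s)
    return out


def _fold(trees) -> set:
    """Maximal splits that are subsplits of some split in every tree."""
    current = set(trees[0].all_splits())
    for t in trees[1:]:
        nxt: set = set()
        tsplits = t.all_splits()
        for c in current:
            for s in tsplits:
                nxt.update(_common_candidates(c, s))
        current = _maximalize(nxt)
        if not current:
            break
    return current


def _required_count(minsup, n: int) -> int:
    if isinstance(minsup, int) and not isinstance(minsup, bool) and minsup >= 1:
        k = minsup
    else:
        if not 0 < minsup <= 1:
            raise ValueError("relative minsup must lie in (0, 1]")
        k = ceil(minsup * n)
    if not 1 <= k <= n:
        raise ValueError(f"minsup {minsup!r} out of range for {n} trees")
    return k


def representative_splitset(p: Profile, minsup=1.0) -> RepresentativeSplitset:
    """Mine the maximal frequent subsplits of a profile.

    ``minsup`` is a fraction in (0, 1] or an absolute tree count.  An
    integral ``minsup`` given as an ``int`` is read as absolute; 1.0 as
    a float means 100%.
    """
    n = len(p)
    k = _required_count(minsup, n)
    if k == n:
        cands = _fold(p.trees)
    else:
        cands = set()
        for subset in combinations(p.trees, k):
            cands.update(_fold(list(subset)))
        cands = _maximalize(cands)
    members = frozenset(support(s, p) for s in cands)
    return RepresentativeSplitset(
        minsup=(k / n), min_count=k, n_trees=n, splits=members
    )


def splitset_to_trees(rs: RepresentativeSplitset) -> list:
    """One tree per distinct member leafset, plus the intersection tree.

    Requires minsup > 50%, which guarantees that the restricted members
    on any shared leafset are pairwise compatible and hence form a
    tree.  Every member appears, in restricted form, in at least one
    output tree.
    """
    if 2 * rs.min_count <= rs.n_trees:
        raise ValueError("tree visualisation requires minsup > 50%")
    members = sorted(rs.member_splits())
    if not members:
        raise ValueError("empty representative splitset")
    leafsets = {m.leafset for m in members}
    inter = frozenset.intersection(*leafsets)
    ordered = sorted(leafsets, key=lambda z: (-len(z), tuple(sorted(z))))
    if inter and inter not in leafsets:
        ordered.append(inter)
    trees = []
    for z in ordered:
        kept = set()
        for m in members:
            if z <= m.leafset:
                r = restrict_split(m, z)
                if r is not None and not r.is_trivial():
                    kept.add(r)
        try:
            trees.append(LeafTree(z, kept))
        except ValueError as exc:  # pragma: no cover - excluded by minsup > 50%
            raise RuntimeError(f"incompatible restricted members on {sorted(z)}") from exc
    for m in members:  # every member is visible, at least on its own leafset
        assert any(
            t.leafset == m.leafset
            and (m.is_trivial() or m in t.nontrivial_splits)
            for t in trees
        )
    return trees


def _modified_union(t1: LeafTree, t2: LeafTree) -> set:
    """Union of both full splitsets, sub/supersplit pairs collapsed to
    the supersplit."""
    u = set(t1.all_splits()) | set(t2.all_splits())
    return {s for s in u if not any(c != s and is_subsplit(s, c) for c in u)}


def fs_dissimilarity(t1: LeafTree, t2: LeafTree) -> float:
    """``1 - |SFS(t1, t2)| / |S1 (+) S2|`` with trivial splits counted
    on both sides of the fraction; in [0, 1], 0 iff equal splitsets."""
    sfs = representative_splitset(Profile([t1, t2]), 1.0)
    return 1.0 - len(sfs.splits) / len(_modified_union(t1, t2))
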