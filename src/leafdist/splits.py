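"""Split algebra for unrooted leaf-labelled trees.

An unrooted tree whose leaves carry labels (and whose internal nodes do
not) is fully described by its leafset together with the set of
*splits* -- the bipartitions of the leafset induced by deleting one
edge.  Splits with a single leaf on one side (*trivial* splits) are
implied by the leafset, so a :class:`LeafTree` stores only the
non-trivial ones.  All higher-level machinery in this package
(distances, consensus, subsplit mining, simulation) is built on the two
elementary editing operations defined here:

* **contraction** -- removal of an internal edge, i.e. of one
  non-trivial split;
* **pruning** -- removal of a leaf; splits that degenerate in the
  process (become trivial, or duplicate a surviving split) are dropped
  as *forced contractions* and counted.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

__all__ = [
    "Split",
    "LeafTree",
    "Profile",
    "PruneResult",
    "restrict_split",
    "restricted_equal",
    "is_subsplit",
    "is_compatible",
    "contract",
    "prune",
    "restrict_tree",
    "tree_from_newick",
    "tree_to_newick",
    "trees_from_newick",
    "trees_to_newick",
    "trees_from_split_text",
    "trees_to_split_text",
    "split_from_text",
]

_FORBIDDEN = set('|(),;')


def _check_label(label: str) -> str:
    if not label or any(ch.isspace() or ch in _FORBIDDEN for ch in label):
        raise ValueError(f"invalid leaf label: {label!r}")
    return label


class Split:
    """An unordered bipartition ``A|B`` of a leafset.

    Both sides must be non-empty and disjoint.  ``Split(A, B)`` and
    ``Split(B, A)`` compare (and hash) equal; the canonical order used
    for printing puts the lexicographically smallest side first.
    """

    __slots__ = ("_a", "_b")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides of a split must be non-empty")
        if a & b:
            raise ValueError(f"split sides overlap: {sorted(a & b)}")
        for lab in a | b:
            _check_label(lab)
        if tuple(sorted(a)) > tuple(sorted(b)):
            a, b = b, a
        self._a = a
        self._b = b

    @property
    def side_a(self) -> frozenset:
        return self._a

    @property
    def side_b(self) -> frozenset:
        return self._b

    @property
    def leafset(self) -> frozenset:
        return self._a | self._b

    def is_trivial(self) -> bool:
        return min(len(self._a), len(self._b)) == 1

    def smaller_side(self) -> frozenset:
        return self._a if len(self._a) <= len(self._b) else self._b

    def __eq__(self, other) -> bool:
        if not isinstance(other, Split):
            return NotImplemented
        return self._a == other._a and self._b == other._b

    def __hash__(self) -> int:
        return hash((self._a, self._b))

    def _key(self):
        return (tuple(sorted(self._a)), tuple(sorted(self._b)))

    def __lt__(self, other: "Split") -> bool:
        return self._key() < other._key()

    def __repr__(self) -> str:
        return f"Split({self})"

    def __str__(self) -> str:
        return "{}|{}".format(" ".join(sorted(self._a)), " ".join(sorted(self._b)))


def split_from_text(text: str) -> Split:
    """Parse ``"a b | c d"`` (labels whitespace-separated, sides by ``|``)."""
    parts = text.split("|")
    if len(parts) != 2:
        raise ValueError(f"a split needs exactly one '|': {text!r}")
    return Split(parts[0].split(), parts[1].split())


def restrict_split(s: Split, z: Iterable[str]) -> Optional[Split]:
    """Restriction of ``s`` to leafset ``z``; ``None`` if a side empties.

    The result may be trivial.
    """
    z = frozenset(z)
    a = s.side_a & z
    b = s.side_b & z
    if not a or not b:
        return None
    return Split(a, b)


def restricted_equal(s1: Split, s2: Split, z: Iterable[str]) -> bool:
    """Whether the two splits have equal, defined restrictions on ``z``."""
    z = frozenset(z)
    r1 = restrict_split(s1, z)
    r2 = restrict_split(s2, z)
    return r1 is not None and r1 == r2


def is_subsplit(s1: Split, s2: Split) -> bool:
    """Whether ``s1`` is a subsplit of ``s2``.

    ``s1`` is a subsplit of ``s2`` when ``leafset(s1) <= leafset(s2)``
    and ``s2`` restricted to ``leafset(s1)`` equals ``s1``.  Reflexive.
    """
    if not s1.leafset <= s2.leafset:
        return False
    return restrict_split(s2, s1.leafset) == s1


def is_compatible(s1: Split, s2: Split) -> bool:
    """Four-intersection compatibility test for same-leafset splits.

    Two splits can coexist in one tree iff at least one of the four
    pairwise side intersections is empty.
    """
    if s1.leafset != s2.leafset:
        raise ValueError("compatibility is defined for splits on the same leafset")
    a1, b1, a2, b2 = s1.side_a, s1.side_b, s2.side_a, s2.side_b
    return not (a1 & a2) or not (a1 & b2) or not (b1 & a2) or not (b1 & b2)


class LeafTree:
    """An unrooted leaf-labelled tree as leafset + non-trivial splits.

    Trivial splits (one per leaf) are implied and never stored.  The
    stored splits must all live on the tree's leafset, be non-trivial
    and pairwise compatible; a tree on *n* leaves carries at most
    ``n - 3`` of them (with equality iff the tree is binary).
    """

    __slots__ = ("_leafset", "_splits")

    def __init__(self, leafset: Iterable[str], nontrivial_splits: Iterable[Split] = ()):
        leafset = frozenset(leafset)
        if not leafset:
            raise ValueError("a tree needs at least one leaf")
        for lab in leafset:
            _check_label(lab)
        splits = frozenset(nontrivial_splits)
        for s in splits:
            if s.leafset != leafset:
                raise ValueError(f"split {s} is not on the tree leafset")
            if s.is_trivial():
                raise ValueError(f"trivial split {s} must not be stored")
        if len(splits) > max(0, len(leafset) - 3):
            raise ValueError("too many non-trivial splits for the leaf count")
        slist = sorted(splits)
        for i, s1 in enumerate(slist):
            for s2 in slist[i + 1:]:
                if not is_compatible(s1, s2):
                    raise ValueError(f"incompatible splits: {s1} vs {s2}")
        self._leafset = leafset
        self._splits = splits

    @property
    def leafset(self) -> frozenset:
        return self._leafset

    @property
    def nontrivial_splits(self) -> frozenset:
        return self._splits

    def trivial_splits(self) -> frozenset:
        if len(self._leafset) < 2:
            return frozenset()
        return frozenset(
            Split({leaf}, self._leafset - {leaf}) for leaf in self._leafset
        )

    def all_splits(self) -> frozenset:
        """Non-trivial plus implied trivial splits."""
        return self._splits | self.trivial_splits()

    def is_binary(self) -> bool:
        return len(self._splits) == max(0, len(self._leafset) - 3)

    def is_star(self) -> bool:
        return not self._splits

    def __eq__(self, other) -> bool:
        if not isinstance(other, LeafTree):
            return NotImplemented
        return self._leafset == other._leafset and self._splits == other._splits

    def __hash__(self) -> int:
        return hash((self._leafset, self._splits))

    def __repr__(self) -> str:
        splits = ", ".join(str(s) for s in sorted(self._splits)) or "star"
        return f"LeafTree({{{' '.join(sorted(self._leafset))}}}: {splits})"


@dataclass(frozen=True)
class Profile:
    """An ordered collection of trees; leafsets may differ."""

    trees: tuple

    def __init__(self, trees: Iterable[LeafTree]):
        trees = tuple(trees)
        if not trees:
            raise ValueError("a profile needs at least one tree")
        object.__setattr__(self, "trees", trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[LeafTree]:
        return iter(self.trees)

    def common_leafset(self) -> frozenset:
        out = self.trees[0].leafset
        for t in self.trees[1:]:
            out = out & t.leafset
        return out

    def same_leafset(self) -> bool:
        return all(t.leafset == self.trees[0].leafset for t in self.trees)


@dataclass(frozen=True)
class PruneResult:
    """Outcome of pruning one leaf.

    ``forced_contractions`` is the number of non-trivial splits lost in
    the operation (splits that degenerated to trivial or collapsed onto
    a surviving duplicate); ``lost`` records their post-prune forms for
    edit-script bookkeeping.
    """

    tree: LeafTree
    forced_contractions: int
    lost: tuple = ()

    def __post_init__(self):
        assert self.forced_contractions == len(self.lost) >= 0


def contract(t: LeafTree, s: Split) -> LeafTree:
    """Remove the internal edge identified by non-trivial split ``s``."""
    if s.is_trivial():
        raise ValueError(f"cannot contract trivial split {s}")
    if s not in t.nontrivial_splits:
        raise ValueError(f"split {s} is not in the tree")
    return LeafTree(t.leafset, t.nontrivial_splits - {s})


def prune(t: LeafTree, leaf: str) -> PruneResult:
    """Remove ``leaf``, performing (and counting) forced contractions."""
    if leaf not in t.leafset:
        raise ValueError(f"leaf {leaf!r} is not in the tree")
    if len(t.leafset) < 2:
        raise ValueError("cannot prune the last leaf")
    new_leafset = t.leafset - {leaf}
    kept: set = set()
    lost: list = []
    for s in sorted(t.nontrivial_splits):
        r = restrict_split(s, new_leafset)
        # removing one leaf from a non-trivial split never empties a side
        if r.is_trivial() or r in kept:
            lost.append(r)
        else:
            kept.add(r)
    return PruneResult(LeafTree(new_leafset, kept), len(lost), tuple(lost))


def restrict_tree(t: LeafTree, z: Iterable[str]) -> LeafTree:
    """The induced subtree on leafset ``z`` (all other leaves pruned).

    Equals iterated pruning of ``leafset - z`` in any order.
    """
    z = frozenset(z)
    if not z:
        raise ValueError("restriction leafset must be non-empty")
    if not z <= t.leafset:
        raise ValueError(f"{sorted(z - t.leafset)} not in the tree leafset")
    kept = set()
    for s in t.nontrivial_splits:
        r = restrict_split(s, z)
        if r is not None and not r.is_trivial():
            kept.add(r)
    return LeafTree(z, kept)


# ---------------------------------------------------------------------------
# Newick I/O
#
# Unrooted semantics: branch lengths and internal labels are parsed and
# discarded, polytomies are allowed, a degree-2 root is suppressed.

def tree_from_newick(text: str) -> LeafTree:
    import dendropy

    text = text.strip()
    if not text:
        raise ValueError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    leaves = [nd for nd in dtree.leaf_node_iter()]
    labels = [nd.taxon.label if nd.taxon else nd.label for nd in leaves]
    if any(lab is None for lab in labels):
        raise ValueError("Newick tree has an unlabelled leaf")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in Newick tree")
    leafset = frozenset(labels)
    n = len(leafset)
    splits: set = set()

    def collect(nd) -> frozenset:
        if nd.is_leaf():
            return frozenset({nd.taxon.label if nd.taxon else nd.label})
        below = frozenset().union(*(collect(ch) for ch in nd.child_nodes()))
        if nd.parent_node is not None and 2 <= len(below) <= n - 2:
            splits.add(Split(below, leafset - below))
        return below

    collect(dtree.seed_node)
    return LeafTree(leafset, splits)


def _tree_adjacency(t: LeafTree) -> dict:
    """Adjacency map of the tree; leaves are labels, internal nodes ints."""
    adj: dict = defaultdict(set)
    leaves = sorted(t.leafset)
    if len(leaves) == 1:
        adj[leaves[0]]
        return dict(adj)
    if len(leaves) == 2:
        a, b = leaves
        adj[a].add(b)
        adj[b].add(a)
        return dict(adj)
    center = 0
    for leaf in leaves:
        adj[center].add(leaf)
        adj[leaf].add(center)
    next_id = 1

    def component_leaves(start, avoid) -> frozenset:
        seen = {avoid, start}
        stack = [start]
        out = set()
        while stack:
            nd = stack.pop()
            if isinstance(nd, str):
                out.add(nd)
            for nb in adj[nd]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(out)

    for s in sorted(t.nontrivial_splits, key=lambda s: (len(s.smaller_side()), s._key())):
        placed = False
        for side in (s.side_a, s.side_b):
            for v in [nd for nd in adj if isinstance(nd, int)]:
                group = [nb for nb in adj[v] if component_leaves(nb, v) <= side]
                covered = frozenset().union(*(component_leaves(nb, v) for nb in group)) if group else frozenset()
                if covered == side and len(group) < len(adj[v]):
                    u = next_id
                    next_id += 1
                    for nb in group:
                        adj[v].discard(nb)
                        adj[nb].discard(v)
                        adj[u].add(nb)
                        adj[nb].add(u)
                    adj[u].add(v)
                    adj[v].add(u)
                    placed = True
                    break
            if placed:
                break
        if not placed:  # pragma: no cover - guarded by LeafTree invariants
            raise RuntimeError(f"could not place split {s}")
    return dict(adj)


def tree_to_newick(t: LeafTree) -> str:
    leaves = sorted(t.leafset)
    if len(leaves) == 1:
        return f"{leaves[0]};"
    if len(leaves) == 2:
        return f"({leaves[0]},{leaves[1]});"
    adj = _tree_adjacency(t)
    root = 0

    def emit(nd, parent) -> str:
        children = sorted(
            (nb for nb in adj[nd] if nb != parent),
            key=lambda x: (isinstance(x, int), str(x)),
        )
        if not children:
            return str(nd)
        return "(" + ",".join(emit(ch, nd) for ch in children) + ")"

    return emit(root, None) + ";"


def trees_from_newick(text: str) -> list:
    """Read one tree per non-empty line."""
    return [tree_from_newick(line) for line in text.splitlines() if line.strip()]


def trees_to_newick(trees: Iterable[LeafTree]) -> str:
    return "\n".join(tree_to_newick(t) for t in trees) + "\n"


# ---------------------------------------------------------------------------
# Split-file I/O
#
# One split per line ("a b | c d e"); lines starting with '#' (and
# trailing '#' comments) are ignored; a blank line separates trees.

def trees_from_split_text(text: str) -> list:
    groups: list = [[]]
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if raw.strip().startswith("#"):
            continue
        if not raw.strip():
            if groups[-1]:
                groups.append([])
            continue
        if line:
            groups[-1].append(split_from_text(line))
    trees = []
    for group in groups:
        if not group:
            continue
        leafset = frozenset().union(*(s.leafset for s in group))
        nontrivial = {s for s in group if not s.is_trivial()}
        for s in nontrivial:
            if s.leafset != leafset:
                raise ValueError(f"split {s} does not cover the tree leafset")
        trees.append(LeafTree(leafset, nontrivial))
    if not trees:
        raise ValueError("no splits found in split file")
    return trees


def trees_to_split_text(trees: Iterable[LeafTree]) -> str:
    out = io.StringIO()
    for i, t in enumerate(trees):
        if i:
            out.write("\n")
        for s in sorted(t.all_splits(), key=lambda s: (s.is_trivial(), s._key())):
            out.write(str(s).replace("|", " | ") + "\n")
    return out.getvalue()
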