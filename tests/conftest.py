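"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's optimised search paths:
they enumerate leaf subsets (and split restrictions) directly, so the
memoised algorithms can be checked against exhaustive search on small
trees.
"""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from leafdist import LeafTree, Profile, Split, is_subsplit, restrict_tree, rf_distance
from leafdist.splits import is_compatible, restrict_split


# ---------------------------------------------------------------------------
# Brute-force oracles


def subsets(items, min_size=1):
    items = sorted(items)
    for k in range(min_size, len(items) + 1):
        for combo in combinations(items, k):
            yield frozenset(combo)


def edit_oracle(t1: LeafTree, t2: LeafTree, cost_c=1.0, cost_p=1.0, count_fc=True):
    """Minimum over all final leafsets x of: per-tree pruning charges,
    forced contractions (non-trivial splits lost while restricting),
    and the contraction cost of the residual split difference."""
    fc_cost = cost_c if count_fc else 0.0
    best = None
    for x in subsets(t1.leafset & t2.leafset):
        r1 = restrict_tree(t1, x)
        r2 = restrict_tree(t2, x)
        fc = (len(t1.nontrivial_splits) - len(r1.nontrivial_splits)) + (
            len(t2.nontrivial_splits) - len(r2.nontrivial_splits)
        )
        cost = (
            cost_p * (len(t1.leafset - x) + len(t2.leafset - x))
            + fc_cost * fc
            + cost_c * len(r1.nontrivial_splits ^ r2.nontrivial_splits)
        )
        if best is None or cost < best:
            best = cost
    return best


def mast_oracle(t1: LeafTree, t2: LeafTree):
    best = 0
    for x in subsets(t1.leafset & t2.leafset):
        if restrict_tree(t1, x) == restrict_tree(t2, x):
            best = max(best, len(x))
    return len(t1.leafset | t2.leafset) - best


def p_oracle(t1: LeafTree, t2: LeafTree, cost_c=1.0, cost_p=1.0):
    best = None
    for x in subsets(t1.leafset & t2.leafset):
        r1 = restrict_tree(t1, x)
        r2 = restrict_tree(t2, x)
        if r1 != r2:
            continue
        fc = (len(t1.nontrivial_splits) - len(r1.nontrivial_splits)) + (
            len(t2.nontrivial_splits) - len(r2.nontrivial_splits)
        )
        cost = cost_p * (len(t1.leafset - x) + len(t2.leafset - x)) + cost_c * fc
        if best is None or cost < best:
            best = cost
    return best


def frequent_subsplits_oracle(profile: Profile, min_count: int):
    """All maximal subsplits supported by >= min_count trees, found by
    enumerating every restriction of every observed split."""
    candidates = set()
    for t in profile.trees:
        for s in t.all_splits():
            for z in subsets(s.leafset, min_size=2):
                r = restrict_split(s, z)
                if r is not None:
                    candidates.add(r)
    frequent = set()
    for c in candidates:
        n = sum(
            1
            for t in profile.trees
            if c.leafset <= t.leafset
            and any(is_subsplit(c, u) for u in t.all_splits())
        )
        if n >= min_count:
            frequent.add(c)
    return {
        s
        for s in frequent
        if not any(c != s and is_subsplit(s, c) for c in frequent)
    }


# ---------------------------------------------------------------------------
# Enumerated tree families


def all_nontrivial_splits(labels):
    labels = sorted(labels)
    leafset = frozenset(labels)
    out = []
    rest = labels[1:]
    for k in range(1, len(labels) - 1):
        for combo in combinations(rest, k):
            side = frozenset(combo) | {labels[0]}
            if 2 <= len(side) <= len(labels) - 2:
                out.append(Split(side, leafset - side))
    return out


def all_trees_on(labels):
    """Every leaf-labelled tree on the label set (all compatible split
    subsets, from the star to the binary resolutions)."""
    labels = sorted(labels)
    splits = all_nontrivial_splits(labels)
    trees = []

    def grow(chosen, remaining):
        trees.append(LeafTree(labels, chosen))
        for i, s in enumerate(remaining):
            if all(is_compatible(s, c) for c in chosen):
                grow(chosen + [s], remaining[i + 1:])

    grow([], splits)
    # dedupe (different insertion orders reach the same split set)
    return sorted(set(trees), key=lambda t: sorted(map(str, t.nontrivial_splits)))


@pytest.fixture(scope="session")
def five_leaf_trees():
    return all_trees_on("abcde")


@pytest.fixture(scope="session")
def small_tree_family(five_leaf_trees):
    """All 5-leaf trees plus a seeded sample of 6-leaf trees."""
    rng = random.Random(20240917)
    six = all_trees_on("abcdef")
    return five_leaf_trees + rng.sample(six, 20)


def random_leaftree(rng: random.Random, labels, binary=False) -> LeafTree:
    """Random tree drawn independently of the package's generator."""
    from leafdist.simulate import _random_binary

    t = _random_binary(sorted(labels), rng)
    if not binary:
        drop = [s for s in sorted(t.nontrivial_splits) if rng.random() < 0.4]
        return LeafTree(t.leafset, t.nontrivial_splits - frozenset(drop))
    return t
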