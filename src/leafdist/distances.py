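"""Reference distance measures: Robinson-Foulds, MAST, c- and p-distance.

R-F is the symmetric difference of the non-trivial split sets and only
exists for trees on one leafset.  The MAST distance counts the leaves
of the union leafset that must be removed to reach a maximum agreement
subtree, so it extends to free leafsets.  The c-distance is R-F scaled
by the contraction cost; the p-distance is the cheapest unification
using prunings only, charging the pruning cost per leaf removal per
tree plus the contraction cost for every forced contraction incurred.
The MAST and p-distance searches are exact subset searches (exponential
in the leaf count), which is adequate at the leaf counts this package
targets; published polynomial MAST algorithms are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .splits import LeafTree, restrict_tree

__all__ = ["MastResult", "rf_distance", "mast", "p_distance", "c_distance"]


@dataclass(frozen=True)
class MastResult:
    """A maximum agreement leafset and the induced leaf-removal count."""

    agreement_leafset: frozenset
    distance: int


def rf_distance(t1: LeafTree, t2: LeafTree) -> int:
    """Robinson-Foulds distance ``|S1 Δ S2|`` over non-trivial splits."""
    if t1.leafset != t2.leafset:
        raise ValueError("R-F distance requires identical leafsets")
    return len(t1.nontrivial_splits ^ t2.nontrivial_splits)


def _max_agreement(t1: LeafTree, t2: LeafTree) -> frozenset:
    """Largest x with ``t1|x == t2|x`` (lexicographically smallest on ties)."""
    common = t1.leafset & t2.leafset
    memo: dict = {}

    def best(x: frozenset) -> frozenset:
        if x in memo:
            return memo[x]
        if len(x) <= 3 or restrict_tree(t1, x) == restrict_tree(t2, x):
            res = x
        else:
            res = None
            for leaf in sorted(x):
                cand = best(x - {leaf})
                if (
                    res is None
                    or len(cand) > len(res)
                    or (len(cand) == len(res) and tuple(sorted(cand)) < tuple(sorted(res)))
                ):
                    res = cand
        memo[x] = res
        return res

    return best(common)


def mast(t1: LeafTree, t2: LeafTree) -> MastResult:
    """Maximum agreement subtree distance, free-leafset aware.

    The distance is ``|L1 | L2| - |x*|`` where ``x*`` is a maximum
    subset of the common leafset on which the restricted trees agree:
    every removed leaf is counted once, whether it was present in one
    tree or in both.
    """
    if not (t1.leafset & t2.leafset):
        raise ValueError("MAST requires a non-empty common leafset")
    agreement = _max_agreement(t1, t2)
    return MastResult(agreement, len(t1.leafset | t2.leafset) - len(agreement))


def p_distance(t1: LeafTree, t2: LeafTree, cm) -> float:
    """Minimal cost of unifying the trees with prunings only.

    Minimises, over agreement leafsets ``x``, the per-tree pruning
    charges ``cost_p * (|L1 - x| + |L2 - x|)`` plus ``cost_c`` per
    forced contraction (non-trivial split lost while pruning down to
    ``x``), when the cost model counts forced contractions.
    """
    common = t1.leafset & t2.leafset
    if not common:
        raise ValueError("p-distance requires a non-empty common leafset")
    fc_cost = cm.cost_fc
    best = None
    order = sorted(common)
    for k in range(len(common), 0, -1):
        for subset in combinations(order, k):
            x = frozenset(subset)
            r1 = restrict_tree(t1, x)
            r2 = restrict_tree(t2, x)
            if r1 != r2:
                continue
            fc = (len(t1.nontrivial_splits) - len(r1.nontrivial_splits)) + (
                len(t2.nontrivial_splits) - len(r2.nontrivial_splits)
            )
            cost = cm.cost_p * (len(t1.leafset - x) + len(t2.leafset - x)) + fc_cost * fc
            if best is None or cost < best:
                best = cost
    return best


def c_distance(t1: LeafTree, t2: LeafTree, cm) -> float:
    """Contraction-only unification cost: ``cost_c * R-F``."""
    if t1.leafset != t2.leafset:
        raise ValueError("c-distance is undefined for different leafsets")
    return cm.cost_c * rf_distance(t1, t2)
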