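"""Consensus trees: strict, majority-rule, and tree edit consensus.

Strict and majority-rule consensus are the classical split-counting
constructions and require a shared leafset.  The tree edit consensus
(TEC) generalises the pairwise edit distance to a profile: it is the
common tree reachable from every input tree by the jointly cheapest
edit scripts.  A pruning, if used, must be applied to every input tree
(the unification's leafset is contained in every input leafset), and
the contraction endgame reduces every tree to the strict consensus of
the current restrictions; the recursion below therefore minimises over
"contract down to the strict consensus now" versus "prune one shared
leaf from all trees and recurse", after first pruning the leaves
missing from at least one input.  For two trees the TEC score equals
the edit distance under the same cost model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .edit import CostModel, EditOperation, _phase1
from .splits import LeafTree, Profile, prune

__all__ = [
    "TecResult",
    "strict_consensus",
    "majority_consensus",
    "tree_edit_consensus",
    "enumerate_tec_optima",
]


@dataclass(frozen=True)
class TecResult:
    """Optimal tree edit consensus: total script cost, the unified
    tree, and one operation sequence per input tree reaching it."""

    score: float
    tree: LeafTree
    scripts: tuple


def strict_consensus(p: Profile) -> LeafTree:
    """Tree of the splits present in every input tree."""
    if not p.same_leafset():
        raise ValueError("strict consensus requires one shared leafset")
    splits = p.trees[0].nontrivial_splits
    for t in p.trees[1:]:
        splits = splits & t.nontrivial_splits
    return LeafTree(p.trees[0].leafset, splits)


def majority_consensus(p: Profile) -> LeafTree:
    """Tree of the splits occurring in strictly more than half the trees.

    Majority splits are automatically pairwise compatible.
    """
    if not p.same_leafset():
        raise ValueError("majority consensus requires one shared leafset")
    counts: dict = {}
    for t in p.trees:
        for s in t.nontrivial_splits:
            counts[s] = counts.get(s, 0) + 1
    n = len(p)
    keep = {s for s, c in counts.items() if c * 2 > n}
    return LeafTree(p.trees[0].leafset, keep)


_TOL = 1e-9


def tree_edit_consensus(p: Profile, cm: CostModel = CostModel()) -> TecResult:
    """Minimal-cost unification of a whole profile (exact, memoised).

    Phase 1 prunes, from each carrying tree, every leaf outside the
    profile's common leafset (cost_p per carrying tree plus charged
    forced contractions).  Phase 2 minimises over the strict-consensus
    contraction endgame and shared-leaf prunings.  Ties are broken as
    in the pairwise edit distance (contraction endgame first, then the
    lexicographically smallest leaf); the score is tie-free, the
    returned tree is one optimum among possibly several.
    """
    common = p.common_leafset()
    if not common:
        raise ValueError("tree edit consensus requires a non-empty common leafset")
    n = len(p)
    work = []
    ops = []
    total = 0.0
    for i, t in enumerate(p.trees):
        w, o, c = _phase1(t, common, cm, i + 1)
        work.append(w)
        ops.append(list(o))
        total += c

    memo: dict = {}

    def solve(trees: tuple) -> float:
        key = trees[0].leafset
        if key in memo:
            return memo[key][0]
        sct = trees[0].nontrivial_splits
        for t in trees[1:]:
            sct = sct & t.nontrivial_splits
        contract_cost = cm.cost_c * sum(
            len(t.nontrivial_splits - sct) for t in trees
        )
        best, choice = contract_cost, None
        if contract_cost and len(key) > 1:
            for leaf in sorted(key):
                pruned = [prune(t, leaf) for t in trees]
                cand = (
                    n * cm.cost_p
                    + cm.cost_fc * sum(r.forced_contractions for r in pruned)
                    + solve(tuple(r.tree for r in pruned))
                )
                if cand < best - _TOL:
                    best, choice = cand, leaf
        memo[key] = (best, choice)
        return best

    cur = tuple(work)
    total += solve(cur)

    # replay the argmin path
    while True:
        _, choice = memo[cur[0].leafset]
        if choice is None:
            break
        nxt = []
        for i, t in enumerate(cur):
            r = prune(t, choice)
            ops[i].append(EditOperation("prune", choice, i + 1))
            ops[i].extend(
                EditOperation("forced_contract", s, i + 1) for s in r.lost
            )
            nxt.append(r.tree)
        cur = tuple(nxt)
    sct = cur[0].nontrivial_splits
    for t in cur[1:]:
        sct = sct & t.nontrivial_splits
    for i, t in enumerate(cur):
        for s in sorted(t.nontrivial_splits - sct):
            ops[i].append(EditOperation("contract", s, i + 1))
    tree = LeafTree(cur[0].leafset, sct)
    return TecResult(total, tree, tuple(tuple(o) for o in ops))


def enumerate_tec_optima(p: Profile, cm: CostModel = CostModel()) -> list:
    """All co-optimal TEC unification trees (score ties within 1e-9)."""
    best = tree_edit_consensus(p, cm)
    common = p.common_leafset()
    work = tuple(_phase1(t, common, cm, i + 1)[0] for i, t in enumerate(p.trees))
    n = len(p)
    out: dict = {}

    def explore(trees: tuple, spent: float):
        if spent > best.score + _TOL:
            return
        sct = trees[0].nontrivial_splits
        for t in trees[1:]:
            sct = sct & t.nontrivial_splits
        contract_cost = cm.cost_c * sum(len(t.nontrivial_splits - sct) for t in trees)
        if abs(spent + contract_cost - best.score) <= _TOL:
            out[LeafTree(trees[0].leafset, sct)] = True
        if len(trees[0].leafset) > 1:
            for leaf in sorted(trees[0].leafset):
                pruned = [prune(t, leaf) for t in trees]
                step = n * cm.cost_p + cm.cost_fc * sum(
                    r.forced_contractions for r in pruned
                )
                explore(tuple(r.tree for r in pruned), spent + step)

    phase1_cost = sum(_phase1(t, common, cm, 1)[2] for t in p.trees)
    explore(work, phase1_cost)
    return sorted(out, key=lambda t: sorted(map(str, t.nontrivial_splits)))
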