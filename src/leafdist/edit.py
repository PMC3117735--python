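"""Tree edit distance for leaf-labelled trees on free leafsets.

The distance between two trees is the minimal cost of an *edit script*:
a pair of per-tree operation sequences (contractions and prunings,
prunings dragging forced contractions along) that transform both trees
into one common tree.  With positive operation costs and forced
contractions charged at the contraction cost, the distance is a metric.
The variant that charges nothing for forced contractions (NFC) is a
dissimilarity measure whose metric status is open, and is exposed
separately.

The optimisation exploits two facts: the order of operations within a
subscript never changes the outcome, and shared splits are never worth
contracting.  Leaves private to one tree must be pruned up front
(phase 1); on the resulting shared leafset the minimum is either
"contract every differing split" (the R-F term) or "prune some leaf
from both trees and recurse", memoised on the remaining leafset
(phase 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .distances import rf_distance
from .splits import LeafTree, Split, contract, prune, restrict_split, is_subsplit

__all__ = [
    "CostModel",
    "EditOperation",
    "EditScript",
    "EditResult",
    "edit_distance",
    "nfc_dissimilarity",
    "apply_script",
]

_TOL = 1e-9


@dataclass(frozen=True)
class CostModel:
    """Operation costs: contraction, pruning, and whether forced
    contractions are charged (at the contraction cost) or free."""

    cost_c: float = 1.0
    cost_p: float = 1.0
    count_fc: bool = True

    def __post_init__(self):
        if self.cost_c <= 0 or self.cost_p <= 0:
            raise ValueError("operation costs must be positive")

    @property
    def cost_fc(self) -> float:
        return self.cost_c if self.count_fc else 0.0


@dataclass(frozen=True)
class EditOperation:
    """One step of a subscript.

    ``kind`` is ``"prune"`` (target: leaf label), ``"contract"`` or
    ``"forced_contract"`` (target: split).  ``tree_index`` says which
    input tree the enclosing subscript belongs to.
    """

    kind: str
    target: Union[str, Split]
    tree_index: int = 1

    def __post_init__(self):
        if self.kind not in ("prune", "contract", "forced_contract"):
            raise ValueError(f"unknown operation kind {self.kind!r}")

    def __str__(self) -> str:
        tag = {"prune": "p", "contract": "c", "forced_contract": "fc"}[self.kind]
        return f"{tag}({self.target})"


@dataclass(frozen=True)
class EditScript:
    """Per-tree operation sequences whose joint application unifies the
    two input trees; ``cost`` is the script cost under the cost model."""

    subscript1: tuple
    subscript2: tuple
    cost: float


@dataclass(frozen=True)
class EditResult:
    distance: float
    script: EditScript
    unified_tree: LeafTree


def _phase1(t: LeafTree, keep: frozenset, cm: CostModel, tree_index: int):
    """Prune the leaves of ``t`` outside ``keep``; return tree, ops, cost."""
    ops = []
    cost = 0.0
    cur = t
    for leaf in sorted(t.leafset - keep):
        res = prune(cur, leaf)
        ops.append(EditOperation("prune", leaf, tree_index))
        ops.extend(EditOperation("forced_contract", s, tree_index) for s in res.lost)
        cost += cm.cost_p + cm.cost_fc * res.forced_contractions
        cur = res.tree
    return cur, ops, cost


def _solve_same_leafset(t1: LeafTree, t2: LeafTree, cm: CostModel) -> dict:
    """Memoised phase-2 recursion, keyed by the remaining leafset.

    Each entry is ``(cost, choice)`` where ``choice`` is ``None`` for
    the contraction-only base case or the leaf pruned from both trees.
    Ties prefer the base case, then the lexicographically smallest
    leaf, so the distance is deterministic.
    """
    memo: dict = {}

    def solve(u1: LeafTree, u2: LeafTree) -> float:
        key = u1.leafset
        if key in memo:
            return memo[key][0]
        rf = rf_distance(u1, u2)
        best = cm.cost_c * rf
        choice = None
        if rf and len(key) > 1:
            for leaf in sorted(key):
                p1 = prune(u1, leaf)
                p2 = prune(u2, leaf)
                cand = (
                    2 * cm.cost_p
                    + cm.cost_fc * (p1.forced_contractions + p2.forced_contractions)
                    + solve(p1.tree, p2.tree)
                )
                if cand < best - _TOL:
                    best = cand
                    choice = leaf
        memo[key] = (best, choice)
        return best

    solve(t1, t2)
    return memo


def edit_distance(t1: LeafTree, t2: LeafTree, cm: CostModel = CostModel()) -> EditResult:
    """Minimal-cost edit script between two trees (exact, memoised).

    Phase 1 prunes the leaves outside the common leafset from the tree
    carrying them (cost_p each, plus charged forced contractions).
    Phase 2 runs the same-leafset recursion.  An optimal script is
    reconstructed along the argmin path; the distance is tie-free, the
    script's tie-breaks are deterministic but not canonical.
    """
    common = t1.leafset & t2.leafset
    if not common:
        raise ValueError("edit distance requires a non-empty common leafset")
    w1, ops1, cost1 = _phase1(t1, common, cm, 1)
    w2, ops2, cost2 = _phase1(t2, common, cm, 2)
    memo = _solve_same_leafset(w1, w2, cm)
    total = cost1 + cost2 + memo[w1.leafset][0]

    # replay the argmin path to emit the phase-2 operations
    u1, u2 = w1, w2
    ops1, ops2 = list(ops1), list(ops2)
    while True:
        _, choice = memo[u1.leafset]
        if choice is None:
            break
        p1 = prune(u1, choice)
        p2 = prune(u2, choice)
        ops1.append(EditOperation("prune", choice, 1))
        ops1.extend(EditOperation("forced_contract", s, 1) for s in p1.lost)
        ops2.append(EditOperation("prune", choice, 2))
        ops2.extend(EditOperation("forced_contract", s, 2) for s in p2.lost)
        u1, u2 = p1.tree, p2.tree
    for s in sorted(u1.nontrivial_splits - u2.nontrivial_splits):
        ops1.append(EditOperation("contract", s, 1))
    for s in sorted(u2.nontrivial_splits - u1.nontrivial_splits):
        ops2.append(EditOperation("contract", s, 2))
    unified = LeafTree(u1.leafset, u1.nontrivial_splits & u2.nontrivial_splits)
    script = EditScript(tuple(ops1), tuple(ops2), total)
    return EditResult(total, script, unified)


def nfc_dissimilarity(
    t1: LeafTree, t2: LeafTree, cost_c: float = 1.0, cost_p: float = 1.0
) -> EditResult:
    """Edit-script optimum with forced contractions free of charge."""
    return edit_distance(t1, t2, CostModel(cost_c, cost_p, count_fc=False))


# ---------------------------------------------------------------------------
# Script application


def apply_script(t: LeafTree, ops: Sequence[EditOperation]) -> LeafTree:
    """Apply an operation sequence; the result is order-independent.

    The working state keeps degenerate split copies created by pruning
    (duplicates, splits gone trivial) as pending forced contractions,
    so that explicitly recorded ``fc`` operations consume them
    regardless of where they sit in the sequence; any still pending at
    the end are swept implicitly.  Contract/forced-contract targets may
    be written in pre- or post-prune form: the matching edge is found
    by subsplit containment.
    """
    leafset = set(t.leafset)
    slots: list = sorted(t.nontrivial_splits)  # may hold trivial/duplicate entries

    def match(target: Split):
        r = restrict_split(target, frozenset(target.leafset) & frozenset(leafset))
        if r is None:
            return None
        exact = [s for s in slots if s == r]
        if exact:
            return exact[0]
        supers = sorted(s for s in slots if is_subsplit(r, s) and s != r)
        return supers[0] if supers else None

    for i, op in enumerate(ops):
        if op.kind == "prune":
            if op.target not in leafset or len(leafset) < 2:
                raise ValueError(f"step {i}: cannot prune leaf {op.target!r}")
            leafset.discard(op.target)
            slots = [
                restrict_split(s, frozenset(leafset))
                for s in slots
                if restrict_split(s, frozenset(leafset)) is not None
            ]
        else:
            hit = match(op.target)
            if op.kind == "contract":
                if hit is None or hit.is_trivial():
                    raise ValueError(f"step {i}: cannot contract {op.target}")
                slots.remove(hit)
            else:  # forced_contract: remove the matching edge (a pending
                # degenerate copy, or -- applied before its prune -- the
                # not-yet-degenerate supersplit); lenient no-op if gone
                if hit is not None:
                    slots.remove(hit)
    # sweep forced contractions not spelled out explicitly
    final: set = set()
    for s in slots:
        if not s.is_trivial():
            final.add(s)
    return LeafTree(frozenset(leafset), final)
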