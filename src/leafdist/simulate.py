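"""Random trees, mutation operators and the two evaluation harnesses.

The statistical evaluation of the distance measures rests on two
experiments over randomly generated unrooted trees:

* **distribution** -- draw independent tree pairs and histogram each
  measure's values, to judge how discriminative a measure is;
* **dynamics** -- draw one tree, mutate it ``k`` times (contraction,
  pruning, or nearest non-brother interchange), and track the mean
  distance as a function of ``k``.

Binary trees are generated by sequential uniform edge attachment,
which samples uniformly over labelled unrooted binary topologies.
"Unconstrained" trees contract each internal edge of a binary draw
independently with a fixed probability.  With ``free_leafset`` the
leaf count is drawn uniformly and labels are sampled from a universe,
so generated pairs need not share a leafset.
"""

from __future__ import annotations

import random
import re
import string
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .distances import mast, p_distance, c_distance, rf_distance
from .edit import CostModel, edit_distance, nfc_dissimilarity
from .splits import LeafTree, Split, contract, prune
from .subsplits import fs_dissimilarity

__all__ = [
    "TreeModel",
    "Mutation",
    "ExperimentResult",
    "random_tree",
    "mutate",
    "distribution_experiment",
    "dynamics_experiment",
    "get_measure",
    "default_labels",
]


def default_labels(n: int) -> list:
    letters = list(string.ascii_lowercase)
    if n <= len(letters):
        return letters[:n]
    return letters + [f"t{i}" for i in range(len(letters) + 1, n + 1)]


@dataclass(frozen=True)
class TreeModel:
    """Random-tree generation parameters.

    ``contraction_prob`` applies to the unconstrained model only: each
    internal edge of a binary draw is contracted independently with
    this probability (default 0.25).  With ``free_leafset`` the leaf
    count is uniform on [4, n_leaves] and labels are sampled from
    ``label_universe`` (default: the first ``n_leaves`` letters).
    """

    kind: str = "binary"
    n_leaves: int = 8
    free_leafset: bool = False
    label_universe: Optional[tuple] = None
    contraction_prob: float = 0.25

    def __post_init__(self):
        if self.kind not in ("binary", "unconstrained"):
            raise ValueError(f"unknown tree model {self.kind!r}")
        if self.n_leaves < 4:
            raise ValueError("need at least 4 leaves")
        if not 0 <= self.contraction_prob < 1:
            raise ValueError("contraction_prob must lie in [0, 1)")

    def universe(self) -> list:
        if self.label_universe is not None:
            return list(self.label_universe)
        return default_labels(self.n_leaves)


@dataclass(frozen=True)
class Mutation:
    """``kind`` in {contraction, pruning, nnbi}; ``count`` steps."""

    kind: str
    count: int

    def __post_init__(self):
        if self.kind not in ("contraction", "pruning", "nnbi"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.count < 0:
            raise ValueError("mutation count must be >= 0")


@dataclass(frozen=True)
class ExperimentResult:
    """Histograms (distribution runs) or per-k mean curves (dynamics)."""

    seed: int
    n_trials: int
    histogram: Optional[dict] = None
    curves: Optional[dict] = None


def _rng(seed) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def _splits_from_adjacency(adj: dict, leafset: frozenset) -> set:
    n = len(leafset)
    splits = set()
    internal = [nd for nd in adj if isinstance(nd, int)]
    seen = set()
    for u in internal:
        for v in adj[u]:
            if not isinstance(v, int) or (v, u) in seen:
                continue
            seen.add((u, v))
            # leaves on u's side of edge (u, v)
            stack, comp, visited = [u], set(), {u, v}
            while stack:
                nd = stack.pop()
                for nb in adj[nd]:
                    if nb in visited:
                        continue
                    visited.add(nb)
                    if isinstance(nb, str):
                        comp.add(nb)
                    else:
                        stack.append(nb)
            if 2 <= len(comp) <= n - 2:
                splits.add(Split(comp, leafset - comp))
    return splits


def _random_binary(labels: list, rng: random.Random) -> LeafTree:
    labels = list(labels)
    leafset = frozenset(labels)
    adj: dict = {0: set(labels[:3])}
    for lab in labels[:3]:
        adj[lab] = {0}
    next_id = 1
    edges = [(0, lab) for lab in labels[:3]]
    for lab in labels[3:]:
        u, v = edges[rng.randrange(len(edges))]
        w = next_id
        next_id += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[w] = {u, v, lab}
        adj[u].add(w)
        adj[v].add(w)
        adj[lab] = {w}
        edges.remove((u, v))
        edges.extend([(u, w), (v, w), (w, lab)])
    return LeafTree(leafset, _splits_from_adjacency(adj, leafset))


def random_tree(model: TreeModel, seed) -> LeafTree:
    """Draw one tree; deterministic per seed (int or Random)."""
    rng = _rng(seed)
    universe = model.universe()
    if model.free_leafset:
        n = rng.randint(4, model.n_leaves)
        labels = sorted(rng.sample(sorted(universe), n))
    else:
        labels = sorted(universe)[: model.n_leaves]
    t = _random_binary(labels, rng)
    if model.kind == "unconstrained":
        for s in sorted(t.nontrivial_splits):
            if rng.random() < model.contraction_prob:
                t = contract(t, s)
    return t


def _leaf_distances(t: LeafTree) -> dict:
    from .splits import _tree_adjacency

    adj = _tree_adjacency(t)
    dists: dict = {}
    leaves = sorted(t.leafset)
    for src in leaves:
        seen = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for nd in frontier:
                for nb in adj[nd]:
                    if nb not in seen:
                        seen[nb] = seen[nd] + 1
                        nxt.append(nb)
            frontier = nxt
        for dst in leaves:
            if dst > src:
                dists[(src, dst)] = seen[dst]
    return dists


def _relabel(t: LeafTree, a: str, b: str) -> LeafTree:
    swap = {a: b, b: a}

    def m(side):
        return frozenset(swap.get(x, x) for x in side)

    return LeafTree(
        t.leafset, {Split(m(s.side_a), m(s.side_b)) for s in t.nontrivial_splits}
    )


def _nnbi_step(t: LeafTree, rng: random.Random) -> LeafTree:
    """Swap the labels of a closest pair of non-sibling leaves."""
    dists = _leaf_distances(t)
    nonsib = {pair: d for pair, d in dists.items() if d > 2}
    if not nonsib:
        raise ValueError("tree has no non-sibling leaf pair")
    dmin = min(nonsib.values())
    nearest = sorted(pair for pair, d in nonsib.items() if d == dmin)
    a, b = nearest[rng.randrange(len(nearest))]
    return _relabel(t, a, b)


def mutate(t: LeafTree, m: Mutation, seed) -> LeafTree:
    """Apply ``m.count`` mutation steps of the given kind."""
    rng = _rng(seed)
    if m.kind == "contraction":
        if m.count > len(t.nontrivial_splits):
            raise ValueError("not enough non-trivial splits to contract")
        for s in rng.sample(sorted(t.nontrivial_splits), m.count):
            t = contract(t, s)
        return t
    if m.kind == "pruning":
        if len(t.leafset) < m.count + 4:
            raise ValueError("not enough leaves to prune")
        for leaf in rng.sample(sorted(t.leafset), m.count):
            t = prune(t, leaf).tree
        return t
    for _ in range(m.count):
        t = _nnbi_step(t, rng)
    return t


# ---------------------------------------------------------------------------
# Measures by name

_PARAM_RE = re.compile(r"^(E|NFC)\s*\(\s*([0-9.]+)\s*,\s*([0-9.]+)\s*\)$")


def _num(x: str):
    f = float(x)
    return int(f) if f == int(f) else f


def _rf_free(t1: LeafTree, t2: LeafTree):
    """R-F, with the maximum-value convention on differing leafsets."""
    if t1.leafset != t2.leafset:
        return len(t1.nontrivial_splits) + len(t2.nontrivial_splits)
    return rf_distance(t1, t2)


def get_measure(name: str) -> Callable[[LeafTree, LeafTree], float]:
    """Resolve a measure name: rf, mast, fs, pdist, cdist, edit, nfc,
    or the parametrised forms E(x,y) / NFC(x,y) with contraction cost
    x and pruning cost y."""
    key = name.strip()
    m = _PARAM_RE.match(key)
    if m:
        kind, x, y = m.group(1), _num(m.group(2)), _num(m.group(3))
        if kind == "E":
            cm = CostModel(cost_c=x, cost_p=y, count_fc=True)
            return lambda t1, t2: edit_distance(t1, t2, cm).distance
        return lambda t1, t2: nfc_dissimilarity(t1, t2, x, y).distance
    simple = {
        "rf": _rf_free,
        "mast": lambda t1, t2: mast(t1, t2).distance,
        "fs": fs_dissimilarity,
        "edit": lambda t1, t2: edit_distance(t1, t2, CostModel()).distance,
        "nfc": lambda t1, t2: nfc_dissimilarity(t1, t2).distance,
        "pdist": lambda t1, t2: p_distance(t1, t2, CostModel()),
        "cdist": lambda t1, t2: c_distance(t1, t2, CostModel()),
    }
    if key not in simple:
        raise ValueError(f"unknown measure {name!r}")
    return simple[key]


def distribution_experiment(
    model: TreeModel, measures: Iterable[str], n_pairs: int, seed: int
) -> ExperimentResult:
    """Histogram each measure over independent random tree pairs.

    All measures see the identical pair stream, so their value ranges
    are directly comparable.
    """
    names = list(measures)
    fns = {name: get_measure(name) for name in names}
    rng = _rng(seed)
    hist: dict = {name: {} for name in names}
    for _ in range(n_pairs):
        t1 = random_tree(model, rng)
        t2 = random_tree(model, rng)
        for name in names:
            v = fns[name](t1, t2)
            h = hist[name]
            h[v] = h.get(v, 0) + 1
    return ExperimentResult(seed=seed, n_trials=n_pairs, histogram=hist)


def dynamics_experiment(
    model: TreeModel,
    mutation_kind: str,
    k_max: int,
    n_reps: int,
    measures: Iterable[str],
    seed: int,
) -> ExperimentResult:
    """Mean distance per measure as a function of the mutation count."""
    names = list(measures)
    fns = {name: get_measure(name) for name in names}
    rng = _rng(seed)
    sums: dict = {name: {k: 0.0 for k in range(k_max + 1)} for name in names}
    for _ in range(n_reps):
        t = random_tree(model, rng)
        for k in range(k_max + 1):
            t2 = mutate(t, Mutation(mutation_kind, k), rng)
            for name in names:
                sums[name][k] += fns[name](t, t2)
    curves = {
        name: {k: (v / n_reps if n_reps else 0.0) for k, v in ks.items()}
        for name, ks in sums.items()
    }
    return ExperimentResult(seed=seed, n_trials=n_reps, curves=curves)
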