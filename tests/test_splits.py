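"""Split algebra, contraction/pruning operators, and I/O."""

import random
from pathlib import Path

import pytest
from hypothesis import given, settings, strategies as st

from leafdist import (
    LeafTree,
    Split,
    contract,
    is_compatible,
    is_subsplit,
    prune,
    restrict_split,
    restrict_tree,
    restricted_equal,
    split_from_text,
    tree_from_newick,
    tree_to_newick,
    trees_from_split_text,
    trees_to_split_text,
)
from leafdist.examples import (
    NOISY_LEAF_T1,
    PRUNED_QUARTET,
    REFINEMENT_T1,
    REFINEMENT_T2,
)

from conftest import random_leaftree

DATA = Path(__file__).parent / "data"


def s(text: str) -> Split:
    return split_from_text(" | ".join(" ".join(side) for side in text.split("|")))


class TestSplit:
    def test_unordered_equality_and_hash(self):
        assert s("ab|cde") == s("cde|ab")
        assert hash(s("ab|cde")) == hash(s("cde|ab"))
        assert s("ab|cde") != s("ae|cdb")

    def test_invalid_splits_rejected(self):
        with pytest.raises(ValueError):
            Split(set(), {"a"})
        with pytest.raises(ValueError):
            Split({"a", "b"}, {"b", "c"})
        with pytest.raises(ValueError):
            Split({"a|x"}, {"b"})

    @given(
        st.sets(st.sampled_from("abcdefgh"), min_size=2, max_size=8).filter(
            lambda x: len(x) >= 2
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_canonicalization_under_side_swap(self, labels, rng):
        labels = sorted(labels)
        cut = rng.randint(1, len(labels) - 1)
        a, b = labels[:cut], labels[cut:]
        assert Split(a, b) == Split(b, a)
        assert hash(Split(a, b)) == hash(Split(b, a))
        assert str(Split(a, b)) == str(Split(b, a))


class TestSplitAlgebra:
    @pytest.mark.parametrize(
        "split,z,expected",
        [
            ("ab|cde", "abce", "ab|ce"),
            ("abe|cd", "abce", "abe|c"),
            ("ab|cd", "ab", None),
        ],
    )
    def test_restrict_split(self, split, z, expected):
        r = restrict_split(s(split), set(z))
        assert r == (s(expected) if expected else None)

    def test_restricted_equal(self):
        assert restricted_equal(s("abcd|efghi"), s("abcd|efghj"), set("abcdefgh"))
        assert restricted_equal(s("ab|cd"), s("ab|cd"), set("abcd"))
        assert not restricted_equal(s("ab|cd"), s("ac|bd"), set("abc"))
        # undefined restriction on either side fails
        assert not restricted_equal(s("ab|cd"), s("ab|cd"), set("ab"))

    def test_is_subsplit(self):
        assert is_subsplit(s("abcd|efgh"), s("abcd|efghi"))
        assert is_subsplit(s("abcd|efgh"), s("abcd|efghj"))
        assert is_subsplit(s("ab|cd"), s("ab|cd"))  # reflexive
        assert not is_subsplit(s("abcd|efghi"), s("abcd|efgh"))
        assert not is_subsplit(s("ac|bd"), s("ab|cde"))

    def test_is_compatible(self):
        assert is_compatible(s("ab|cde"), s("abe|cd"))
        assert is_compatible(s("ab|cdef"), s("abc|def"))
        assert not is_compatible(s("abc|def"), s("abd|cef"))
        with pytest.raises(ValueError):
            is_compatible(s("ab|cd"), s("ab|ce"))


class TestLeafTree:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LeafTree(set("abcde"), {s("ab|cd")})  # split off the leafset
        with pytest.raises(ValueError):
            LeafTree(set("abcd"), {s("a|bcd")})  # trivial stored
        with pytest.raises(ValueError):
            LeafTree(set("abcdef"), {s("abc|def"), s("abd|cef")})  # incompatible
        with pytest.raises(ValueError):
            LeafTree(set())

    def test_split_budget(self):
        # a binary tree on n leaves has exactly n - 3 non-trivial splits
        assert len(REFINEMENT_T1.nontrivial_splits) == 2
        assert REFINEMENT_T1.is_binary()
        with pytest.raises(ValueError):
            LeafTree(set("abcd"), {s("ab|cd"), s("ac|bd")})


class TestContractPrune:
    def test_contract_refinement(self):
        assert contract(REFINEMENT_T1, s("abe|cd")) == REFINEMENT_T2

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            contract(REFINEMENT_T2, s("abe|cd"))  # not present
        with pytest.raises(ValueError):
            contract(REFINEMENT_T1, s("a|bcde"))  # trivial
        star = LeafTree(set("abcde"))
        with pytest.raises(ValueError):
            contract(star, s("ab|cde"))

    def test_contract_all_yields_star(self):
        t = REFINEMENT_T1
        for sp in sorted(t.nontrivial_splits):
            t = contract(t, sp)
        assert t.is_star()

    def test_prune_refinement_forces_contraction(self):
        res = prune(REFINEMENT_T1, "d")
        assert res.tree == PRUNED_QUARTET
        assert res.forced_contractions == 1

    def test_prune_noisy_leaf_example(self):
        res = prune(NOISY_LEAF_T1, "d")
        expect = {s("gh|abcef"), s("fgh|abce"), s("efgh|abc"), s("aefgh|bc")}
        assert res.tree.nontrivial_splits == frozenset(expect)
        assert res.forced_contractions == 1

    def test_prune_star(self):
        star = LeafTree(set("abcde"))
        res = prune(star, "a")
        assert res.tree == LeafTree(set("bcde")) and res.forced_contractions == 0

    def test_prune_errors(self):
        with pytest.raises(ValueError):
            prune(REFINEMENT_T1, "z")

    def test_forced_contractions_equal_split_drop(self):
        rng = random.Random(11)
        for _ in range(50):
            t = random_leaftree(rng, "abcdefg")
            leaf = rng.choice(sorted(t.leafset))
            res = prune(t, leaf)
            assert res.forced_contractions == len(t.nontrivial_splits) - len(
                res.tree.nontrivial_splits
            )


class TestRestrictTree:
    def test_identity_restriction(self):
        assert restrict_tree(REFINEMENT_T1, REFINEMENT_T1.leafset) == REFINEMENT_T1

    def test_noisy_leaf_restriction(self):
        r = restrict_tree(NOISY_LEAF_T1, set("abcefh"))
        assert r.nontrivial_splits == frozenset(
            {s("fh|abce"), s("efh|abc"), s("aefh|bc")}
        )

    def test_three_leaf_restriction_is_star(self):
        assert restrict_tree(NOISY_LEAF_T1, set("abc")).is_star()

    def test_restriction_equals_iterated_pruning_any_order(self):
        import itertools

        rng = random.Random(5)
        for _ in range(20):
            t = random_leaftree(rng, "abcdefg")
            removed = rng.sample(sorted(t.leafset), 3)
            expected = restrict_tree(t, t.leafset - frozenset(removed))
            for order in itertools.permutations(removed):
                cur = t
                for leaf in order:
                    cur = prune(cur, leaf).tree
                assert cur == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            restrict_tree(REFINEMENT_T1, set("az"))
        with pytest.raises(ValueError):
            restrict_tree(REFINEMENT_T1, set())


class TestNewick:
    def test_parse_polytomy(self):
        t = tree_from_newick("((a,b),(c,d),e);")
        assert t.leafset == frozenset("abcde")
        assert t.nontrivial_splits == frozenset({s("ab|cde"), s("cd|abe")})

    def test_parse_two_leaves(self):
        assert tree_from_newick("(a,b);") == LeafTree(set("ab"))

    def test_degree_two_root_suppressed(self):
        rooted = tree_from_newick("((a,b),((c,d),e));")
        unrooted = tree_from_newick("((a,b),(c,d),e);")
        assert rooted == unrooted

    def test_branch_lengths_and_internal_labels_ignored(self):
        t = tree_from_newick("((a:0.1,b:0.2)x:0.3,(c,d)y,e);")
        assert t.nontrivial_splits == frozenset({s("ab|cde"), s("cd|abe")})

    def test_malformed_and_duplicates_rejected(self):
        with pytest.raises(ValueError):
            tree_from_newick("((a,b,;")
        with pytest.raises(ValueError):
            tree_from_newick("((a,b),(a,c),d);")

    @given(st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_random_trees(self, seed):
        rng = random.Random(seed)
        t = random_leaftree(rng, "abcdefgh"[: rng.randint(4, 8)])
        assert tree_from_newick(tree_to_newick(t)) == t


class TestSplitFiles:
    def test_read_fixture_profile(self):
        trees = trees_from_split_text((DATA / "refinement_pair.txt").read_text())
        assert trees == [REFINEMENT_T1, REFINEMENT_T2]

    def test_roundtrip(self):
        rng = random.Random(3)
        trees = [random_leaftree(rng, "abcdef") for _ in range(3)]
        assert trees_from_split_text(trees_to_split_text(trees)) == trees

    def test_comments_and_blank_lines(self):
        text = "# header\na b | c d e\n\n# second tree\na b | c d e  # inline\na b e | c d\n"
        trees = trees_from_split_text(text)
        assert trees == [REFINEMENT_T2, REFINEMENT_T1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trees_from_split_text("# nothing\n")


class TestOperationOrderIndependence:
    def test_shuffled_scripts_reach_same_tree(self):
        # contraction and pruning steps commute whenever each remains
        # applicable, so shuffled orders agree on the final tree
        rng = random.Random(99)
        for _ in range(30):
            t = random_leaftree(rng, "abcdefgh")
            splits = rng.sample(sorted(t.nontrivial_splits), min(2, len(t.nontrivial_splits)))
            leaves = rng.sample(sorted(t.leafset), 2)
            results = set()
            for _ in range(6):
                ops = [("c", sp) for sp in splits] + [("p", lf) for lf in leaves]
                rng.shuffle(ops)
                cur, ok = t, True
                for kind, target in ops:
                    if kind == "c":
                        if target not in cur.nontrivial_splits:
                            ok = False
                            break
                        cur = contract(cur, target)
                    else:
                        cur = prune(cur, target).tree
                if ok:
                    results.add(cur)
            assert len(results) <= 1
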