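"""Trees, bipartitions, Fitch parsimony and the homoplasy index."""

import itertools

import dendropy
import numpy as np
import pytest

from rgccam.phylo import (
    Bipartition,
    Tree,
    TreeError,
    bootstrap_support,
    enumerate_unrooted_trees,
    fitch_length,
    homoplasy_index,
    min_length_any_tree,
    parse_newick,
    parsimony_search,
    site_bipartition,
    support_table,
    tree_bipartitions,
)
from rgccam.scan import CAM, scan_alignment
from rgccam.simulate import generate_alignment

TAXA5 = ("c", "p", "m", "k", "b")


def brute_force_fitch(newick: str, states: dict) -> int:
    """Independent parsimony oracle: enumerate every assignment of observed
    states to the internal vertices of a dendropy-parsed tree and count
    mismatched edges.  Complete data only."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    observed = sorted(set(states.values()))
    edges = [
        (e.tail_node, e.head_node)
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None
    ]

    def state_of(node, assignment):
        if node.is_leaf():
            return states[node.taxon.label]
        return assignment[internals.index(node)]

    best = len(edges)
    for assignment in itertools.product(observed, repeat=len(internals)):
        cost = sum(state_of(u, assignment) != state_of(v, assignment) for u, v in edges)
        best = min(best, cost)
    return best


def pattern(groups: dict) -> dict:
    """taxon -> state map from state -> taxa-string shorthand."""
    return {t: s for s, taxa in groups.items() for t in taxa}


class TestParseNewick:
    def test_yeast_tree(self, yeast_tree):
        assert set(yeast_tree.taxa) == set(TAXA5)
        names = {b.name for b in tree_bipartitions(yeast_tree)}
        assert names == {"cp", "bk"}

    def test_rooted_input_is_unrooted(self, yeast_tree):
        rooted = parse_newick("(((c,p),m),(k,b));")
        assert rooted == yeast_tree

    def test_two_leaves_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("(a,b);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((a,a),b,c);")

    def test_polytomy_rejected_unless_allowed(self):
        text = "(a,b,c,d,e);"
        with pytest.raises(TreeError):
            parse_newick(text)
        star = parse_newick(text, allow_polytomies=True)
        assert tree_bipartitions(star) == frozenset()

    def test_newick_round_trip_preserves_bipartitions(self):
        for tree in enumerate_unrooted_trees(tuple("abcdef")):
            again = parse_newick(tree.to_newick())
            assert again == tree


class TestBipartition:
    def test_canonical_block_is_smaller(self):
        b = Bipartition(block=frozenset("cpm"), taxa=frozenset(TAXA5))
        assert b.block == frozenset("kb")
        assert b.name == "bk"

    def test_from_name_accepts_any_letter_order(self):
        taxa = frozenset(TAXA5)
        assert Bipartition.from_name("kb", taxa) == Bipartition.from_name("bk", taxa)

    def test_binary_tree_has_n_minus_3_bipartitions(self):
        for n in (4, 5, 6):
            taxa = tuple("abcdefgh"[:n])
            for tree in enumerate_unrooted_trees(taxa)[:10]:
                assert len(tree_bipartitions(tree)) == n - 3


class TestSiteBipartition:
    def test_nc_column_induces_kb_split(self, cam_matrix):
        from rgccam.scan import classify_site, SiteRecord

        cls, groups = classify_site(("N", "N", "N", "C", "C"), TAXA5, cam_matrix)
        rec = SiteRecord(0, ("N", "N", "N", "C", "C"), cls, groups)
        bip = site_bipartition(rec, TAXA5)
        assert bip.block == frozenset("kb")

    def test_alternating_column_groups_p_and_k(self, cam_matrix):
        from rgccam.scan import classify_site, SiteRecord

        column = ("D", "H", "D", "H", "D")
        cls, groups = classify_site(column, TAXA5, cam_matrix)
        rec = SiteRecord(0, column, cls, groups)
        bip = site_bipartition(rec, TAXA5)
        assert bip.block == frozenset("pk")
        assert bip.block | bip.other_block == frozenset(TAXA5)

    def test_three_groups_rejected(self, cam_matrix):
        from rgccam.scan import classify_site, SiteRecord

        column = ("N", "N", "C", "C", "W")
        cls, groups = classify_site(column, ("a", "b", "c", "d", "e"), cam_matrix)
        rec = SiteRecord(0, column, cls, groups)
        with pytest.raises(TreeError):
            site_bipartition(rec)


class TestFitchLength:
    def test_compatible_split_costs_one(self, yeast_tree):
        assert fitch_length(pattern({"N": "cpm", "C": "kb"}), yeast_tree) == 1

    def test_conflicting_split_costs_two(self, yeast_tree):
        assert fitch_length(pattern({"N": "cb", "C": "pmk"}), yeast_tree) == 2

    def test_constant_site_costs_zero(self, yeast_tree):
        assert fitch_length({t: "A" for t in TAXA5}, yeast_tree) == 0

    def test_missing_data_is_wildcard(self, yeast_tree):
        states = {"c": "N", "p": "N", "m": None, "k": "C", "b": "C"}
        assert fitch_length(states, yeast_tree) == 1

    def test_matches_brute_force_on_random_sites_and_trees(self):
        rng = np.random.default_rng(42)
        trees = enumerate_unrooted_trees(TAXA5)
        for _ in range(60):
            tree = trees[rng.integers(len(trees))]
            n_states = int(rng.integers(1, 4))
            letters = "NCDW"[:n_states]
            states = {t: letters[rng.integers(n_states)] for t in TAXA5}
            assert tree.fitch_length(states) == brute_force_fitch(tree.to_newick(), states)

    def test_six_taxon_sites_match_brute_force(self):
        rng = np.random.default_rng(7)
        taxa = tuple("abcdef")
        trees = enumerate_unrooted_trees(taxa)
        for _ in range(20):
            tree = trees[rng.integers(len(trees))]
            states = {t: "XY"[rng.integers(2)] for t in taxa}
            assert tree.fitch_length(states) == brute_force_fitch(tree.to_newick(), states)

    def test_taxon_mismatch_rejected(self, yeast_tree):
        with pytest.raises(TreeError):
            yeast_tree.fitch_length({"c": "A"})


class TestMinLengthAnyTree:
    def test_state_count_minus_one(self):
        assert min_length_any_tree(pattern({"N": "cpm", "C": "kb"})) == 1
        assert min_length_any_tree(pattern({"N": "cp", "C": "mk", "W": "b"})) == 2
        assert min_length_any_tree({t: "A" for t in TAXA5}) == 0

    def test_equals_minimum_over_all_topologies(self):
        rng = np.random.default_rng(3)
        trees = enumerate_unrooted_trees(TAXA5)
        for _ in range(30):
            n_states = int(rng.integers(1, 4))
            states = {t: "NCD"[:n_states][rng.integers(n_states)] for t in TAXA5}
            exhaustive = min(t.fitch_length(states) for t in trees)
            assert min_length_any_tree(states) == exhaustive


class TestHomoplasyIndex:
    def test_supporting_site_scores_zero(self, yeast_tree):
        assert homoplasy_index(pattern({"N": "cpm", "C": "kb"}), yeast_tree).hi == 0.0

    def test_conflicting_site_scores_half(self, yeast_tree):
        assert homoplasy_index(pattern({"N": "cb", "C": "pmk"}), yeast_tree).hi == 0.5

    def test_constant_site_scores_zero(self, yeast_tree):
        assert homoplasy_index({t: "A" for t in TAXA5}, yeast_tree).hi == 0.0

    def test_informative_two_state_sites_take_only_two_values(self, yeast_tree):
        # every 3+2 grouping of the five taxa
        for block in itertools.combinations(TAXA5, 2):
            rest = "".join(t for t in TAXA5 if t not in block)
            hi = homoplasy_index(pattern({"N": rest, "C": "".join(block)}), yeast_tree).hi
            assert hi in (0.0, 0.5)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105)])
    def test_double_factorial_counts(self, n, count):
        trees = enumerate_unrooted_trees(tuple("abcdefgh"[:n]))
        assert len(trees) == count
        assert len({t.bipartitions() for t in trees}) == count  # duplicate-free

    def test_out_of_range_rejected(self):
        with pytest.raises(TreeError):
            enumerate_unrooted_trees(("a", "b", "c"))


class TestParsimonySearch:
    def test_planted_signal_recovers_yeast_topology(self, yeast_tree):
        plan = {("kb", CAM): 10, ("cp", CAM): 10}
        aln, _ = generate_alignment(TAXA5, plan, seed=0)
        best, length = parsimony_search(aln)
        assert best == [yeast_tree]
        assert length == 20

    def test_constant_alignment_ties_all_topologies(self):
        plan = {}
        aln, _ = generate_alignment(TAXA5, plan, n_constant=4, seed=0)
        best, length = parsimony_search(aln)
        assert length == 0
        assert len(best) == 15

    def test_tree_length_formula_for_two_state_sites(self, yeast_tree):
        # length = (n - m) + 2m with m homoplastic sites on the best tree
        plan = {("kb", CAM): 10, ("cp", CAM): 10, ("cb", CAM): 3}
        aln, _ = generate_alignment(TAXA5, plan, seed=1)
        best, length = parsimony_search(aln)
        assert yeast_tree in best
        assert length == (23 - 3) + 2 * 3


class TestBootstrap:
    def test_clean_signal_gives_full_support(self, yeast_tree):
        aln, _ = generate_alignment(TAXA5, {("kb", CAM): 10, ("cp", CAM): 10}, seed=0)
        support = bootstrap_support(aln, yeast_tree, replicates=50, seed=5)
        assert all(v == 100.0 for v in support.values())

    def test_identical_seed_identical_support(self, yeast_tree):
        plan = {("kb", CAM): 8, ("cp", CAM): 8, ("cb", CAM): 4}
        aln, _ = generate_alignment(TAXA5, plan, seed=2)
        a = bootstrap_support(aln, yeast_tree, replicates=40, seed=9)
        b = bootstrap_support(aln, yeast_tree, replicates=40, seed=9)
        assert a == b

    def test_any_semantics_at_least_as_generous_as_strict(self, yeast_tree):
        plan = {("kb", CAM): 5, ("cp", CAM): 5, ("cb", CAM): 4, ("bm", CAM): 3}
        aln, _ = generate_alignment(TAXA5, plan, seed=3)
        strict = bootstrap_support(aln, yeast_tree, replicates=40, seed=11)
        anysem = bootstrap_support(aln, yeast_tree, replicates=40, seed=11, semantics="any")
        for bip in strict:
            assert anysem[bip] >= strict[bip]


class TestSupportTable:
    def test_counts_and_supporting_fraction(self, cam_matrix, yeast_tree):
        plan = {("kb", CAM): 3, ("cb", CAM): 1}
        aln, _ = generate_alignment(TAXA5, plan, seed=0)
        records = scan_alignment(aln, cam_matrix).records
        table = support_table(records, TAXA5)
        by_name = {b.name: c for b, c in table.counts.items()}
        assert by_name == {"bk": 3, "bc": 1}
        assert table.total == 4
        supporting, conflicting = table.split_by_tree(yeast_tree)
        assert sum(supporting.values()) / table.total == 0.75

    def test_empty_records_give_empty_table(self):
        table = support_table([], TAXA5)
        assert table.counts == {} and table.total == 0

    def test_counts_sum_to_record_count(self, cam_matrix):
        plan = {("kb", CAM): 4, ("cp", CAM): 2, ("pm", CAM): 1}
        aln, _ = generate_alignment(TAXA5, plan, seed=4)
        records = scan_alignment(aln, cam_matrix).records
        table = support_table(records, TAXA5)
        assert sum(table.counts.values()) == len(records) == table.total
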