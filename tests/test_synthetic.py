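"""Generators: ultrametric trees, birth-death counts, planted proteomes,
method-tree triplets."""

import numpy as np
import pytest

from npsphylome import synthetic as syn
from npsphylome.io_formats import tree_to_newick


# ---------------------------------------------------------------------------
# simulate_yule_tree
# ---------------------------------------------------------------------------

def test_yule_cherry():
    tree = syn.simulate_yule_tree(2, 5.0, seed=0)
    lengths = [l.edge.length for l in tree.leaf_node_iter()]
    assert len(lengths) == 2 and all(abs(x - 5.0) < 1e-12 for x in lengths)


def test_yule_tree_arithmetic():
    tree = syn.simulate_yule_tree(10, 1.0, seed=4)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    assert len(internal) == 9 and len(edges) == 18


@pytest.mark.parametrize("n,height", [(5, 1.0), (16, 250.0)])
def test_yule_ultrametric_and_deterministic(n, height):
    t1 = syn.simulate_yule_tree(n, height, seed=9)
    depths = []
    for leaf in t1.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depths.append(d)
    assert max(abs(d - height) for d in depths) <= 1e-9 * height
    assert tree_to_newick(t1) == tree_to_newick(syn.simulate_yule_tree(n, height, seed=9))
    with pytest.raises(ValueError):
        syn.simulate_yule_tree(1, height, seed=0)


# ---------------------------------------------------------------------------
# simulate_family_counts
# ---------------------------------------------------------------------------

def test_family_counts_lambda_zero_is_constant():
    tree = syn.simulate_yule_tree(6, 100.0, seed=2)
    cm, anc = syn.simulate_family_counts(tree, 0.0, root_count=3, n_families=5, seed=1)
    assert (cm.counts.values == 3).all()
    assert all(v == 3 for states in anc.values() for v in states.values())
    with pytest.raises(ValueError):
        syn.simulate_family_counts(tree, -0.1, 1, 1, seed=0)


def test_family_counts_martingale_mean_and_variance():
    """The equal-rates linear birth-death process is a martingale: E[tip] =
    root count, Var[tip] = 2 lambda t s."""
    tree = syn.simulate_yule_tree(4, 1.0, seed=3)
    lam, s, n = 0.5, 2, 10_000
    cm, _ = syn.simulate_family_counts(tree, lam, root_count=s, n_families=n, seed=7)
    tips = cm.counts.values.astype(float)
    mean = tips.mean(axis=1).mean()
    var_expected = 2 * lam * 1.0 * s
    se = np.sqrt(var_expected / (n * tips.shape[0]))
    assert abs(mean - s) < 3 * se
    var = tips.var()
    assert abs(var - var_expected) < 0.15 * var_expected


def test_family_counts_extinction_dominates_at_high_rate():
    tree = syn.simulate_yule_tree(4, 1.0, seed=3)
    cm, _ = syn.simulate_family_counts(tree, 20.0, root_count=1, n_families=500, seed=5)
    frac_extinct = (cm.counts.values == 0).mean()
    assert frac_extinct > 0.5  # alpha = 20/21 per unit branch


# ---------------------------------------------------------------------------
# synth_proteome
# ---------------------------------------------------------------------------

def test_proteome_zero_divergence_equals_consensus():
    records, truth, seeds = syn.synth_proteome(
        {"X": "A-T-C"}, 0.0, {"X": 2}, seed=5
    )
    consensus_a = seeds["A:X"].records[0].residues  # first copy is undiverged
    for rec in records:
        (dtype, s, e, sf) = truth.proteins[rec.id][0]
        assert dtype == "A"
        assert rec.residues[s:e] == consensus_a


def test_proteome_degenerate_module_truth():
    records, truth, _ = syn.synth_proteome(
        {"NPS6": "A-T-C-dA-T-C"}, 0.05, {"NPS6": 1}, seed=6
    )
    doms = truth.proteins[records[0].id]
    assert [d[0] for d in doms] == ["A", "T", "C", "dA", "T", "C"]
    d_a = [d for d in doms if d[0] == "dA"][0]
    assert d_a[2] - d_a[1] == syn.DOMAIN_LENGTHS["A"] // 2
    assert truth.architectures[records[0].id] == "A-T-C-dA-T-C"


def test_proteome_counts_and_unknown_token():
    _, truth, _ = syn.synth_proteome({"S": "A"}, 0.1, {"S": 5}, seed=1)
    assert sum(1 for sf in truth.subfamily_of.values() if sf == "S") == 5
    with pytest.raises(ValueError, match="unknown template token"):
        syn.synth_proteome({"S": "A-QQ"}, 0.1, {"S": 1}, seed=1)
    with pytest.raises(ValueError, match="divergence"):
        syn.synth_proteome({"S": "A"}, 0.6, {"S": 1}, seed=1)


def test_proteome_hybrid_template_and_intervals():
    records, truth, _ = syn.synth_proteome(
        {"H": "KS-AT-ACP-C-A-T-R"}, 0.1, {"H": 2}, seed=8
    )
    assert truth.architectures[records[0].id] == "C-A-T-R"
    truth.validate()
    # intervals ordered, disjoint, inside the protein
    for pid, doms in truth.proteins.items():
        prev = 0
        for _, s, e, _ in doms:
            assert prev <= s < e <= truth.protein_lengths[pid]
            prev = e


def test_proteome_between_exceeds_within_subfamily_distance():
    records, truth, _ = syn.synth_proteome(
        {"P": "A", "Q": "A"}, 0.05, {"P": 3, "Q": 3}, seed=13
    )
    def a_dom(rec):
        _, s, e, _ = truth.proteins[rec.id][0]
        return rec.residues[s:e]
    def dist(x, y):
        return sum(a != b for a, b in zip(x, y)) / len(x)
    ps = [a_dom(r) for r in records if truth.subfamily_of[r.id] == "P"]
    qs = [a_dom(r) for r in records if truth.subfamily_of[r.id] == "Q"]
    within = max(dist(ps[0], ps[1]), dist(qs[0], qs[1]))
    between = min(dist(p, q) for p in ps for q in qs)
    assert between > within


# ---------------------------------------------------------------------------
# synth_method_trees
# ---------------------------------------------------------------------------

CLADES = [["A1", "A2", "A3"], ["B1", "B2"]]


def test_method_trees_planted_supports_per_tree():
    trees = syn.synth_method_trees(5, CLADES, [(90, 90, 90), (90, 90, 65)], seed=2)
    for i, tree in enumerate(trees):
        found = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            labels = frozenset(l.taxon.label for l in node.leaf_iter())
            found[labels] = node.support
        assert found[frozenset(CLADES[0])] == 90
        assert found[frozenset(CLADES[1])] == (65 if i == 2 else 90)


def test_method_trees_zero_moves_identical():
    trees = syn.synth_method_trees(4, CLADES, [(90, 90, 90), (80, 80, 80)],
                                   seed=5, n_nni_moves=0)
    assert len({tree_to_newick(t) for t in trees}) == 1


def test_method_trees_outgroup_intact_and_errors():
    trees = syn.synth_method_trees(6, CLADES, [90, 80], seed=7, n_nni_moves=12)
    for tree in trees:
        og_nodes = [
            n for n in tree.preorder_node_iter()
            if not n.is_leaf()
            and {l.taxon.label for l in n.leaf_iter()} == {"OG1", "OG2", "OG3"}
        ]
        assert og_nodes, "outgroup clade must stay intact"
    with pytest.raises(ValueError, match="overlapping"):
        syn.synth_method_trees(4, [["A1", "A2"], ["A2", "B1"]], [90, 90], seed=1)
    with pytest.raises(ValueError, match="supports"):
        syn.synth_method_trees(4, CLADES, [(90, 90, 90), (80, 80, 101)], seed=1)
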