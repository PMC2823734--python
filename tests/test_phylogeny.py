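"""WAG+gamma ML distances, neighbor joining, bootstrap, outgroup rooting."""

import numpy as np
import pytest

from npsphylome import phylogeny as ph
from npsphylome.io_formats import Alignment, SequenceRecord, read_newick
from npsphylome.residues import AMINO
from npsphylome.synthetic import simulate_yule_tree


@pytest.fixture(scope="module")
def model():
    return ph.EvolModel(alpha=1.0)


def _tree_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(tax)
    D = np.array([[pdm.distance(tax[a], tax[b]) for b in labels] for a in labels])
    return labels, D


# ---------------------------------------------------------------------------
# Model and distances
# ---------------------------------------------------------------------------

def test_model_invariants(model):
    assert abs(model.pi.sum() - 1) < 1e-12
    assert abs(model.rates.mean() - 1) < 1e-12
    assert (np.diff(model.rates) > 0).all()
    P = model.mixture_matrix(0.7)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
    # detailed balance of the underlying chain: pi_x P_xy = pi_y P_yx
    bal = model.pi[:, None] * P
    assert np.allclose(bal, bal.T, atol=1e-12)


def test_distance_identical_and_symmetry(model):
    s1, s2 = ph.simulate_wag_pair(0.4, 800, model, seed=1)
    assert ph.wag_gamma_distance(s1, s1, model) <= 1e-6
    d12 = ph.wag_gamma_distance(s1, s2, model)
    d21 = ph.wag_gamma_distance(s2, s1, model)
    assert d12 == pytest.approx(d21, abs=1e-9)


def test_distance_simulation_oracle(model):
    s1, s2 = ph.simulate_wag_pair(0.5, 10_000, model, seed=7)
    d = ph.wag_gamma_distance(s1, s2, model)
    assert abs(d - 0.5) < 0.05


def test_distance_bias_shrinks_with_sites(model):
    errors = []
    for n_sites in (500, 5_000, 50_000):
        errs = [
            abs(ph.wag_gamma_distance(*ph.simulate_wag_pair(0.5, n_sites, model,
                                                            seed=100 + r), model) - 0.5)
            for r in range(3)
        ]
        errors.append(np.mean(errs))
    assert errors[2] < errors[0]
    assert errors[2] < 0.02


def test_distance_gaps_and_errors(model):
    assert ph.wag_gamma_distance("AC-E", "AC-E", model) <= 1e-6
    with pytest.raises(ValueError, match="comparable"):
        ph.wag_gamma_distance("A-", "-A", model)
    with pytest.raises(ValueError, match="aligned"):
        ph.wag_gamma_distance("AA", "AAA", model)


def test_saturated_pairs_capped(model):
    rng = np.random.default_rng(0)
    s1 = "".join(rng.choice(list(AMINO), 400))
    s2 = "".join(rng.choice(list(AMINO), 400))
    assert ph.wag_gamma_distance(s1, s2, model) <= ph.MAX_DISTANCE


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxon_closed_form():
    D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    tree = ph.neighbor_joining(D, ["A", "B", "C"])
    lens = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lens == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_nj_additive_four_taxon():
    # tree ((A:1,B:2):1,(C:3,D:4)): additive distances
    D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    tree = ph.neighbor_joining(D, list("ABCD"))
    assert frozenset({"C", "D"}) in ph.tree_bipartitions(tree) or \
        frozenset({"A", "B"}) in ph.tree_bipartitions(tree)
    _, back = _tree_distances(tree)
    assert np.allclose(back, D, atol=1e-9)  # least-squares residual 0


def test_nj_validation_errors():
    bad = np.array([[0, 1.0], [1.0, 0]])
    with pytest.raises(ValueError, match="at least 3"):
        ph.neighbor_joining(bad, ["A", "B"])
    asym = np.array([[0, 1, 2], [1.1, 0, 2], [2, 2, 0]], float)
    with pytest.raises(ValueError, match="asymmetric"):
        ph.neighbor_joining(asym, list("ABC"))


@pytest.mark.parametrize("seed", range(50))
def test_nj_consistent_on_additive_distances(seed):
    """NJ recovers the generating topology from exact path-length distances
    of random ultrametric 8-leaf trees."""
    tree = simulate_yule_tree(8, 1.0, seed=seed)
    labels, D = _tree_distances(tree)
    rebuilt = ph.neighbor_joining(D, labels)
    assert ph.tree_bipartitions(rebuilt) == ph.tree_bipartitions(tree)


def test_nj_recovers_12_leaf_generated_topology():
    tree = simulate_yule_tree(12, 2.0, seed=99)
    labels, D = _tree_distances(tree)
    rebuilt = ph.neighbor_joining(D, labels)
    assert ph.tree_bipartitions(rebuilt) == ph.tree_bipartitions(tree)
    _, back = _tree_distances(rebuilt)
    assert np.allclose(back, D, atol=1e-9)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment(seed=5, div=0.05, n_each=4, length=300):
    rng = np.random.default_rng(seed)
    def mutate(s, p):
        out = list(s)
        for i in range(len(out)):
            if rng.random() < p:
                out[i] = AMINO[(AMINO.index(out[i]) + rng.integers(1, 20)) % 20]
        return "".join(out)
    c1 = "".join(rng.choice(list(AMINO), length))
    c2 = mutate(c1, 0.5)
    recs = [SequenceRecord(f"x{i}", mutate(c1, div)) for i in range(n_each)]
    recs += [SequenceRecord(f"y{i}", mutate(c2, div)) for i in range(n_each)]
    return Alignment(recs)


def test_bootstrap_strong_signal_and_determinism(model):
    aln = _two_clade_alignment()
    tree = ph.bootstrap_support(aln, n_replicates=100, seed=3, model=model)
    supports = {}
    all_labels = frozenset(aln.ids())
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.support is None:
            continue
        labels = frozenset(l.taxon.label for l in node.leaf_iter())
        supports[labels] = node.support
        assert 0 <= node.support <= 100
    clade_x = frozenset(l for l in all_labels if l.startswith("x"))
    clade_y = all_labels - clade_x
    planted = [s for ls, s in supports.items() if ls in (clade_x, clade_y)]
    assert planted and all(s >= 95 for s in planted)
    tree2 = ph.bootstrap_support(aln, n_replicates=100, seed=3, model=model)
    s2 = {
        frozenset(l.taxon.label for l in n.leaf_iter()): n.support
        for n in tree2.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
    }
    assert supports == {k: v for k, v in s2.items() if v is not None or k in supports}


def test_bootstrap_invariant_to_row_order(model):
    aln = _two_clade_alignment(n_each=3, length=200)
    rev = Alignment(list(reversed(aln.records)))
    def support_map(a):
        t = ph.bootstrap_support(a, n_replicates=25, seed=9, model=model)
        return {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.support
            for n in t.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        }
    assert support_map(aln) == support_map(rev)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def test_root_single_outgroup():
    tree = read_newick("(A,B,(C,D));")
    rooted = ph.root_with_outgroup(tree, {"A"})
    kids = rooted.seed_node.child_nodes()
    sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
    assert frozenset({"A"}) in sides
    assert frozenset({"B", "C", "D"}) in sides
    assert {l.taxon.label for l in rooted.leaf_node_iter()} == {"A", "B", "C", "D"}


def test_root_monophyletic_outgroup_and_supports():
    tree = read_newick("((A:1,B:1)80:1,(C:1,D:1)90:2,E:1);")
    rooted = ph.root_with_outgroup(tree, {"C", "D"})
    sides = {
        frozenset(l.taxon.label for l in k.leaf_iter()): k
        for k in rooted.seed_node.child_nodes()
    }
    assert frozenset({"C", "D"}) in sides
    # supports re-attach to the same bipartitions
    for node in rooted.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        labels = frozenset(l.taxon.label for l in node.leaf_iter())
        if labels == frozenset({"A", "B"}):
            assert node.support == 80
        if labels == frozenset({"C", "D"}):
            assert node.support == 90
    with pytest.raises(ValueError, match="empty outgroup"):
        ph.root_with_outgroup(tree, set())
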