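"""Linear birth-death transition probabilities, pruning likelihood, rate
estimation, parsimony root filter, Monte-Carlo p-values, Viterbi branches.

Oracles: the alternating-sign closed form from the gene-family literature,
the matrix exponential of the truncated generator, and the event-driven
(Gillespie) simulator from the synthetic module.
"""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import comb

from npsphylome import birthdeath as bd
from npsphylome.io_formats import read_newick
from npsphylome.synthetic import (
    _gillespie_bd,
    simulate_family_counts,
    simulate_yule_tree,
)


def bailey_form(s, c, t, lam):
    """Alternating-sign closed form (independent oracle for bdp_transition)."""
    if lam * t == 0:
        return float(c == s)
    if s == 0:
        return float(c == 0)
    a = lam * t / (1 + lam * t)
    return float(sum(
        comb(s, j) * comb(s + c - j - 1, s - 1)
        * a ** (s + c - 2 * j) * (1 - 2 * a) ** j
        for j in range(0, min(s, c) + 1)
    ))


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def test_transition_identity_and_absorption():
    assert bd.bdp_transition(3, 3, 0.0, 0.7) == 1.0
    assert bd.bdp_transition(3, 2, 0.0, 0.7) == 0.0
    assert bd.bdp_transition(0, 0, 5.0, 0.7) == 1.0
    assert bd.bdp_transition(0, 4, 5.0, 0.7) == 0.0
    with pytest.raises(ValueError):
        bd.bdp_transition(1, 1, 1.0, -0.1)


def test_single_lineage_extinction_probability():
    # alpha = lam*t/(1+lam*t) = 1/3 at lam=0.5, t=1
    assert bd.bdp_transition(1, 0, 1.0, 0.5) == pytest.approx(1 / 3, abs=1e-12)


def test_equals_alternating_closed_form():
    for s in range(0, 7):
        for c in range(0, 7):
            for lt in (0.2, 0.45, 0.8):
                assert bd.bdp_transition(s, c, lt, 1.0) == pytest.approx(
                    bailey_form(s, c, lt, 1.0), abs=1e-11
                ), (s, c, lt)


def test_matrix_exponential_oracle():
    cmax, lam, t = 30, 0.7, 1.3
    Q = np.zeros((cmax + 1, cmax + 1))
    for i in range(1, cmax + 1):
        Q[i, i - 1] = i * lam
        if i < cmax:
            Q[i, i + 1] = i * lam
        Q[i, i] = -Q[i].sum()
    P_exp = expm(Q * t)
    P = bd.transition_matrix(t, lam, cmax, renormalize=False)
    assert np.allclose(P_exp[:10, :12], P[:10, :12], atol=1e-6)


def test_row_sums_one():
    for lt in (0.1, 0.5, 1.0, 2.0):
        P = bd.transition_matrix(lt, 1.0, 100, renormalize=False)
        assert np.abs(P[:11].sum(axis=1) - 1.0).max() <= 1e-9


def test_gillespie_simulation_oracle():
    """Closed form within 3 sigma of event-driven simulation frequencies."""
    rng = np.random.default_rng(1)
    n = 20_000
    for s, lt in [(1, 0.5), (2, 1.0), (3, 0.3)]:
        outcomes = np.array([_gillespie_bd(s, lt, 1.0, rng) for _ in range(n)])
        for c in range(0, 7):
            p = bd.bdp_transition(s, c, lt, 1.0)
            se = max(np.sqrt(p * (1 - p) / n), 1e-4)
            assert abs((outcomes == c).mean() - p) < 3.5 * se, (s, c, lt)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def test_single_edge_tree_closed_form():
    tree = read_newick("(A:2.0);")
    model = bd.BDPModel(lam=0.4, c_max=12)
    ll = bd.family_loglikelihood(tree, {"A": 3}, model)
    expected = sum(
        model.root_prior[s] * bd.transition_matrix(2.0, 0.4, 12)[s, 3]
        for s in range(13)
    )
    assert ll == pytest.approx(np.log(expected), abs=1e-10)


@pytest.mark.parametrize("newick,tips", [
    ("((A:1,B:1):1,C:2);", {"A": 2, "B": 1, "C": 3}),
    ("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", {"A": 2, "B": 0, "C": 1, "D": 4}),
])
def test_pruning_equals_exhaustive_enumeration(newick, tips):
    cmax = 10
    model = bd.BDPModel(lam=0.8, c_max=cmax)
    tree = read_newick(newick)
    ll = bd.family_loglikelihood(tree, tips, model)

    P = {}
    def trans(s, c, t):
        if t not in P:
            P[t] = bd.transition_matrix(t, 0.8, cmax)
        return P[t][s, c]

    def enumerate_node(node, state):
        if node.is_leaf():
            return 1.0
        total_by_assignment = 1.0
        for child in node.child_nodes():
            t = child.edge.length
            if child.is_leaf():
                total_by_assignment *= trans(state, tips[child.taxon.label], t)
            else:
                total_by_assignment *= sum(
                    trans(state, m, t) * enumerate_node(child, m)
                    for m in range(cmax + 1)
                )
        return total_by_assignment

    brute = sum(
        model.root_prior[r] * enumerate_node(tree.seed_node, r)
        for r in range(cmax + 1)
    )
    assert ll == pytest.approx(np.log(brute), abs=1e-9)


def test_likelihood_plateaus_with_cmax():
    """With the root state held fixed, growing the truncation bound changes
    the likelihood less and less (truncation property)."""
    tree = simulate_yule_tree(5, 1.0, seed=2)
    tips = {f"T{i}": c for i, c in zip(range(1, 6), [2, 3, 1, 2, 4])}
    lls = [
        bd.family_loglikelihood(
            tree, tips,
            bd.BDPModel(lam=0.6, c_max=cm, root_prior=bd._point_prior(2, cm)),
        )
        for cm in (8, 16, 32, 64)
    ]
    assert abs(lls[1] - lls[0]) > abs(lls[2] - lls[1])
    assert abs(lls[3] - lls[2]) / abs(lls[3]) < 1e-10


def test_likelihood_preconditions():
    tree = simulate_yule_tree(4, 1.0, seed=1)
    model = bd.BDPModel(lam=0.5, c_max=5)
    with pytest.raises(ValueError, match="without counts"):
        bd.family_loglikelihood(tree, {"T1": 1}, model)
    bad = read_newick("((A:1,B:2):1,C:2);")  # not ultrametric
    with pytest.raises(ValueError, match="ultrametric"):
        bd.family_loglikelihood(bad, {"A": 1, "B": 1, "C": 1}, model)


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def test_lambda_zero_event_limit():
    tree = simulate_yule_tree(5, 10.0, seed=4)
    fams = [{f"T{i}": 2 for i in range(1, 6)} for _ in range(5)]
    with pytest.warns(UserWarning, match="lower bound"):
        lam = bd.estimate_lambda(fams, tree)
    assert lam <= 1e-6


def test_lambda_recovery_single_design():
    tree = simulate_yule_tree(10, 1000.0, seed=3)
    cm, _ = simulate_family_counts(tree, 0.002, root_count=2, n_families=100,
                                   seed=4, condition_on_survival=True)
    lam = bd.estimate_lambda(cm, tree)
    assert abs(lam - 0.002) / 0.002 < 0.3


def test_lambda_optimality():
    tree = simulate_yule_tree(6, 100.0, seed=5)
    cm, _ = simulate_family_counts(tree, 0.005, root_count=2, n_families=30,
                                   seed=6, condition_on_survival=True)
    lam = bd.estimate_lambda(cm, tree)
    fams = bd._families_from(cm)
    def total_ll(l):
        model = bd.BDPModel(lam=l, c_max=2 * int(cm.counts.values.max()) + 10)
        return sum(bd.family_loglikelihood(tree, f, model) for f in fams)
    best = total_ll(lam)
    assert best >= total_ll(lam * 1.1) - 1e-9
    assert best >= total_ll(lam * 0.9) - 1e-9


# ---------------------------------------------------------------------------
# Parsimony root filter
# ---------------------------------------------------------------------------

def test_parsimony_examples():
    tri = read_newick("(A,B,C);")
    assert bd.parsimony_root_count(tri, {"A": 2, "B": 2, "C": 1}) == 2
    assert bd.parsimony_root_count(tri, {"A": 1, "B": 1, "C": 1}) == 1
    # ACV-like pattern: present in one lineage only -> root 0 -> excluded
    tree = simulate_yule_tree(6, 1.0, seed=7)
    acv = {f"T{i}": (1 if i == 2 else 0) for i in range(1, 7)}
    assert bd.parsimony_root_count(tree, acv) == 0


def test_analyze_families_excludes_root_zero():
    tree = simulate_yule_tree(5, 200.0, seed=8)
    cm, _ = simulate_family_counts(tree, 0.004, root_count=2, n_families=10,
                                   seed=9, condition_on_survival=True)
    df = cm.counts.copy()
    df["acv_like"] = [1 if i == 0 else 0 for i in range(len(df))]
    from npsphylome.io_formats import CountMatrix
    lam, results, excluded = bd.analyze_families(
        tree, CountMatrix(df), n_resamples=200, seed=1
    )
    # the planted single-lineage family is excluded; simulated null families
    # that happen to survive in one lineage only may legitimately join it
    assert "acv_like" in excluded
    scored = {r.family for r in results}
    assert "acv_like" not in scored
    assert scored | set(excluded) == set(df.columns)
    assert all(0 < r.p_value <= 1 for r in results)


# ---------------------------------------------------------------------------
# Monte-Carlo p-values and Viterbi branches
# ---------------------------------------------------------------------------

def test_family_pvalue_extremes():
    tree = simulate_yule_tree(8, 500.0, seed=3)
    model = bd.BDPModel(lam=0.002, c_max=30)
    pool = bd.simulate_null_logliks(tree, model, 1000, seed=11)
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    extreme = {l: 1 for l in leaves}
    extreme[leaves[0]] = 10
    assert bd.family_pvalue(tree, extreme, model, null_pool=pool) <= 0.05
    modal = {l: 15 for l in leaves}  # near the uniform root prior's middle
    assert bd.family_pvalue(tree, modal, model, null_pool=pool) > 0.5
    # add-one rule bounds
    assert bd.family_pvalue(tree, extreme, model, null_pool=pool) >= 1 / 1001


def test_null_pvalues_uniform():
    """Families simulated under the fitted null give uniform p-values
    (KS test at alpha = 0.01)."""
    import scipy.stats as sps
    tree = simulate_yule_tree(8, 500.0, seed=3)
    model = bd.BDPModel(lam=0.002, c_max=30)
    pool = bd.simulate_null_logliks(tree, model, 1000, seed=21)
    obs = bd.simulate_null_logliks(tree, model, 500, seed=22)
    ps = np.array([(1 + (pool <= o + 1e-12).sum()) / (len(pool) + 1) for o in obs])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_viterbi_modal_branch_and_bounds():
    tree = read_newick("((A:0.001,B:0.001):0.999,C:1.0);")
    model = bd.BDPModel(lam=0.1, c_max=10)
    tips = {"A": 2, "B": 2, "C": 2}
    ancestral, branch = bd.viterbi_branch_pvalues(tree, tips, model)
    for lbl in ("A", "B"):
        assert branch[lbl]["direction"] == "none"
        assert branch[lbl]["p"] == pytest.approx(1.0, abs=1e-6)
    assert all(0 < info["p"] <= 1 for info in branch.values())


def test_viterbi_flags_planted_jump():
    """A forced 1 -> 8 expansion on one ~50 My branch is flagged."""
    tree = simulate_yule_tree(8, 500.0, seed=13)
    target = next(
        nd for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
        and 30 <= nd.edge.length <= 80
    )
    inside = {l.taxon.label for l in target.leaf_iter()}
    tips = {l.taxon.label: (8 if l.taxon.label in inside else 1)
            for l in tree.leaf_node_iter()}
    model = bd.BDPModel(lam=0.002, c_max=30)
    ancestral, branch = bd.viterbi_branch_pvalues(tree, tips, model)
    flagged = [lbl for lbl, info in branch.items()
               if info["p"] < 0.05 and info["direction"] == "expansion"]
    assert target.label in flagged
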