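"""Gene-family expansion/contraction under a linear birth-death process.

The model: each gene in a family duplicates and is lost at the same rate
λ (events per gene per time unit, the time unit being that of the species
tree, My for dated trees); zero genes is absorbing.  The transition
probability from ``s`` genes to ``c`` genes over time ``t`` has the closed
form (with α = λt/(1+λt), the single-lineage extinction probability)

    P(c|s,t) = Σ_{k=1..min(s,c)} C(s,k) C(c-1,k-1) α^{s+c-2k} (1-α)^{2k}
    P(0|s,t) = α^s

— every term positive, so it is evaluated stably in log space.  (The
alternating-sign form Σ_j C(s,j) C(s+c−j−1,s−1) α^{s+c−2j} (1−2α)^j quoted in
the gene-family literature is algebraically identical; the tests assert the
equality and also check against a matrix-exponential and a Gillespie oracle.)

On an ultrametric species tree the family likelihood is computed by pruning
over a truncated state space, a single global λ is fitted by maximizing the
summed log-likelihood across families, family-level significance comes from
Monte-Carlo resampling under the fitted model, and per-branch significance
from the most-probable (Viterbi) joint ancestral reconstruction: a branch's
p-value is the total probability of parent→child transitions no more probable
than the reconstructed one.  Families inferred by parsimony to have zero
genes at the root are excluded from fitting (the model assumes presence at
the root).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import gammaln, logsumexp

from .io_formats import CountMatrix

__all__ = [
    "BDPModel",
    "FamilyResult",
    "bdp_transition",
    "transition_matrix",
    "family_loglikelihood",
    "estimate_lambda",
    "parsimony_root_count",
    "family_pvalue",
    "viterbi_branch_pvalues",
    "simulate_null_logliks",
    "analyze_families",
]


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def bdp_transition(s: int, c: int, t: float, lam: float) -> float:
    """P(c genes at time t | s genes at time 0) for the equal-rates linear
    birth-death process; state 0 is absorbing."""
    if s < 0 or c < 0 or t < 0 or lam < 0:
        raise ValueError("s, c, t and lambda must all be non-negative")
    if lam * t == 0:
        return 1.0 if c == s else 0.0
    if s == 0:
        return 1.0 if c == 0 else 0.0
    alpha = lam * t / (1.0 + lam * t)
    if c == 0:
        return alpha ** s
    la, l1a = np.log(alpha), np.log1p(-alpha)
    kmax = min(s, c)
    ks = np.arange(1, kmax + 1)
    terms = (
        gammaln(s + 1) - gammaln(ks + 1) - gammaln(s - ks + 1)
        + gammaln(c) - gammaln(ks) - gammaln(c - ks + 1)
        + (s + c - 2 * ks) * la
        + 2 * ks * l1a
    )
    return float(np.exp(logsumexp(terms)))


def transition_matrix(
    t: float, lam: float, c_max: int, renormalize: bool = True
) -> np.ndarray:
    """(c_max+1) x (c_max+1) matrix of P(c|s,t); rows renormalized to absorb
    truncation error."""
    N = c_max + 1
    if lam * t == 0:
        return np.eye(N)
    alpha = lam * t / (1.0 + lam * t)
    la, l1a = np.log(alpha), np.log1p(-alpha)
    lg = gammaln(np.arange(2 * N + 2))
    logM = np.full((N, N), -np.inf)
    s_idx = np.arange(N)
    c_idx = np.arange(N)
    for k in range(1, N):
        s = s_idx[k:]
        c = c_idx[k:]
        logC_sk = lg[s + 1] - lg[k + 1] - lg[s - k + 1]
        logC_ck = lg[c] - lg[k] - lg[c - k + 1]
        term = (
            logC_sk[:, None] + logC_ck[None, :]
            + (s[:, None] + c[None, :] - 2 * k) * la
            + 2 * k * l1a
        )
        logM[k:, k:] = np.logaddexp(logM[k:, k:], term)
    P = np.exp(logM)
    P[:, 0] = alpha ** s_idx
    P[0, :] = 0.0
    P[0, 0] = 1.0
    if renormalize:
        P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Model and tree utilities
# ---------------------------------------------------------------------------

@dataclass
class BDPModel:
    """Global birth(=death) rate with a truncated state space and root prior
    (default: uniform over 1..c_max, excluding extinction at the root)."""

    lam: float
    c_max: int
    root_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")
        if self.root_prior is None:
            prior = np.zeros(self.c_max + 1)
            prior[1:] = 1.0 / self.c_max
            self.root_prior = prior
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if len(self.root_prior) != self.c_max + 1:
                raise ValueError("root_prior must have c_max + 1 entries")
            if self.root_prior[0] != 0:
                raise ValueError("root_prior must exclude state 0")
            if abs(self.root_prior.sum() - 1.0) > 1e-9:
                raise ValueError("root_prior must sum to 1")

    def edge_matrices(self, tree: dendropy.Tree) -> dict[float, np.ndarray]:
        lengths = {
            round(nd.edge.length, 12)
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        }
        return {t: transition_matrix(t, self.lam, self.c_max) for t in lengths}


def _leaf_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._depth = 0.0
        else:
            node._depth = node.parent_node._depth + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label if node.taxon else node.label] = node._depth
    return depths


def check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> float:
    """Return the tree height; raise if root-to-leaf depths differ beyond
    ``rel_tol`` relative tolerance."""
    depths = list(_leaf_depths(tree).values())
    height = max(depths)
    if height <= 0:
        raise ValueError("tree has zero height")
    if (height - min(depths)) / height > rel_tol:
        raise ValueError("tree is not ultrametric within tolerance")
    return height


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label


def _require_labels(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if _node_label(node) is None:
            k += 1
            node.label = f"N{k}"


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _pruning_batch(
    tree: dendropy.Tree,
    tip_matrix: np.ndarray,  # (n_families, n_leaves) in leaf order
    leaf_order: list[str],
    model: BDPModel,
    matrices: dict | None = None,
) -> np.ndarray:
    """Vectorized pruning over families; returns log-likelihood per family."""
    N = model.c_max + 1
    nfam = tip_matrix.shape[0]
    if (tip_matrix > model.c_max).any():
        raise ValueError("tip count exceeds the state-space bound c_max")
    mats = matrices or model.edge_matrices(tree)
    col = {lbl: i for i, lbl in enumerate(leaf_order)}
    logscale = np.zeros(nfam)

    def _visit(node: dendropy.Node) -> np.ndarray:
        nonlocal logscale
        if node.is_leaf():
            counts = tip_matrix[:, col[_node_label(node)]]
            vec = np.zeros((nfam, N))
            vec[np.arange(nfam), counts] = 1.0
            return vec
        vec = np.ones((nfam, N))
        for child in node.child_nodes():
            child_vec = _visit(child)
            P = mats[round(child.edge.length, 12)]
            vec *= child_vec @ P.T
        m = vec.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        logscale += np.where(m > 0, np.log(safe), -np.inf)
        return vec / safe[:, None]

    root_vec = _visit(tree.seed_node)
    lik = root_vec @ model.root_prior
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def family_loglikelihood(
    tree: dendropy.Tree,
    tip_counts: dict[str, int],
    model: BDPModel,
    matrices: dict | None = None,
) -> float:
    """Pruning log-likelihood of one family's tip counts."""
    check_ultrametric(tree)
    leaves = [_node_label(lf) for lf in tree.leaf_node_iter()]
    missing = [lf for lf in leaves if lf not in tip_counts]
    if missing:
        raise ValueError(f"tips without counts: {missing}")
    mat = np.asarray([[tip_counts[lf] for lf in leaves]], dtype=int)
    return float(_pruning_batch(tree, mat, leaves, model, matrices)[0])


def _families_from(counts) -> list[dict[str, int]]:
    if isinstance(counts, CountMatrix):
        return [
            {sp: int(counts.counts.loc[sp, fam]) for sp in counts.species}
            for fam in counts.subfamilies
        ]
    return list(counts)


def estimate_lambda(
    counts,
    tree: dendropy.Tree,
    c_max: int | None = None,
) -> float:
    """Global λ maximizing the summed family log-likelihood (bounded scalar
    search on [1e-8, 10/height])."""
    families = _families_from(counts)
    if not families:
        raise ValueError("no families to fit")
    height = check_ultrametric(tree)
    for fam in families:
        if all(v == 0 for v in fam.values()):
            raise ValueError("family extinct at every tip; cannot fit")
    max_count = max(max(f.values()) for f in families)
    if c_max is None:
        c_max = 2 * max_count + 10
    leaves = [_node_label(lf) for lf in tree.leaf_node_iter()]
    tip_matrix = np.asarray([[f[lf] for lf in leaves] for f in families], dtype=int)

    def neg_loglik(lam: float) -> float:
        model = BDPModel(lam=lam, c_max=c_max)
        return -float(_pruning_batch(tree, tip_matrix, leaves, model).sum())

    lo, hi = 1e-8, 10.0 / height
    res = optimize.minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    lam_hat = float(res.x)
    if lam_hat <= lo * 10:
        warnings.warn("lambda estimate at the lower bound (no birth-death signal)",
                      stacklevel=2)
    return lam_hat


# ---------------------------------------------------------------------------
# Parsimony root filter
# ---------------------------------------------------------------------------

def parsimony_root_count(tree: dendropy.Tree, tip_counts: dict[str, int]) -> int:
    """Sankoff minimum-cost root state under |Δcount| edge costs (smallest
    state on ties).  Families with root 0 are excluded from birth-death
    fitting."""
    max_state = max(tip_counts.values())
    n_states = max_state + 1
    INF = float("inf")

    def _min_abs_transform(g: np.ndarray) -> np.ndarray:
        h = g.copy()
        for s in range(1, n_states):
            h[s] = min(h[s], h[s - 1] + 1)
        for s in range(n_states - 2, -1, -1):
            h[s] = min(h[s], h[s + 1] + 1)
        return h

    def _visit(node: dendropy.Node) -> np.ndarray:
        if node.is_leaf():
            g = np.full(n_states, INF)
            g[tip_counts[_node_label(node)]] = 0.0
            return g
        total = np.zeros(n_states)
        for child in node.child_nodes():
            total += _min_abs_transform(_visit(child))
        return total

    costs = _visit(tree.seed_node)
    return int(np.argmin(costs))


# ---------------------------------------------------------------------------
# Monte-Carlo family p-values
# ---------------------------------------------------------------------------

def simulate_null_logliks(
    tree: dendropy.Tree,
    model: BDPModel,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Log-likelihoods of ``n`` families simulated from the root prior under
    the fitted model on the same tree."""
    rng = np.random.default_rng(seed)
    mats = model.edge_matrices(tree)
    cumrows = {}
    for t, P in mats.items():
        C = np.cumsum(P, axis=1)
        C[:, -1] = 1.0  # guard against rounding so sampling never overflows
        cumrows[t] = C
    _require_labels(tree)
    states: dict[str, np.ndarray] = {}
    leaves = []
    for node in tree.preorder_node_iter():
        lbl = _node_label(node)
        if node.parent_node is None:
            states[lbl] = rng.choice(model.c_max + 1, size=n, p=model.root_prior)
        else:
            C = cumrows[round(node.edge.length, 12)]
            u = rng.random(n)
            parent = states[_node_label(node.parent_node)]
            states[lbl] = (u[:, None] > C[parent]).sum(axis=1)
        if node.is_leaf():
            leaves.append(lbl)
    tip_matrix = np.column_stack([states[lf] for lf in leaves]).astype(int)
    return _pruning_batch(tree, tip_matrix, leaves, model, mats)


def family_pvalue(
    tree: dendropy.Tree,
    tip_counts: dict[str, int],
    model: BDPModel,
    n_resamples: int = 1000,
    seed: int = 0,
    null_pool: np.ndarray | None = None,
) -> float:
    """Monte-Carlo family p-value: the proportion of simulated families whose
    log-likelihood is at or below the observed one, with the add-one rule so
    p ∈ [1/(n+1), 1]."""
    if null_pool is None:
        if n_resamples < 100:
            raise ValueError("n_resamples must be >= 100")
        null_pool = simulate_null_logliks(tree, model, n_resamples, seed)
    obs = family_loglikelihood(tree, tip_counts, model)
    n = len(null_pool)
    return float((1 + np.sum(null_pool <= obs + 1e-12)) / (n + 1))


# ---------------------------------------------------------------------------
# Viterbi ancestral states and branch p-values
# ---------------------------------------------------------------------------

def viterbi_branch_pvalues(
    tree: dendropy.Tree,
    tip_counts: dict[str, int],
    model: BDPModel,
) -> tuple[dict[str, int], dict[str, dict]]:
    """Most probable joint ancestral counts (ties to the smaller state) and,
    per edge, the exact tail probability of parent→child transitions no more
    probable than the reconstructed one, with its direction."""
    _require_labels(tree)
    N = model.c_max + 1
    mats = model.edge_matrices(tree)
    with np.errstate(divide="ignore"):
        logmats = {t: np.log(P) for t, P in mats.items()}

    back: dict[str, np.ndarray] = {}

    def _visit(node: dendropy.Node) -> np.ndarray:
        if node.is_leaf():
            v = np.full(N, -np.inf)
            v[tip_counts[_node_label(node)]] = 0.0
            return v
        total = np.zeros(N)
        for child in node.child_nodes():
            child_v = _visit(child)
            scores = logmats[round(child.edge.length, 12)] + child_v[None, :]
            back[_node_label(child)] = np.argmax(scores, axis=1)  # ties -> smaller
            total += np.max(scores, axis=1)
        return total

    root_scores = _visit(tree.seed_node) + np.log(
        np.where(model.root_prior > 0, model.root_prior, 1e-300)
    )
    ancestral: dict[str, int] = {}
    root_lbl = _node_label(tree.seed_node)
    ancestral[root_lbl] = int(np.argmax(root_scores))
    for node in tree.preorder_node_iter():
        lbl = _node_label(node)
        if node.parent_node is None:
            continue
        parent_state = ancestral[_node_label(node.parent_node)]
        if node.is_leaf():
            ancestral[lbl] = int(tip_counts[lbl])
        else:
            ancestral[lbl] = int(back[lbl][parent_state])

    branch_p: dict[str, dict] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lbl = _node_label(node)
        s = ancestral[_node_label(node.parent_node)]
        c = ancestral[lbl]
        row = mats[round(node.edge.length, 12)][s]
        p = float(row[row <= row[c] + 1e-15].sum())
        direction = "expansion" if c > s else ("contraction" if c < s else "none")
        branch_p[lbl] = {
            "p": min(p, 1.0),
            "direction": direction,
            "parent_count": s,
            "child_count": c,
        }
    return ancestral, branch_p


# ---------------------------------------------------------------------------
# Whole-analysis orchestration
# ---------------------------------------------------------------------------

@dataclass
class FamilyResult:
    family: str
    log_likelihood: float
    p_value: float
    ancestral_counts: dict[str, int] = field(default_factory=dict)
    branch_p: dict[str, dict] = field(default_factory=dict)


def _point_prior(root: int, c_max: int) -> np.ndarray:
    prior = np.zeros(c_max + 1)
    prior[root] = 1.0
    return prior


def analyze_families(
    tree: dendropy.Tree,
    count_matrix: CountMatrix,
    n_resamples: int = 1000,
    seed: int = 0,
    lam: float | None = None,
    c_max: int | None = None,
    root_mode: str = "parsimony",
) -> tuple[float, list[FamilyResult], list[str]]:
    """Fit a global λ and score every family.

    Families whose parsimony root count is zero are excluded from both the
    fit and the per-family scoring (returned as the third element).

    ``root_mode`` sets the root prior used for family p-values and ancestral
    states: ``"parsimony"`` (default) conditions each family on its parsimony
    root count — null families are simulated from the same root state, so the
    p-value asks how surprising the tip configuration is for a family of that
    ancestral size; ``"uniform"`` uses the uninformative prior over 1..c_max
    throughout.
    """
    if root_mode not in ("parsimony", "uniform"):
        raise ValueError("root_mode must be 'parsimony' or 'uniform'")
    check_ultrametric(tree)
    _require_labels(tree)
    names = count_matrix.subfamilies
    fams = _families_from(count_matrix)
    included, excluded = [], []
    for name, fam in zip(names, fams):
        if parsimony_root_count(tree, fam) == 0:
            excluded.append(name)
        else:
            included.append((name, fam))
    if not included:
        raise ValueError("no families with non-zero parsimony root count")
    if lam is None:
        lam = estimate_lambda([f for _, f in included], tree, c_max=c_max)
    max_count = max(max(f.values()) for _, f in included)
    cmx = c_max if c_max is not None else 2 * max_count + 10
    base_model = BDPModel(lam=lam, c_max=cmx)

    pools: dict[int | None, np.ndarray] = {}
    models: dict[int | None, BDPModel] = {None: base_model}

    def _pool_for(root: int | None) -> tuple[BDPModel, np.ndarray]:
        if root not in models:
            models[root] = BDPModel(lam=lam, c_max=cmx, root_prior=_point_prior(root, cmx))
        if root not in pools:
            pool_seed = seed if root is None else seed * 1000003 + root
            pools[root] = simulate_null_logliks(tree, models[root], n_resamples, pool_seed)
        return models[root], pools[root]

    results = []
    for name, fam in included:
        root = parsimony_root_count(tree, fam) if root_mode == "parsimony" else None
        model, null_pool = _pool_for(root)
        ll = family_loglikelihood(tree, fam, model)
        p = float((1 + np.sum(null_pool <= ll + 1e-12)) / (len(null_pool) + 1))
        ancestral, branch = viterbi_branch_pvalues(tree, fam, model)
        results.append(FamilyResult(name, ll, p, ancestral, branch))
    return lam, results, excluded
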