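"""Distance-based phylogenies for A-domain alignments.

Pairwise distances are maximum-likelihood estimates under the WAG
amino-acid replacement model with discrete-gamma rate heterogeneity
(four equal-probability categories, category rate = mean of its quantile
bin).  Trees are built by neighbor joining with deterministic tie-breaking,
bootstrap supports come from column resampling, and rooting on a declared
outgroup re-attaches supports to the same (unrooted) bipartitions.
"""

from __future__ import annotations

import numpy as np
import dendropy
from scipy import optimize
from scipy import stats as sps

from .io_formats import Alignment
from .residues import AA_INDEX, AMINO, N_AA
from .wag_data import AA_ORDER, WAG_FREQS, WAG_RATES

__all__ = [
    "EvolModel",
    "wag_gamma_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "simulate_wag_pair",
    "MAX_DISTANCE",
]

MAX_DISTANCE = 10.0
MIN_DISTANCE = 1e-6

# WAG constants are tabulated in the ARNDCQEGHILKMFPSTWYV order; remap them
# once onto the package's canonical alphabet.
_PERM = np.asarray([AA_ORDER.index(aa) for aa in AMINO])


def _wag_exchangeabilities() -> np.ndarray:
    R = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(N_AA):           # column-major lower triangle
        for j in range(i + 1, N_AA):
            R[j, i] = R[i, j] = WAG_RATES[k]
            k += 1
    return R[np.ix_(_PERM, _PERM)]


def _wag_frequencies() -> np.ndarray:
    pi = np.asarray(WAG_FREQS)[_PERM]
    return pi / pi.sum()


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rate of each equal-probability gamma quantile bin (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    k = n_categories
    edges = sps.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    upper = sps.gamma.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    return rates / rates.mean() * 1.0


class EvolModel:
    """WAG + discrete-gamma substitution model with precomputed spectral
    decomposition (``+F`` observed frequencies via the ``freqs`` argument)."""

    def __init__(self, alpha: float = 1.0, n_categories: int = 4, freqs=None):
        self.alpha = float(alpha)
        self.n_categories = int(n_categories)
        self.pi = _wag_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi <= 0).any():
            raise ValueError("stationary frequencies must be positive and sum to 1")
        self.rates = discrete_gamma_rates(self.alpha, self.n_categories)

        R = _wag_exchangeabilities()
        Q = R * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(self.pi * np.diag(Q))
        Q /= mu  # one expected substitution per site per unit distance
        sq = np.sqrt(self.pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._w = w
        self._left = V / sq[None, :].T   # D^{-1/2} V
        self._right = (V * sq[:, None]).T  # V^T D^{1/2}

    def transition_matrix(self, d: float, rate: float = 1.0) -> np.ndarray:
        P = (self._left * np.exp(self._w * rate * d)) @ self._right
        return np.clip(P, 1e-300, None)

    def mixture_matrix(self, d: float) -> np.ndarray:
        """Rate-category average of the transition matrices at distance d."""
        out = np.zeros((N_AA, N_AA))
        for r in self.rates:
            out += self.transition_matrix(d, r)
        return out / self.n_categories


def _encode_rows(alignment: Alignment) -> np.ndarray:
    mat = np.full((len(alignment), alignment.column_count), -1, dtype=np.int16)
    for i, rec in enumerate(alignment):
        for j, ch in enumerate(rec.residues):
            mat[i, j] = AA_INDEX.get(ch, -1)
    return mat


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        return np.zeros(N_AA * N_AA)
    return np.bincount(
        (a[ok].astype(np.int64) * N_AA + b[ok]), minlength=N_AA * N_AA
    ).astype(float)


def _ml_distance(counts: np.ndarray, model: EvolModel) -> float:
    total = counts.sum()
    if total == 0:
        raise ValueError("zero comparable (gap-free) sites between sequences")
    diag = counts.reshape(N_AA, N_AA).trace()
    if diag == total:
        return MIN_DISTANCE
    nz = counts > 0
    cnz = counts[nz]

    def neg_loglik(d: float) -> float:
        M = model.mixture_matrix(d).ravel()[nz]
        return -float(cnz @ np.log(M))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(MIN_DISTANCE, MAX_DISTANCE), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(min(res.x, MAX_DISTANCE))


def wag_gamma_distance(seq1: str, seq2: str, model: EvolModel | None = None) -> float:
    """ML pairwise distance; sites where either sequence has a gap (or an
    unrecognized residue) are ignored; saturated pairs are capped at 10."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned (equal length)")
    model = model or EvolModel()
    a = np.asarray([AA_INDEX.get(c, -1) for c in seq1], dtype=np.int16)
    b = np.asarray([AA_INDEX.get(c, -1) for c in seq2], dtype=np.int16)
    return _ml_distance(_pair_counts(a, b), model)


def distance_matrix(alignment: Alignment, model: EvolModel | None = None):
    """All pairwise WAG+gamma ML distances; returns (labels, matrix)."""
    model = model or EvolModel()
    rows = _encode_rows(alignment)
    labels = alignment.ids()
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _ml_distance(_pair_counts(rows[i], rows[j]), model)
    return labels, D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei agglomeration with deterministic tie-breaking.

    Negative intermediate branch lengths are clamped to zero with the deficit
    moved to the sister edge.  Returns an unrooted tree (trifurcating root).
    Q-criterion ties (within 1e-12) pick the lexicographically smallest label
    pair.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.abs(D - D.T).max() > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond tolerance 1e-9")
    if (D < 0).any() or np.abs(np.diag(D)).max() > 0:
        raise ValueError("distances must be non-negative with zero diagonal")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # smallest leaf label under each active node
    for lbl in labels:
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(lbl)
        nodes.append(nd)
        reps.append(lbl)
    work = D.copy()
    active = list(range(n))

    def _clamped(li: float, lj: float, total: float) -> tuple[float, float]:
        if li < 0:
            return 0.0, total
        if lj < 0:
            return total, 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tie_idx = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in tie_idx
            if i < j
        )
        _, ai, aj = best
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamped(li, lj, dij)

        parent = dendropy.Node()
        ci, cj = nodes[i_glob], nodes[j_glob]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(li, 0.0)
        cj.edge.length = max(lj, 0.0)

        new_d = 0.5 * (work[i_glob, active] + work[j_glob, active] - dij)
        work = np.pad(work, ((0, 1), (0, 1)))
        k_glob = work.shape[0] - 1
        work[k_glob, active] = new_d
        work[active, k_glob] = new_d
        work[k_glob, k_glob] = 0.0
        nodes.append(parent)
        reps.append(min(reps[i_glob], reps[j_glob]))
        active = [g for g in active if g not in (i_glob, j_glob)] + [k_glob]

    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    a, b, c = active
    la = 0.5 * (work[a, b] + work[a, c] - work[b, c])
    lb = 0.5 * (work[a, b] + work[b, c] - work[a, c])
    lc = 0.5 * (work[a, c] + work[b, c] - work[a, b])
    for g, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[g])
        nodes[g].edge.length = max(ln, 0.0)
    for node in tree.preorder_node_iter():
        node.support = None
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, rooting
# ---------------------------------------------------------------------------

def _leaf_labels(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _canonical_bipartition(side: frozenset, all_labels: frozenset) -> frozenset:
    anchor = min(all_labels)
    return all_labels - side if anchor in side else side


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each canonicalized to the side not
    containing the alphabetically first leaf."""
    all_labels = _leaf_labels(tree.seed_node)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _canonical_bipartition(_leaf_labels(node), all_labels)
        if len(side) >= 2 and len(all_labels) - len(side) >= 2:
            out.add(side)
    return out


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 200,
    seed: int = 0,
    model: EvolModel | None = None,
) -> dendropy.Tree:
    """NJ tree on the full alignment with bootstrap supports.

    Columns are resampled with replacement to the original length per
    replicate; support on each internal edge is the percentage of replicate
    trees containing the identical leaf-set bipartition, rounded to the
    nearest integer.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model = model or EvolModel()
    rows = _encode_rows(alignment)
    labels = alignment.ids()
    # deterministic in row order: sort rows by label for the distance pass
    order = np.argsort(labels)
    rows = rows[order]
    labels = [labels[i] for i in order]
    n = len(labels)

    def _nj_from_rows(mat: np.ndarray) -> dendropy.Tree:
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = _ml_distance(_pair_counts(mat[i], mat[j]), model)
        return neighbor_joining(D, labels)

    full_tree = _nj_from_rows(rows)
    all_labels = frozenset(labels)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncol = rows.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = _nj_from_rows(rows[:, cols])
        for bip in tree_bipartitions(rep_tree):
            counts[bip] = counts.get(bip, 0) + 1
    for node in full_tree.preorder_node_iter():
        node.support = None
        if node.parent_node is None or node.is_leaf():
            continue
        side = _canonical_bipartition(_leaf_labels(node), all_labels)
        if len(side) >= 2 and len(all_labels) - len(side) >= 2:
            node.support = float(round(100.0 * counts.get(side, 0) / n_replicates))
    return full_tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root on the edge subtending the smallest clade holding all outgroup
    labels (split at its midpoint); supports are re-attached to the same
    unrooted bipartitions.  The input tree is not modified."""
    outgroup_labels = set(outgroup_labels)
    if not outgroup_labels:
        raise ValueError("empty outgroup")
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # treat the seed node as root for MRCA queries
    all_labels = _leaf_labels(tree.seed_node)
    missing = outgroup_labels - all_labels
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")

    support_by_bip: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        sup = getattr(node, "support", None)
        if sup is not None:
            support_by_bip[_canonical_bipartition(_leaf_labels(node), all_labels)] = sup

    taxa = [tree.taxon_namespace.get_taxon(l) for l in sorted(outgroup_labels)]
    mrca = tree.mrca(taxa=taxa)
    if mrca is tree.seed_node:
        ingroup = sorted(all_labels - outgroup_labels)
        if ingroup:
            taxa_in = [tree.taxon_namespace.get_taxon(l) for l in ingroup]
            mrca = tree.mrca(taxa=taxa_in)
    if mrca is not tree.seed_node:
        edge = mrca.edge
        if edge.length is not None:
            half = edge.length / 2.0
            tree.reroot_at_edge(edge, length1=half, length2=half)
        else:
            tree.reroot_at_edge(edge)
    # else: outgroup spans the trifurcation; root stays above their MRCA

    for node in tree.preorder_node_iter():
        node.support = None
        if node.parent_node is None or node.is_leaf():
            continue
        bip = _canonical_bipartition(_leaf_labels(node), all_labels)
        if bip in support_by_bip:
            node.support = support_by_bip[bip]
    return tree


# ---------------------------------------------------------------------------
# Simulation oracle helpers
# ---------------------------------------------------------------------------

def simulate_wag_pair(
    d: float, n_sites: int, model: EvolModel | None = None, seed: int = 0
) -> tuple[str, str]:
    """A pair of aligned sequences separated by true distance d under the
    model (used as the estimator's simulation oracle)."""
    model = model or EvolModel()
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, model.n_categories, size=n_sites)
    x = rng.choice(N_AA, size=n_sites, p=model.pi)
    y = np.empty(n_sites, dtype=np.int64)
    u = rng.random(n_sites)
    for k, rate in enumerate(model.rates):
        sel = cats == k
        if not sel.any():
            continue
        P = model.transition_matrix(d, rate)
        C = np.cumsum(P, axis=1)
        C[:, -1] = 1.0
        y[sel] = (u[sel, None] > C[x[sel]]).sum(axis=1)
    s1 = "".join(AMINO[i] for i in x)
    s2 = "".join(AMINO[i] for i in y)
    return s1, s2
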