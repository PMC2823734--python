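"""Synthetic inputs with recorded ground truth for every pipeline stage.

Four generators, all pure functions of (parameters, seed):

* :func:`simulate_yule_tree` — ultrametric species trees (pure-birth, rescaled
  to a fixed height).
* :func:`simulate_family_counts` — integer gene counts evolved on an
  ultrametric tree under a linear birth-death process with equal per-gene
  birth and death rate (state 0 absorbing), with all internal-node states
  recorded.  This is an event-driven (Gillespie) simulation, so it doubles as
  an independent oracle for the closed-form transition probabilities.
* :func:`synth_proteome` — proteins assembled from per-domain-type consensus
  sequences into modular architectures (A-T-C repeats, degenerate A domains,
  standalone A, C-terminal R), with per-subfamily consensus offsets so that
  between-subfamily distance exceeds within-subfamily distance, plus seed
  alignments for profile building.
* :func:`synth_method_trees` — triplets of bootstrap-annotated trees that
  agree exactly on planted clades and differ elsewhere by random NNI moves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io_formats import Alignment, CountMatrix, SequenceRecord
from .residues import AMINO, N_AA

__all__ = [
    "DOMAIN_LENGTHS",
    "SyntheticTruth",
    "simulate_yule_tree",
    "simulate_family_counts",
    "synth_proteome",
    "synth_method_trees",
]

# Approximate real domain sizes so planted coordinates are realistic.
DOMAIN_LENGTHS = {"A": 480, "T": 80, "C": 430, "R": 340}

NRPS_TOKENS = {"A", "dA", "T", "C", "R"}
# Non-NRPS tokens seen in hybrid megasynthases; emitted as inert segments.
INERT_TOKENS = {"KS", "AT", "ACP", "KR", "M", "E", "Cyc", "PKS", "TE", "D", "FeR", "X"}
INERT_LENGTH = 300


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators.

    ``proteins`` maps protein id to ordered ``(domain_type, start, end,
    subfamily)`` tuples with 0-based half-open residue coordinates.
    """

    seed: int
    proteins: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)
    protein_lengths: dict[str, int] = field(default_factory=dict)
    subfamily_of: dict[str, str] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)
    architectures: dict[str, str] = field(default_factory=dict)
    planted_clades: list[tuple[frozenset, tuple]] = field(default_factory=list)
    family_params: tuple[int, float] | None = None

    def validate(self) -> None:
        for pid, domains in self.proteins.items():
            plen = self.protein_lengths[pid]
            prev_end = 0
            for dtype, start, end, _sf in domains:
                if not (0 <= start < end <= plen):
                    raise AssertionError(f"{pid}: interval [{start},{end}) outside [0,{plen})")
                if start < prev_end:
                    raise AssertionError(f"{pid}: overlapping or unordered planted intervals")
                prev_end = end
        if self.family_params is not None:
            root_count, lam = self.family_params
            if root_count < 1 or lam < 0:
                raise AssertionError("invalid family parameters")


# ---------------------------------------------------------------------------
# Ultrametric species trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_taxa: int, height: float, seed: int, prefix: str = "T"
) -> dendropy.Tree:
    """Pure-birth tree on ``n_taxa`` leaves rescaled to root-to-tip ``height``.

    The tree is binary and ultrametric (every root-to-leaf path length equals
    ``height`` exactly up to float rounding); internal nodes are labelled
    ``N1..`` in preorder so ancestral states can be reported against them.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if height <= 0:
        raise ValueError("height must be > 0")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    root = tree.seed_node
    root.birth_time = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            child.birth_time = t
            active.append(child)
    total = t + rng.exponential(1.0 / n_taxa)
    scale = height / total

    tns = dendropy.TaxonNamespace()
    tree.taxon_namespace = tns
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"{prefix}{i}")
    # Edge lengths from scaled event times; pendant edges pinned to height.
    for node in tree.preorder_node_iter():
        if node is root:
            node.depth = 0.0
            node.edge.length = None
            continue
        parent_depth = node.parent_node.depth
        if node.is_leaf():
            node.edge.length = height - parent_depth
            node.depth = height
        else:
            node.depth = node.split_time * scale
            node.edge.length = node.depth - parent_depth
    k = itertools.count(1)
    for node in tree.preorder_node_iter():
        node.support = None
        if not node.is_leaf():
            node.label = f"N{next(k)}"
    return tree


# ---------------------------------------------------------------------------
# Birth-death gene counts
# ---------------------------------------------------------------------------

def _gillespie_bd(count: int, t: float, lam: float, rng: np.random.Generator) -> int:
    """Evolve a linear birth-death process (birth rate = death rate = lam per
    gene) for time ``t``; 0 is absorbing."""
    remaining = t
    while count > 0:
        rate = 2.0 * lam * count
        if rate <= 0:
            break
        remaining -= rng.exponential(1.0 / rate)
        if remaining < 0:
            break
        count += 1 if rng.random() < 0.5 else -1
    return count


def ensure_node_labels(tree: dendropy.Tree) -> None:
    """Give every node a stable label (taxon label for leaves, N<k> preorder
    labels for unlabeled internal nodes)."""
    k = itertools.count(1)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label if node.taxon else node.label
        elif node.label is None:
            node.label = f"N{next(k)}"


def simulate_family_counts(
    tree: dendropy.Tree,
    lam: float,
    root_count: int,
    n_families: int,
    seed: int,
    condition_on_survival: bool = False,
    family_prefix: str = "fam",
) -> tuple[CountMatrix, dict[str, dict[str, int]]]:
    """Simulate gene-family counts on an ultrametric tree.

    Returns the tip CountMatrix (species x family) and the full ancestral
    truth (family -> node label -> count, including the root).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if root_count < 1:
        raise ValueError("root_count must be >= 1")
    rng = np.random.default_rng(seed)
    ensure_node_labels(tree)
    leaves = [nd.label for nd in tree.leaf_node_iter()]
    ancestral: dict[str, dict[str, int]] = {}
    columns: dict[str, list[int]] = {}
    width = len(str(n_families))
    for i in range(n_families):
        fam = f"{family_prefix}{i + 1:0{width}d}"
        for _attempt in range(10_000):
            states: dict[str, int] = {}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    states[node.label] = root_count
                else:
                    states[node.label] = _gillespie_bd(
                        states[node.parent_node.label], node.edge.length, lam, rng
                    )
            if not condition_on_survival or any(states[lf] > 0 for lf in leaves):
                break
        ancestral[fam] = states
        columns[fam] = [states[lf] for lf in leaves]
    counts = pd.DataFrame(columns, index=pd.Index(leaves, name="species"))
    return CountMatrix(counts=counts), ancestral


# ---------------------------------------------------------------------------
# Proteomes with planted domain architectures
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, N_AA, size=length, dtype=np.int8)

def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability p (never to the
    same residue)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, N_AA, size=n, dtype=np.int8)) % N_AA
    return out

def _to_str(seq: np.ndarray) -> str:
    return "".join(AMINO[i] for i in seq)


def parse_template(template: str) -> list[str]:
    """Expand a template such as ``(A-T-C)x2`` or ``A-T-C-dA-T-C`` into a
    token list; unknown tokens raise."""
    text = template.replace("×", "x")
    tokens: list[str] = []
    i = 0
    while i < len(text):
        if text[i] == "(":
            j = text.index(")", i)
            inner = text[i + 1:j]
            k = j + 1
            reps = 1
            if k < len(text) and text[k] == "x":
                k += 1
                m = k
                while m < len(text) and text[m].isdigit():
                    m += 1
                reps = int(text[k:m])
                k = m
            tokens.extend(parse_template(inner) * reps)
            i = k + 1 if k < len(text) and text[k] == "-" else k
        else:
            j = text.find("-", i)
            # '(' may follow within a dash-joined run
            jp = text.find("(", i)
            if jp != -1 and (j == -1 or jp < j):
                j = jp - 1 if jp > i else j
            tok = text[i:j] if j != -1 else text[i:]
            tok = tok.strip("-")
            if tok:
                if tok not in NRPS_TOKENS and tok not in INERT_TOKENS:
                    raise ValueError(f"unknown template token {tok!r} in {template!r}")
                tokens.append(tok)
            i = (j + 1) if j != -1 else len(text)
    return tokens


def synth_proteome(
    architecture_templates: dict[str, str],
    divergence: float,
    counts_per_subfamily: dict,
    seed: int,
    subfamily_offset: float = 0.30,
    n_seed_sequences: int = 10,
    seed_divergence: float = 0.02,
) -> tuple[list[SequenceRecord], SyntheticTruth, dict[str, Alignment]]:
    """Generate a proteome of modular synthetases with known coordinates.

    ``counts_per_subfamily`` maps subfamily -> gene count, or subfamily ->
    {species -> gene count} for a multi-species proteome.  Each A domain is a
    subfamily-specific consensus — the shared A consensus with a disjoint
    block of ``subfamily_offset`` of its sites substituted (capped at
    1/n_subfamilies so blocks stay disjoint) — further mutated at
    ``divergence`` per site; T, C and R domains share one consensus per type.  Degenerate A domains (``dA``) are
    the N-terminal half of the subfamily consensus.  Seed alignments
    (``n_seed_sequences`` lightly diverged copies) are emitted per subfamily
    for A and per type for T, C, R, keyed ``"A:<subfamily>"`` / ``"T"`` ...
    """
    if not (0 <= divergence < 0.5):
        raise ValueError("divergence must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    subfamilies = sorted(architecture_templates)
    tokenized = {sf: parse_template(architecture_templates[sf]) for sf in subfamilies}

    base = {d: _random_seq(rng, n) for d, n in DOMAIN_LENGTHS.items()}
    # Subfamily A consensuses mutate *disjoint* site blocks of the shared
    # consensus: subfamilies share no derived residues, so the deep
    # between-subfamily splits carry no grouping signal (a hard polytomy,
    # as in real A-domain radiations) while every between-subfamily distance
    # exceeds the within-subfamily divergence.
    L_a = DOMAIN_LENGTHS["A"]
    eff_offset = min(subfamily_offset, 1.0 / max(len(subfamilies), 1))
    block = int(round(eff_offset * L_a))
    site_order = rng.permutation(L_a)
    a_consensus = {}
    for i, sf in enumerate(subfamilies):
        sites = site_order[i * block:(i + 1) * block]
        cons = base["A"].copy()
        cons[sites] = (cons[sites]
                       + rng.integers(1, N_AA, size=len(sites), dtype=np.int8)) % N_AA
        a_consensus[sf] = cons

    seed_alignments: dict[str, Alignment] = {}
    def _seed_aln(key: str, consensus: np.ndarray) -> None:
        rows = []
        for i in range(n_seed_sequences):
            div = 0.0 if i == 0 else seed_divergence
            rows.append(SequenceRecord(
                id=f"{key.replace(':', '_')}_s{i + 1}",
                residues=_to_str(_mutate(consensus, div, rng)),
            ))
        seed_alignments[key] = Alignment(rows)

    for sf in subfamilies:
        _seed_aln(f"A:{sf}", a_consensus[sf])
    for d in ("T", "C", "R"):
        _seed_aln(d, base[d])

    truth = SyntheticTruth(seed=seed)
    records: list[SequenceRecord] = []

    def _emit_gene(pid: str, sf: str, species: str | None) -> None:
        tokens = tokenized[sf]
        parts: list[np.ndarray] = []
        domains: list[tuple[str, int, int, str]] = []
        pos = 0
        def _linker(n: int) -> None:
            nonlocal pos
            parts.append(_random_seq(rng, n))
            pos += n
        _linker(int(rng.integers(10, 51)))
        for tok in tokens:
            if tok in INERT_TOKENS:
                _linker(INERT_LENGTH)
            else:
                if tok == "A":
                    cons = a_consensus[sf]
                elif tok == "dA":
                    cons = a_consensus[sf][: DOMAIN_LENGTHS["A"] // 2]
                else:
                    cons = base[tok]
                seq = _mutate(cons, divergence, rng)
                domains.append((tok, pos, pos + len(seq), sf))
                parts.append(seq)
                pos += len(seq)
            _linker(int(rng.integers(10, 51)))
        full = np.concatenate(parts)
        records.append(SequenceRecord(id=pid, residues=_to_str(full)))
        truth.proteins[pid] = domains
        truth.protein_lengths[pid] = len(full)
        truth.subfamily_of[pid] = sf
        if species is not None:
            truth.species_of[pid] = species
        truth.architectures[pid] = "-".join(t for t in tokens if t in NRPS_TOKENS)

    for sf in subfamilies:
        spec = counts_per_subfamily.get(sf, 0)
        if isinstance(spec, dict):
            for species in sorted(spec):
                for i in range(spec[species]):
                    _emit_gene(f"{species}_{sf}_g{i + 1}", sf, species)
        else:
            for i in range(int(spec)):
                _emit_gene(f"{sf}_g{i + 1}", sf, None)

    truth.validate()
    return records, truth, seed_alignments


# ---------------------------------------------------------------------------
# Tree triplets with planted subfamily clades
# ---------------------------------------------------------------------------

def _random_binary(units: list[dendropy.Node], rng: np.random.Generator) -> dendropy.Node:
    units = list(units)
    while len(units) > 1:
        i, j = sorted(rng.choice(len(units), size=2, replace=False))
        b = units.pop(j)
        a = units.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        units.append(parent)
    return units[0]

def _leafset(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def synth_method_trees(
    n_background_leaves: int,
    planted_clades: list,
    supports: list,
    seed: int,
    outgroup_labels: list[str] | None = None,
    n_nni_moves: int = 10,
) -> list[dendropy.Tree]:
    """Three trees identical on every planted clade, differing elsewhere.

    ``supports`` holds, per planted clade, a 3-tuple of supports (one per
    tree) or a single number used in all three.  A designated outgroup clade
    is kept intact with support 99; background internal edges carry one shared
    support drawn uniformly from [5, 65] (below any sensible promotion
    cutoff, so only planted clades qualify as ground truth).
    """
    clades = [frozenset(c) for c in planted_clades]
    for a, b in itertools.combinations(clades, 2):
        if a & b:
            raise ValueError(f"overlapping planted clades: {sorted(a & b)}")
    norm_supports = []
    for s in supports:
        norm_supports.append(tuple(s) if hasattr(s, "__len__") else (s, s, s))
    if len(norm_supports) != len(clades):
        raise ValueError("need one support spec per planted clade")
    for tup in norm_supports:
        if any(not (0 <= v <= 100) for v in tup):
            raise ValueError("supports must lie in [0, 100]")
    outgroup = list(outgroup_labels) if outgroup_labels else ["OG1", "OG2", "OG3"]
    rng = np.random.default_rng(seed)

    def _base_tree() -> dendropy.Tree:
        tns = dendropy.TaxonNamespace()
        def leaf(lbl: str) -> dendropy.Node:
            nd = dendropy.Node()
            nd.taxon = tns.new_taxon(lbl)
            return nd
        units = [
            _random_binary([leaf(x) for x in sorted(c)], rng) if len(c) > 1 else leaf(next(iter(c)))
            for c in clades
        ]
        units += [leaf(f"bg{i + 1}") for i in range(n_background_leaves)]
        ingroup = _random_binary(units, rng)
        og = _random_binary([leaf(x) for x in outgroup], rng) if len(outgroup) > 1 else leaf(outgroup[0])
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node.add_child(og)
        tree.seed_node.add_child(ingroup)
        return tree

    base = _base_tree()
    # Shared branch lengths and background supports so that with zero NNI
    # moves the three trees are identical.
    for node in base.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(0.05, 0.3))
    background_support = {}
    for node in base.preorder_node_iter():
        if not node.is_leaf():
            background_support[_leafset(node)] = int(rng.integers(5, 66))

    outgroup_set = frozenset(outgroup)
    trees = []
    for tree_idx in range(3):
        tree = base.clone(depth=1)
        per_tree_rng = np.random.default_rng(seed * 7919 + tree_idx + 1)
        # mark nodes inside planted clades or the outgroup; those subtrees
        # (and their stem edges) are never touched by NNI moves
        for node in tree.preorder_node_iter():
            ls = _leafset(node)
            node._locked = any(ls <= c for c in clades) or ls <= outgroup_set
        eligible = lambda tr: [
            nd for nd in tr.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
            and nd.parent_node.parent_node is not None and not nd._locked
        ]
        moves_done = 0
        attempts = 0
        while moves_done < n_nni_moves and attempts < 50 * max(1, n_nni_moves):
            attempts += 1
            cands = eligible(tree)
            if not cands:
                break
            v = cands[int(per_tree_rng.integers(len(cands)))]
            u = v.parent_node
            sibs = [c for c in u.child_nodes() if c is not v]
            children = v.child_nodes()
            if not sibs or len(children) < 2:
                continue
            b = sibs[int(per_tree_rng.integers(len(sibs)))]
            a = children[int(per_tree_rng.integers(len(children)))]
            # a and b swap as blocks; a block is a complete subtree, so planted
            # clades travel intact and their composition is preserved.
            u.remove_child(b)
            v.remove_child(a)
            u.add_child(a)
            v.add_child(b)
            moves_done += 1
        for node in tree.preorder_node_iter():
            node.support = None
            if node.is_leaf() or node.parent_node is None:
                continue
            ls = _leafset(node)
            placed = False
            for ci, c in enumerate(clades):
                if ls == c:
                    node.support = float(norm_supports[ci][tree_idx])
                    placed = True
                    break
            if not placed:
                if ls == outgroup_set:
                    node.support = 99.0
                else:
                    node.support = float(
                        background_support.get(ls, int(per_tree_rng.integers(5, 66)))
                    )
        trees.append(tree)
    return trees
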