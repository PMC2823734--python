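"""Consensus subfamily extraction across three trees and gene assignment.

A subfamily is the most internal (rootward) clade that is supported at or
above the bootstrap cutoff in all three trees, has the identical leaf-label
composition in all three, and contains at least one reference synthetase of
known function.  Clades that fail in the full-data trees can be rescued by a
reduced-dataset analysis: if the same composition is present in every full
tree and supported at or above the (higher) rescue cutoff in every rescue
tree, the clade is promoted with ``rescued=True``.

Genes are then assigned to subfamilies by majority vote over their A-domain
leaves; ties go to the N-terminal-most module and flag the gene as
recombinant (multimodular synthetases whose modules group in different
subfamilies are a documented signature of intragenic recombination).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

__all__ = ["SubfamilyCall", "GeneAssignment", "extract_subfamilies", "assign_genes"]

_LABEL_RE = re.compile(r"^(?P<protein>.+)\|m(?P<module>\d+)$")


@dataclass
class SubfamilyCall:
    name: str
    member_labels: frozenset
    supports: list[float]
    reference_members: list[str]
    rescued: bool = False


@dataclass
class GeneAssignment:
    gene: str
    subfamily: str
    recombinant: bool = False
    modules: dict[int, str] = field(default_factory=dict)


def _clade_supports(tree: dendropy.Tree) -> dict[frozenset, float | None]:
    out: dict[frozenset, float | None] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out[labels] = getattr(node, "support", None)
    return out


def extract_subfamilies(
    trees: list[dendropy.Tree],
    reference_labels,
    cutoff: float = 70.0,
    rescue_trees: list[dendropy.Tree] | None = None,
    rescue_cutoff: float = 80.0,
    outgroup_labels=None,
    names: dict[str, str] | None = None,
) -> tuple[list[SubfamilyCall], list[str]]:
    """Promote consensus clades of the three trees to subfamilies.

    Preorder traversal of tree 1 from the root; a clade is promoted when its
    support meets the cutoff in tree 1, a clade with the identical leaf set
    meets the cutoff in trees 2 and 3, and it contains a reference label.
    Once promoted the subtree is not descended further, so calls are maximal
    and pairwise disjoint.  Returns (calls, unplaced labels).
    """
    if len(trees) != 3:
        raise ValueError("exactly three trees are required")
    reference_labels = list(reference_labels)
    ref_set = set(reference_labels)
    outgroup = set(outgroup_labels) if outgroup_labels else set()

    leafsets = [
        frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees
    ]
    if not (leafsets[0] == leafsets[1] == leafsets[2]):
        diff = sorted(leafsets[0] ^ leafsets[1] | leafsets[0] ^ leafsets[2])
        raise ValueError(f"leaf sets differ across trees; symmetric difference: {diff}")

    supports2 = _clade_supports(trees[1])
    supports3 = _clade_supports(trees[2])
    rescue_maps = [_clade_supports(t) for t in (rescue_trees or [])]
    rescue_leafsets = [
        frozenset(lf.taxon.label for lf in t.leaf_node_iter())
        for t in (rescue_trees or [])
    ]

    def _meets_full(labels: frozenset, s1: float | None) -> bool:
        if s1 is None or s1 < cutoff:
            return False
        for smap in (supports2, supports3):
            s = smap.get(labels)
            if s is None or s < cutoff:
                return False
        return True

    def _meets_rescue(labels: frozenset) -> bool:
        if not rescue_maps:
            return False
        # composition must at least exist in all three full trees
        if labels not in supports2 or labels not in supports3:
            return False
        for smap, rset in zip(rescue_maps, rescue_leafsets):
            reduced = frozenset(labels & rset)
            if len(reduced) < 2:
                return False
            s = smap.get(reduced)
            if s is None or s < rescue_cutoff:
                return False
        return True

    calls: list[SubfamilyCall] = []
    used_names: set[str] = set()

    def _name_for(refs_inside: list[str]) -> str:
        base = None
        for ref in reference_labels:  # best-known reference order wins
            if ref in refs_inside:
                base = (names or {}).get(ref, ref)
                break
        base = base or "subfamily"
        name, k = base, 1
        while name in used_names:
            k += 1
            name = f"{base}.{k}"
        used_names.add(name)
        return name

    all_leaves = leafsets[0]

    def _descend(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if child.is_leaf():
                continue
            labels = frozenset(lf.taxon.label for lf in child.leaf_iter())
            if labels & outgroup:
                _descend(child)
                continue
            if all_leaves - labels <= outgroup:
                # this clade's subtending edge is the rooting edge itself (its
                # complement is the outgroup): it is the trivial "all
                # synthetases" group, not a subfamily — look inside instead
                _descend(child)
                continue
            refs_inside = [r for r in reference_labels if r in labels]
            s1 = getattr(child, "support", None)
            if refs_inside and _meets_full(labels, s1):
                calls.append(
                    SubfamilyCall(
                        name=_name_for(refs_inside),
                        member_labels=labels,
                        supports=[s1, supports2[labels], supports3[labels]],
                        reference_members=refs_inside,
                    )
                )
                continue  # maximality: do not descend a promoted clade
            if refs_inside and _meets_rescue(labels):
                calls.append(
                    SubfamilyCall(
                        name=_name_for(refs_inside),
                        member_labels=labels,
                        supports=[
                            s1 if s1 is not None else 0.0,
                            supports2.get(labels) or 0.0,
                            supports3.get(labels) or 0.0,
                        ],
                        reference_members=refs_inside,
                        rescued=True,
                    )
                )
                continue
            _descend(child)

    _descend(trees[0].seed_node)

    placed = set().union(*(c.member_labels for c in calls)) if calls else set()
    unplaced = sorted(leafsets[0] - placed - outgroup)
    # disjointness is guaranteed by construction; assert the invariant anyway
    assert sum(len(c.member_labels) for c in calls) == len(placed)
    return calls, unplaced


def parse_domain_label(label: str) -> tuple[str, int]:
    """Split an A-domain leaf label ``<protein>|m<k>`` into its parts."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"not an A-domain label: {label!r}")
    return m.group("protein"), int(m.group("module"))


def assign_genes(
    subfamily_calls: list[SubfamilyCall],
    unplaced_labels=(),
    known_proteins=None,
) -> list[GeneAssignment]:
    """Gene -> subfamily by majority vote over its A-domain leaves.

    Ties take the subfamily of the N-terminal-most A domain and flag the gene
    recombinant; genes whose domains are all unplaced go to ``Other``.
    Unplaced labels that are not A-domain labels at all (e.g. stray non-NRPS
    leaves) are ignored.
    """
    modules: dict[str, dict[int, str]] = {}

    def _add(label: str, subfam: str) -> None:
        protein, module = parse_domain_label(label)
        if known_proteins is not None and protein not in known_proteins:
            raise ValueError(f"label {label!r} parses to unknown protein {protein!r}")
        modules.setdefault(protein, {})[module] = subfam

    for call in subfamily_calls:
        for label in call.member_labels:
            _add(label, call.name)
    for label in unplaced_labels:
        if _LABEL_RE.match(label):
            _add(label, "Other")

    out: list[GeneAssignment] = []
    for gene in sorted(modules):
        mods = modules[gene]
        placed = {k: v for k, v in mods.items() if v != "Other"}
        if not placed:
            out.append(GeneAssignment(gene, "Other", modules=mods))
            continue
        tally: dict[str, int] = {}
        for sf in placed.values():
            tally[sf] = tally.get(sf, 0) + 1
        best = max(tally.values())
        winners = sorted(sf for sf, n in tally.items() if n == best)
        recombinant = len(set(placed.values())) > 1
        if len(winners) == 1:
            subfam = winners[0]
        else:
            subfam = placed[min(placed)]  # N-terminal-most module wins
        out.append(GeneAssignment(gene, subfam, recombinant=recombinant, modules=mods))
    return out
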