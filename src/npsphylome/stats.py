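"""Species x subfamily count matrices and taxon-overrepresentation tests.

A subfamily is tested for overrepresentation in a taxonomic group with
Fisher's exact test on the 2x2 table (genes in subfamily and group, genes in
subfamily outside the group, other genes in the group, other genes outside).
The default alternative is one-sided "greater" (overrepresentation); no
multiple-testing correction is applied by default, with Benjamini-Hochberg
available across the full subfamily x group scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .io_formats import CountMatrix
from .subfamilies import GeneAssignment

__all__ = [
    "ContingencyTable",
    "build_count_matrix",
    "fisher_overrepresentation",
    "fisher_scan",
]


@dataclass
class ContingencyTable:
    """2x2 cells: a = in subfamily & in group, b = in subfamily & not group,
    c = not subfamily & in group, d = not subfamily & not group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_count_matrix(
    gene_assignments: list[GeneAssignment],
    species_of: dict[str, str],
    group_of: dict[str, str],
    subfamilies: list[str] | None = None,
) -> CountMatrix:
    """Tally assigned genes per species per subfamily.

    Every species in ``group_of`` appears (zero rows for species with no
    genes); a gene whose species is missing from ``group_of`` is an error.
    """
    species = sorted(group_of)
    if subfamilies is None:
        subfamilies = sorted({a.subfamily for a in gene_assignments})
    counts = pd.DataFrame(0, index=pd.Index(species, name="species"), columns=subfamilies)
    for a in gene_assignments:
        sp = species_of.get(a.gene)
        if sp is None:
            raise ValueError(f"gene {a.gene!r} has no species")
        if sp not in group_of:
            raise ValueError(f"species {sp!r} missing from the taxonomic-group map")
        if a.subfamily not in counts.columns:
            counts[a.subfamily] = 0
        counts.loc[sp, a.subfamily] += 1
    return CountMatrix(counts=counts, group_of=dict(group_of))


def contingency_table(cm: CountMatrix, group: str, subfamily: str) -> ContingencyTable:
    if subfamily not in cm.subfamilies:
        raise ValueError(f"unknown subfamily {subfamily!r}")
    groups = set(cm.group_of.values())
    if group not in groups:
        raise ValueError(f"unknown taxonomic group {group!r}")
    in_group = [sp for sp in cm.species if cm.group_of[sp] == group]
    out_group = [sp for sp in cm.species if cm.group_of[sp] != group]
    col = cm.counts[subfamily]
    rest = cm.counts.drop(columns=[subfamily]).sum(axis=1)
    return ContingencyTable(
        a=int(col.loc[in_group].sum()),
        b=int(col.loc[out_group].sum()),
        c=int(rest.loc[in_group].sum()),
        d=int(rest.loc[out_group].sum()),
    )


def _odds_ratio(t: ContingencyTable) -> float:
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:  # Haldane-Anscombe continuity correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_overrepresentation(
    cm: CountMatrix,
    group: str,
    subfamily: str,
    sided: str = "greater",
    groups: list[str] | None = None,
) -> tuple[float, float, ContingencyTable]:
    """Fisher's exact test of subfamily x group association.

    ``groups`` restricts the comparison universe (e.g. Euascomycota vs
    Basidiomycota only); the default universe is every species in the matrix.
    Returns (odds_ratio, p_value, table).  An empty margin yields p = 1.0
    with a warning rather than an error.
    """
    if groups is not None:
        keep = [sp for sp in cm.species if cm.group_of[sp] in groups]
        cm = CountMatrix(
            counts=cm.counts.loc[keep],
            group_of={sp: cm.group_of[sp] for sp in keep},
        )
    table = contingency_table(cm, group, subfamily)
    if table.a + table.b == 0 or table.a + table.c == 0:
        warnings.warn(
            f"empty margin for subfamily {subfamily!r} x group {group!r}; p = 1.0",
            stacklevel=2,
        )
        return _odds_ratio(table), 1.0, table
    alternative = {"greater": "greater", "two-sided": "two-sided", "less": "less"}[sided]
    _, p = sps.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative=alternative)
    return _odds_ratio(table), float(p), table


def fisher_scan(
    cm: CountMatrix,
    sided: str = "greater",
    groups: list[str] | None = None,
    bh_correct: bool = False,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Every subfamily x group test as one tidy frame."""
    rows = []
    universe = sorted(set(cm.group_of.values()) if groups is None else groups)
    for subfamily in cm.subfamilies:
        for group in universe:
            orx, p, t = fisher_overrepresentation(cm, group, subfamily, sided, groups)
            rows.append(
                dict(group=group, subfamily=subfamily, a=t.a, b=t.b, c=t.c, d=t.d,
                     odds_ratio=orx, p_value=p)
            )
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        p = df["p_value"].to_numpy()
        m = len(p)
        idx = p.argsort()
        adj = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = idx[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < significance
    else:
        df["significant"] = df["p_value"] < significance
    return df
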