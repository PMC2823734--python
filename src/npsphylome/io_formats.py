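"""Readers and writers for the formats every pipeline stage touches.

FASTA protein files, newick trees with integer bootstrap supports on internal
edges, and TSV species x subfamily gene-count tables.  A packaged count-table
fixture (the published census of NRPS genes per subfamily across fungal
taxonomic groups) ships with the module and is loaded with :func:`load_table1`.

Conventions
-----------
* Gap characters ``.`` and ``-`` are both accepted on input and normalized to
  ``-`` (alignment-database exports vary in their gap character).
* Numeric internal-node labels in newick are interpreted as clade supports and
  stored on ``node.support``; leaf labels are never reinterpreted.
* Unrooted trees are represented with a trifurcating root node; rooting is an
  explicit later operation (:func:`npsphylome.phylogeny.root_with_outgroup`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Alignment",
    "CountMatrix",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "read_count_table",
    "write_count_table",
    "load_table1",
]

_GAP_CHARS = {"-", "."}
_FOOTNOTE_RE = re.compile(r"^(\d+)\^.*\^$")


@dataclass
class SequenceRecord:
    """A protein (or aligned domain block) with a unique id."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id must be non-empty and whitespace-free: {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Ordered equal-length :class:`SequenceRecord` rows; gaps are ``-``."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if records:
            ncol = len(records[0].residues)
            for rec in records:
                if len(rec.residues) != ncol:
                    raise ValueError(
                        f"alignment rows differ in length: {rec.id} has "
                        f"{len(rec.residues)} columns, expected {ncol}"
                    )
        self.records = records

    @property
    def column_count(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, j: int) -> str:
        return "".join(rec.residues[j] for rec in self.records)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Raises on duplicate ids; an empty file yields an empty list with a warning.
    Wrapped and unwrapped sequence lines parse identically (Biopython parser).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, normalizing ``.`` gaps to ``-``."""
    records = read_fasta(path)
    normalized = [
        SequenceRecord(r.id, r.residues.replace(".", "-"), r.description) for r in records
    ]
    return Alignment(normalized)


def write_alignment(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    write_fasta(alignment.records, path, width=width)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _check_balanced(text: str) -> None:
    depth = 0
    prev = ""
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at character offset {offset}")
            if prev == ",":
                raise ValueError(f"dangling comma before ')' at character offset {offset}")
        if not ch.isspace():
            prev = ch
    if depth != 0:
        raise ValueError(f"unbalanced '(' in newick text (final depth {depth})")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse newick text (or a file containing it) into a dendropy tree.

    Numeric internal-node labels are interpreted as bootstrap supports and
    stored as ``node.support`` (float); leaf labels are left untouched.
    """
    if isinstance(source, Path) or (isinstance(source, str) and ";" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    _check_balanced(text)
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for node in tree.preorder_node_iter():
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree, emitting supports as internal-node labels."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        support = getattr(node, "support", None)
        if support is not None:
            node.label = ("%g" % support)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return text + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Species x subfamily integer gene counts with a taxonomic-group map."""

    counts: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate species labels in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate subfamily labels in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in count matrix")
        if self.group_of:
            missing = [sp for sp in self.counts.index if sp not in self.group_of]
            if missing:
                raise ValueError(f"species missing taxonomic group: {missing}")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subfamilies(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def group_species(self, group: str) -> list[str]:
        return [sp for sp in self.species if self.group_of.get(sp) == group]


def _parse_count_cell(value, species: str, column: str) -> int:
    text = str(value).strip()
    m = _FOOTNOTE_RE.match(text)
    if m:
        text = m.group(1)
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"non-integer count {value!r} at species {species!r}, subfamily {column!r}"
        ) from None


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a TSV count table: first column species, optional ``group`` column.

    Footnote markers such as ``2^c^`` are stripped; the integer prefix is the
    count.  An empty body yields a CountMatrix with zero species.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and len(df.columns) == 0:
        return CountMatrix(pd.DataFrame())
    species_col = df.columns[0]
    group_col = next((c for c in df.columns if c.lower() == "group"), None)
    group_of: dict[str, str] = {}
    if group_col is not None:
        for sp, grp in zip(df[species_col], df[group_col]):
            if pd.isna(grp) or str(grp).strip() == "":
                raise ValueError(f"missing taxonomic group for species {sp!r}")
            group_of[str(sp)] = str(grp).strip()
    subfam_cols = [c for c in df.columns if c not in (species_col, group_col)]
    data = {}
    for col in subfam_cols:
        data[col] = [
            _parse_count_cell(v, sp, col) for sp, v in zip(df[species_col], df[col])
        ]
    counts = pd.DataFrame(data, index=pd.Index(df[species_col].astype(str), name="species"))
    return CountMatrix(counts=counts, group_of=group_of)


def write_count_table(cm: CountMatrix, path: str | Path, header_comment: str | None = None) -> None:
    df = cm.counts.copy()
    if cm.group_of:
        df.insert(0, "group", [cm.group_of[sp] for sp in df.index])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="species")


def load_table1() -> CountMatrix:
    """The packaged gene-count census (one row per species, one column per
    subfamily, plus a residual ``Other`` column stored verbatim)."""
    with resources.as_file(
        resources.files("npsphylome.data").joinpath("table1_counts.tsv")
    ) as p:
        return read_count_table(p)
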