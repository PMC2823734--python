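"""A-domain extraction and alignment-column masking.

Phylogenies are built from individual adenylation (A) domains rather than
whole proteins, so multimodular synthetases contribute one leaf per module.
Columns dominated by gaps are removed before distance estimation; the removal
rule is strictly-greater-than the threshold (a column with exactly 30% gaps
survives a 0.30 mask).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .io_formats import Alignment, SequenceRecord, read_alignment, write_fasta
from .profiles import Architecture

__all__ = [
    "MaskResult",
    "extract_a_domains",
    "mask_columns",
    "stack_alignment",
    "align_with_mafft",
]


@dataclass
class MaskResult:
    masked: Alignment
    kept_columns: list[int]
    threshold: float


def extract_a_domains(
    proteins: list[SequenceRecord],
    architectures: dict[str, Architecture],
    include_degenerate: bool = False,
    min_length: int = 150,
    pad_to_profile: bool = False,
) -> list[SequenceRecord]:
    """One record per A domain, id ``<protein>|m<k>`` with k the 1-based
    module index (A and dA both advance the module counter).

    Degenerate A domains are excluded unless ``include_degenerate``; domains
    shorter than ``min_length`` residues are dropped as partial/unalignable.
    With ``pad_to_profile`` each record is gap-padded onto the profile
    coordinate system (possible when hits carry profile coordinates and the
    domains contain no insertions relative to the profile), which yields an
    alignment directly without an external aligner.
    """
    by_id = {p.id: p for p in proteins}
    out: list[SequenceRecord] = []
    for pid in sorted(architectures):
        arch = architectures[pid]
        if pid not in by_id:
            raise ValueError(f"architecture references missing protein {pid!r}")
        protein = by_id[pid]
        module = 0
        for hit in arch.hits:
            if hit.domain_type != "A":
                continue
            module += 1
            if hit.degenerate and not include_degenerate:
                continue
            if hit.end - hit.start < min_length:
                continue
            residues = protein.residues[hit.start:hit.end]
            if pad_to_profile:
                if hit.profile_start < 0 or hit.profile_len <= 0:
                    raise ValueError(
                        f"hit on {pid} lacks profile coordinates; cannot pad"
                    )
                if hit.profile_end - hit.profile_start != len(residues):
                    raise ValueError(
                        f"hit on {pid} contains indels; align externally instead"
                    )
                residues = (
                    "-" * hit.profile_start
                    + residues
                    + "-" * (hit.profile_len - hit.profile_end)
                )
            out.append(SequenceRecord(id=f"{pid}|m{module}", residues=residues))
    return out


def mask_columns(alignment: Alignment, max_gap_fraction: float) -> MaskResult:
    """Remove columns whose gap fraction strictly exceeds the threshold."""
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    if not (0 < max_gap_fraction <= 1):
        raise ValueError("max_gap_fraction must lie in (0, 1]")
    nrow = len(alignment)
    kept: list[int] = []
    for j in range(alignment.column_count):
        gaps = sum(1 for ch in alignment.column(j) if ch == "-")
        if gaps / nrow <= max_gap_fraction:
            kept.append(j)
    if not kept:
        raise ValueError("empty masked alignment")
    masked = Alignment(
        [
            SequenceRecord(rec.id, "".join(rec.residues[j] for j in kept), rec.description)
            for rec in alignment
        ]
    )
    return MaskResult(masked=masked, kept_columns=kept, threshold=max_gap_fraction)


def stack_alignment(records: list[SequenceRecord]) -> Alignment:
    """Treat equal-length ungapped records as already aligned (the common case
    for domains excised against the same profile); raises on ragged input."""
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"records have unequal lengths {sorted(lengths)}; run an aligner first"
        )
    return Alignment(records)


def align_with_mafft(records: list[SequenceRecord], binary: str = "mafft") -> Alignment:
    """Optional external-aligner adapter (used only when an aligner is on
    PATH; all tests and the demo pipeline use generator-emitted or stacked
    alignments)."""
    if shutil.which(binary) is None:
        raise RuntimeError(f"external aligner {binary!r} not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fasta"
        write_fasta(records, inp)
        result = subprocess.run(
            [binary, "--auto", "--quiet", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = Path(td) / "out.fasta"
        out.write_text(result.stdout)
        return read_alignment(out)
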