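"""Position-specific domain profiles, local scanning, and architecture calls.

A :class:`ProfileModel` is a calibrated position-specific scoring model built
from a seed alignment: per-position log-odds over the 20 residues (bits),
affine gap penalties, and a Gumbel null fitted to the local-alignment scores
of shuffled length-matched random sequences.  :func:`scan_protein` finds the
optimal and sub-optimal non-overlapping local alignments (Smith-Waterman
against the position-specific scores) and converts scores to e-values via the
Gumbel tail scaled by search space.  Hits scoring below a fraction of the
profile's trusted self-score are flagged *degenerate* — the hallmark of the
dA domains seen in some fungal synthetases.

:func:`call_architecture` merges hits from several profiles into one modular
architecture string (e.g. ``A-T-C-dA-T-C``), and :func:`screen_candidates`
applies the phylogenetic screening rule: queries are accepted when they fall
inside a well-supported clade containing the known reference synthetases and
excluding the adenylating-enzyme outgroups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy import stats as sps

from .io_formats import Alignment, SequenceRecord
from .residues import AA_INDEX, AMINO, N_AA

__all__ = [
    "ProfileModel",
    "DomainHit",
    "Architecture",
    "build_profile",
    "scan_protein",
    "call_architecture",
    "screen_candidates",
    "read_hmmer2_profile",
    "DOMAIN_TYPE_ORDER",
]

DOMAIN_TYPE_ORDER = {"A": 0, "T": 1, "C": 2, "R": 3}
BACKGROUND = 0.05  # uniform residue background


@dataclass
class ProfileModel:
    """Per-position log-odds profile with a fitted Gumbel null."""

    domain_type: str
    match_scores: np.ndarray  # (length, 20) bits
    gap_open: float = 10.0
    gap_extend: float = 1.0
    calibration: tuple[float, float] | None = None  # Gumbel (mu, scale)
    calib_len: int = 0
    self_score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != N_AA:
            raise ValueError("match_scores must be (length, 20)")
        if self.length < 1:
            raise ValueError("profile must have at least one position")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValueError("calibration scale must be > 0")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO[i] for i in np.argmax(self.match_scores, axis=1))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domain_type": self.domain_type,
            "name": self.name,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "calibration": self.calibration,
            "calib_len": self.calib_len,
            "self_score": self.self_score,
            "alphabet": AMINO,
            "match_scores": [[round(float(v), 4) for v in row] for row in self.match_scores],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            domain_type=payload["domain_type"],
            match_scores=np.asarray(payload["match_scores"], dtype=float),
            gap_open=payload["gap_open"],
            gap_extend=payload["gap_extend"],
            calibration=tuple(payload["calibration"]) if payload["calibration"] else None,
            calib_len=payload["calib_len"],
            self_score=payload["self_score"],
            name=payload.get("name", ""),
        )


@dataclass
class DomainHit:
    protein_id: str
    domain_type: str
    start: int  # 0-based half-open, residue coordinates
    end: int
    bit_score: float
    e_value: float
    degenerate: bool = False
    profile_name: str = ""
    profile_start: int = -1  # matched profile positions (for padding domains
    profile_end: int = -1    # back onto the profile coordinate system)
    profile_len: int = 0

    def length(self) -> int:
        return self.end - self.start


@dataclass
class Architecture:
    protein_id: str
    hits: list[DomainHit] = field(default_factory=list)

    @property
    def architecture_string(self) -> str:
        labels = []
        for h in self.hits:
            if h.domain_type == "A" and h.degenerate:
                labels.append("dA")
            else:
                labels.append(h.domain_type)
        return "-".join(labels)

    @property
    def module_count(self) -> int:
        return sum(1 for h in self.hits if h.domain_type == "A")


def _encode(residues: str) -> np.ndarray:
    return np.asarray([AA_INDEX.get(ch, -1) for ch in residues], dtype=np.int64)


# ---------------------------------------------------------------------------
# Profile construction and calibration
# ---------------------------------------------------------------------------

def build_profile(
    seed_alignment: Alignment,
    domain_type: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    max_gap_fraction: float = 0.5,
    calibrate_n: int = 200,
    seed: int = 0,
    name: str = "",
) -> ProfileModel:
    """Build a calibrated profile from a seed alignment.

    Columns with more than ``max_gap_fraction`` gaps are dropped from the
    match states.  Match scores are log2((count + 1) / (n + 20) / 0.05)
    (pseudocount 1 per residue, uniform background).  The Gumbel null is
    fitted to the local-alignment scores of ``calibrate_n`` random sequences
    of the profile's own length.
    """
    if len(seed_alignment) == 0:
        raise ValueError("empty seed alignment")
    nrow = len(seed_alignment)
    keep_cols = []
    for j in range(seed_alignment.column_count):
        col = seed_alignment.column(j)
        gaps = sum(1 for ch in col if ch == "-")
        if gaps / nrow <= max_gap_fraction:
            keep_cols.append(j)
    if not keep_cols:
        raise ValueError("all columns are gap-dominated; no match states")
    scores = np.empty((len(keep_cols), N_AA), dtype=float)
    for out_i, j in enumerate(keep_cols):
        counts = np.zeros(N_AA)
        n_res = 0
        for rec in seed_alignment:
            idx = AA_INDEX.get(rec.residues[j])
            if idx is not None:
                counts[idx] += 1
                n_res += 1
        freqs = (counts + 1.0) / (n_res + N_AA)
        scores[out_i] = np.log2(freqs / BACKGROUND)
    profile = ProfileModel(
        domain_type=domain_type,
        match_scores=scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        name=name or domain_type,
    )
    cons_idx = np.argmax(scores, axis=1)
    profile.self_score = float(scores[np.arange(len(cons_idx)), cons_idx].sum())
    calibrate_profile(profile, n=calibrate_n, seed=seed)
    return profile


def calibrate_profile(profile: ProfileModel, n: int = 200, seed: int = 0) -> None:
    """Fit the Gumbel null from local-alignment scores of ``n`` shuffled
    (i.e. i.i.d. uniform-background) sequences length-matched to the profile."""
    if n < 200:
        raise ValueError("calibration needs at least 200 null scores")
    rng = np.random.default_rng(seed)
    L = profile.length
    null_scores = np.empty(n)
    for i in range(n):
        seq = rng.integers(0, N_AA, size=L)
        null_scores[i] = _best_local_hit(profile, seq)[0]
    mu, scale = sps.gumbel_r.fit(null_scores)
    profile.calibration = (float(mu), float(scale))
    profile.calib_len = L


# ---------------------------------------------------------------------------
# Smith-Waterman against the position-specific scores
# ---------------------------------------------------------------------------

def _sw_matrices(profile: ProfileModel, seq_idx: np.ndarray):
    """Fill the three affine-gap DP matrices (match, gap-in-sequence,
    gap-in-profile).  Row recurrences are vectorized along the sequence."""
    L, n = profile.length, len(seq_idx)
    go, ge = profile.gap_open, profile.gap_extend
    NEG = -1e30
    M = np.full((L + 1, n + 1), 0.0)
    Ix = np.full((L + 1, n + 1), NEG)  # gap consumes sequence residues
    Iy = np.full((L + 1, n + 1), NEG)  # gap consumes profile positions
    valid = seq_idx >= 0
    for i in range(1, L + 1):
        sc = np.where(valid, profile.match_scores[i - 1, np.clip(seq_idx, 0, N_AA - 1)], NEG)
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = np.maximum(0.0, best_prev[:-1] + sc)
        Iy[i, 1:] = np.maximum(M[i - 1, 1:] - go, Iy[i - 1, 1:] - ge)
        # Ix along the row via prefix running max: Ix[i,j] =
        # max_{j0<j} M[i,j0] - go - (j-j0-1)*ge
        a = M[i, :-1] + ge * np.arange(n)
        run = np.maximum.accumulate(a)
        Ix[i, 1:] = run - go - ge * (np.arange(1, n + 1) - 1)
    return M, Ix, Iy


def _best_local_hit(profile: ProfileModel, seq_idx: np.ndarray):
    """Optimal local alignment: (score, seq_start, seq_end, prof_start,
    prof_end) with half-open intervals on both axes."""
    if len(seq_idx) == 0:
        return 0.0, 0, 0, 0, 0
    M, Ix, Iy = _sw_matrices(profile, seq_idx)
    flat = int(np.argmax(M))
    i, j = divmod(flat, M.shape[1])
    score = float(M[i, j])
    if score <= 0:
        return 0.0, 0, 0, 0, 0
    end_j = j
    end_i = i
    go, ge = profile.gap_open, profile.gap_extend
    eps = 1e-6
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            val = M[i, j]
            idx = seq_idx[j - 1]
            sc = profile.match_scores[i - 1, idx] if idx >= 0 else -1e30
            if abs(val - sc) < eps:  # alignment starts here
                i -= 1
                j -= 1
                break
            prev = val - sc
            if abs(M[i - 1, j - 1] - prev) < eps:
                state = "M"
            elif abs(Ix[i - 1, j - 1] - prev) < eps:
                state = "Ix"
            else:
                state = "Iy"
            i -= 1
            j -= 1
        elif state == "Ix":
            val = Ix[i, j]
            if abs(M[i, j - 1] - go - val) < eps:
                state = "M"
            j -= 1
        else:  # Iy
            val = Iy[i, j]
            if abs(M[i - 1, j] - go - val) < eps:
                state = "M"
            i -= 1
    return score, j, end_j, i, end_i


def _hit_evalue(profile: ProfileModel, score: float, seq_len: int, search_space: float) -> float:
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    mu, scale = profile.calibration
    p = float(sps.gumbel_r.sf(score, loc=mu, scale=scale))
    length_factor = max(seq_len, 1) / max(profile.calib_len, 1)
    return p * length_factor * search_space


def scan_protein(
    profile: ProfileModel,
    protein: SequenceRecord,
    e_value_max: float = 1.0,
    search_space: float = 1000.0,
    degeneracy_fraction: float = 0.6,
    max_hits: int = 50,
) -> list[DomainHit]:
    """All non-overlapping local hits with e-value below ``e_value_max``.

    ``search_space`` is the effective number of sequences searched (an
    e-value of 1 then means one random hit this good is expected per scan of
    that many proteins).  Hits scoring below ``degeneracy_fraction`` of the
    profile's trusted self-score are flagged degenerate.
    """
    seq_idx = _encode(protein.residues)
    n = len(seq_idx)
    hits: list[DomainHit] = []

    def _scan_segment(lo: int, hi: int) -> None:
        if hi - lo < 3 or len(hits) >= max_hits:
            return
        score, s, e, ps, pe = _best_local_hit(profile, seq_idx[lo:hi])
        if score <= 0 or e <= s:
            return
        e_val = _hit_evalue(profile, score, n, search_space)
        if e_val >= e_value_max:
            return
        hits.append(
            DomainHit(
                protein_id=protein.id,
                domain_type=profile.domain_type,
                start=lo + s,
                end=lo + e,
                bit_score=score,
                e_value=e_val,
                degenerate=score < degeneracy_fraction * profile.self_score,
                profile_name=profile.name,
                profile_start=ps,
                profile_end=pe,
                profile_len=profile.length,
            )
        )
        _scan_segment(lo, lo + s)
        _scan_segment(lo + e, hi)

    _scan_segment(0, n)
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Architecture calling
# ---------------------------------------------------------------------------

def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def call_architecture(
    hits_all_profiles: list[DomainHit],
    protein: SequenceRecord,
    overlap_fraction: float = 0.30,
) -> Architecture:
    """Resolve overlapping hits greedily by bit score and emit the modular
    architecture.  An overlap counts when it exceeds ``overlap_fraction`` of
    the shorter hit; score ties break by earlier start, then by the canonical
    domain-type order A < T < C < R."""
    order = sorted(
        hits_all_profiles,
        key=lambda h: (-h.bit_score, h.start, DOMAIN_TYPE_ORDER.get(h.domain_type, 99)),
    )
    kept: list[DomainHit] = []
    for h in order:
        clash = any(
            _overlap(h, k) > overlap_fraction * min(h.length(), k.length()) for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return Architecture(protein_id=protein.id, hits=kept)


# ---------------------------------------------------------------------------
# Phylogenetic candidate screening
# ---------------------------------------------------------------------------

def screen_candidates(
    a_domain_tree: dendropy.Tree,
    reference_labels: set[str],
    outgroup_labels: set[str],
    support_cutoff: float = 90.0,
) -> set[str]:
    """Labels accepted as candidate synthetases.

    After rooting on the outgroup, the smallest clade containing every
    reference label, excluding all outgroup labels, and carrying support at or
    above the cutoff is located; every other leaf inside it is accepted.
    Returns an empty set when no clade on the reference-to-root path reaches
    the cutoff; raises when the references cannot be separated from the
    outgroup at all.
    """
    from .phylogeny import root_with_outgroup  # local import, avoids cycle

    reference_labels = set(reference_labels)
    outgroup_labels = set(outgroup_labels)
    tree = root_with_outgroup(a_domain_tree, outgroup_labels)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = reference_labels - leaf_labels
    if missing:
        raise ValueError(f"reference labels absent from tree: {sorted(missing)}")

    taxa = [tree.taxon_namespace.get_taxon(lbl) for lbl in sorted(reference_labels)]
    node = tree.mrca(taxa=taxa)
    while node is not None:
        labels = {lf.taxon.label for lf in node.leaf_iter()}
        if labels & outgroup_labels:
            raise ValueError("no qualifying clade: references not separable from outgroup")
        support = getattr(node, "support", None)
        if support is not None and support >= support_cutoff:
            return labels - reference_labels - outgroup_labels
        parent = node.parent_node
        if parent is None or parent.parent_node is None:
            # next step up is the root: the clade would absorb the outgroup
            return set()
        node = parent
    return set()


# ---------------------------------------------------------------------------
# HMMER2 import adapter
# ---------------------------------------------------------------------------

def read_hmmer2_profile(
    path: str | Path,
    domain_type: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    calibrate_n: int = 200,
    seed: int = 0,
) -> ProfileModel:
    """Map a HMMER2 ASCII profile onto the native ProfileModel.

    Only the match-emission scores are used (HMMER2 stores them as
    1000 x log2(p/null); ``*`` means minus infinity).  The imported profile is
    recalibrated natively so e-values are comparable with built profiles.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("HMMER2"):
        raise ValueError(f"{path}: not a HMMER2 ASCII profile")
    hmm_at = next((i for i, l in enumerate(lines) if l.startswith("HMM ")), None)
    if hmm_at is None:
        raise ValueError(f"{path}: missing HMM symbol header")
    symbols = lines[hmm_at].split()[1:]
    if len(symbols) != N_AA:
        raise ValueError(f"{path}: expected 20 residue symbols, got {len(symbols)}")
    col_map = [AA_INDEX[s] for s in symbols]

    def _score(tok: str) -> float:
        return -1e4 if tok == "*" else int(tok) / 1000.0

    rows = []
    i = hmm_at + 2  # skip the transition-name line
    # optional B-state insert/transition prelude: node lines start with an int
    while i < len(lines) and not lines[i].strip().startswith("//"):
        parts = lines[i].split()
        if parts and parts[0].isdigit():
            vals = parts[1:1 + N_AA]
            if len(vals) == N_AA:
                row = np.empty(N_AA)
                for k, tok in enumerate(vals):
                    row[col_map[k]] = _score(tok)
                rows.append(row)
            i += 3  # match line + insert line + transition line
        else:
            i += 1
    if not rows:
        raise ValueError(f"{path}: no match states parsed")
    profile = ProfileModel(
        domain_type=domain_type,
        match_scores=np.vstack(rows),
        gap_open=gap_open,
        gap_extend=gap_extend,
        name=Path(path).stem,
    )
    cons = np.argmax(profile.match_scores, axis=1)
    profile.self_score = float(profile.match_scores[np.arange(len(cons)), cons].sum())
    calibrate_profile(profile, n=calibrate_n, seed=seed)
    return profile
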