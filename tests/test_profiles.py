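"""Profile building, calibrated local scanning, architecture calls,
phylogenetic candidate screening, HMMER2 import."""

import numpy as np
import pytest

from npsphylome import profiles as pr
from npsphylome.io_formats import Alignment, SequenceRecord, read_newick
from npsphylome.residues import AMINO


def test_single_sequence_profile_scores_consensus_positive():
    prof = pr.build_profile(Alignment([SequenceRecord("s", "ACD")]), "A", seed=1)
    for pos, aa in enumerate("ACD"):
        assert prof.match_scores[pos, AMINO.index(aa)] > 0
        # every other residue scores negative under pseudocount smoothing
        for other in AMINO:
            if other != aa:
                assert prof.match_scores[pos, AMINO.index(other)] < 0


def test_gap_dominated_columns_dropped():
    aln = Alignment([
        SequenceRecord("a", "AC-E"),
        SequenceRecord("b", "AC-E"),
        SequenceRecord("c", "A--E"),
    ])
    prof = pr.build_profile(aln, "A", seed=1)
    assert prof.length == 3  # the all/mostly-gap column is not a match state
    with pytest.raises(ValueError):
        pr.build_profile(Alignment([]), "A")


def test_self_hit_far_above_null(built_profiles):
    for prof in built_profiles:
        mu, scale = prof.calibration
        assert prof.self_score > mu + 5 * scale


def test_scan_finds_planted_domains(planted_proteome, built_profiles):
    """Each planted non-degenerate A domain is recovered with >=90% overlap."""
    records, truth, _ = planted_proteome
    a_profiles = [p for p in built_profiles if p.domain_type == "A"]
    found = total = 0
    for rec in records:
        hits = []
        for prof in a_profiles:
            hits.extend(pr.scan_protein(prof, rec))
        arch = pr.call_architecture(hits, rec)
        for dtype, s, e, _sf in truth.proteins[rec.id]:
            if dtype != "A":
                continue
            total += 1
            for h in arch.hits:
                overlap = max(0, min(h.end, e) - max(h.start, s))
                if overlap >= 0.9 * (e - s) and not h.degenerate:
                    found += 1
                    break
    assert found / total >= 0.95


def test_scan_contracts(planted_proteome, built_profiles):
    records, _, _ = planted_proteome
    prof = built_profiles[0]
    assert pr.scan_protein(prof, SequenceRecord("tiny", "ACDE")) == []
    for rec in records[:5]:
        hits = pr.scan_protein(prof, rec)
        assert hits == sorted(hits, key=lambda h: h.start)
        for h in hits:
            assert 0 <= h.start < h.end <= len(rec.residues)
            assert h.e_value >= 0


def test_evalue_monotone_in_score(built_profiles):
    prof = built_profiles[0]
    scores = np.linspace(10, prof.self_score, 25)
    evals = [pr._hit_evalue(prof, s, 1000, 1000.0) for s in scores]
    assert all(a >= b for a, b in zip(evals, evals[1:]))


def test_architecture_simple_merge():
    hits = [
        pr.DomainHit("p", "A", 0, 480, 900.0, 1e-40),
        pr.DomainHit("p", "T", 500, 580, 150.0, 1e-10),
        pr.DomainHit("p", "C", 600, 1030, 800.0, 1e-38),
    ]
    arch = pr.call_architecture(hits, SequenceRecord("p", "A" * 1100))
    assert arch.architecture_string == "A-T-C"
    assert arch.module_count == 1


def test_architecture_overlap_resolution_prefers_score():
    hits = [
        pr.DomainHit("p", "A", 0, 480, 900.0, 1e-40),
        pr.DomainHit("p", "C", 100, 500, 300.0, 1e-12),  # >30% overlap, weaker
        pr.DomainHit("p", "T", 460, 540, 150.0, 1e-10),  # <30% of its length
    ]
    arch = pr.call_architecture(hits, SequenceRecord("p", "A" * 600))
    assert arch.architecture_string == "A-T"


def test_architecture_planted_strings(planted_proteome, scanned_architectures):
    records, truth, _ = planted_proteome
    archs, _ = scanned_architectures
    nps6 = [r.id for r in records if truth.subfamily_of[r.id] == "SID"][0]
    assert archs[nps6].architecture_string == "A-T-C-dA-T-C"
    assert archs[nps6].module_count == 2
    mono = [r.id for r in records if truth.subfamily_of[r.id] == "NPS12"][0]
    assert archs[mono].architecture_string == "A"
    assert archs[mono].module_count == 1
    empty = pr.call_architecture([], SequenceRecord("none", "ACDEF"))
    assert empty.architecture_string == "" and empty.module_count == 0


def test_shuffled_sequences_rarely_hit(built_profiles):
    """Calibration property: e-value < 1 hits on random sequences in <=10%
    of 100 trials."""
    prof = [p for p in built_profiles if p.domain_type == "A"][0]
    rng = np.random.default_rng(42)
    false_hits = 0
    for i in range(100):
        seq = "".join(rng.choice(list(AMINO), size=600))
        if pr.scan_protein(prof, SequenceRecord(f"sh{i}", seq)):
            false_hits += 1
    assert false_hits <= 10


def test_screen_candidates_rules():
    t = read_newick("((OG1:1,OG2:1)99:1,((REF1:1,Q1:1)95:1,(Q2:1,OG3:1)80:1)60:1);")
    assert pr.screen_candidates(t, {"REF1"}, {"OG1", "OG2", "OG3"}, 90) == {"Q1"}
    t2 = read_newick("((OG1:1,OG2:1)99:1,((REF1:1,Q1:1)85:1,Q2:1)60:1);")
    assert pr.screen_candidates(t2, {"REF1"}, {"OG1", "OG2"}, 90) == set()
    t3 = read_newick("(((OG1:1,Q9:1)99:1,OG2:1)90:1,(REF1:1,Q1:1)95:1);")
    assert "Q9" not in pr.screen_candidates(t3, {"REF1"}, {"OG1", "OG2"}, 90)
    t4 = read_newick("((REF1:1,OG1:1):1,(REF2:1,OG2:1):1,X:1);")
    with pytest.raises(ValueError, match="no qualifying clade"):
        pr.screen_candidates(t4, {"REF1", "REF2"}, {"OG1", "OG2"}, 90)


def test_hmmer2_adapter(tmp_path):
    """Synthetic HMMER2-format text (a stand-in built by hand, not a real
    published profile) maps onto the native model with correct columns."""
    sym = list("ACDEFGHIKLMNPQRSTVWY")
    lines = ["HMMER2.0  [synthetic]", "NAME  toy", "LENG  3",
             "HMM        " + "     ".join(sym),
             "         m->m   m->i   m->d   i->m   i->i   d->m   d->d"]
    for i, fav in enumerate("ACD", start=1):
        lines.append(f"     {i}   " + " ".join(
            "2000" if s == fav else "-500" for s in sym))
        lines.append("     -   " + " ".join(["0"] * 20))
        lines.append("     -   0 0 0 0 0 0 0")
    lines.append("//")
    p = tmp_path / "toy.hmm"
    p.write_text("\n".join(lines) + "\n")
    prof = pr.read_hmmer2_profile(p, "A", calibrate_n=200, seed=1)
    assert prof.length == 3
    assert prof.consensus == "ACD"
    assert abs(prof.match_scores[1, AMINO.index("C")] - 2.0) < 1e-9
    assert abs(prof.match_scores[1, AMINO.index("A")] + 0.5) < 1e-9
    with pytest.raises(ValueError, match="HMMER2"):
        bad = tmp_path / "bad.hmm"
        bad.write_text("not a profile\n")
        pr.read_hmmer2_profile(bad, "A")


def test_profile_json_roundtrip(tmp_path, built_profiles):
    prof = built_profiles[0]
    p = tmp_path / "prof.json"
    prof.to_json(p)
    back = pr.ProfileModel.from_json(p)
    assert back.length == prof.length
    assert back.domain_type == prof.domain_type
    assert np.allclose(back.match_scores, prof.match_scores, atol=1e-4)
    assert back.calibration == pytest.approx(prof.calibration)
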