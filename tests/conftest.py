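"""Shared fixtures: one synthetic proteome with planted architectures and the
profiles built from its seed alignments (expensive, so session-scoped)."""

import pytest

from npsphylome import profiles as pr
from npsphylome import synthetic as syn

TEMPLATES = {
    "EAS": "(A-T-C)x2",
    "SID": "A-T-C-dA-T-C",
    "AAR": "A-T-R",
    "NPS12": "A",
}


@pytest.fixture(scope="session")
def planted_proteome():
    """20 genes (5 per subfamily) at divergence 0.15 with recorded truth."""
    records, truth, seeds = syn.synth_proteome(
        TEMPLATES, divergence=0.15, counts_per_subfamily={sf: 5 for sf in TEMPLATES},
        seed=11,
    )
    return records, truth, seeds


@pytest.fixture(scope="session")
def built_profiles(planted_proteome):
    """Calibrated profiles from the generator's emitted seed alignments."""
    _, _, seeds = planted_proteome
    profs = []
    for key in sorted(seeds):
        domain_type = key.split(":")[0]
        profs.append(
            pr.build_profile(seeds[key], domain_type, seed=3, name=key.replace(":", "_"))
        )
    return profs


@pytest.fixture(scope="session")
def scanned_architectures(planted_proteome, built_profiles):
    """Architecture calls for every planted protein."""
    records, _, _ = planted_proteome
    archs = {}
    hits_by_protein = {}
    for rec in records:
        hits = []
        for prof in built_profiles:
            hits.extend(pr.scan_protein(prof, rec))
        hits_by_protein[rec.id] = hits
        archs[rec.id] = pr.call_architecture(hits, rec)
    return archs, hits_by_protein
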