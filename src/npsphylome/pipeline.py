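"""End-to-end orchestration: scan → architectures → A domains → trees →
subfamilies → counts → Fisher → birth-death, from one declarative config.

Every stage reads its inputs from files and writes TSV/FASTA/newick outputs
into the working directory, so any stage can be re-run from stored
intermediates.  All outputs carry a header comment naming the config hash and
seed; identical config + seed gives byte-identical outputs.

The demo bundle generates a complete synthetic input set (multi-species
proteomes with planted architectures, seed alignments, taxonomy map,
ultrametric species tree, and birth-death family counts with one planted
expansion) so the whole chain runs without any downloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import birthdeath, msa, phylogeny, profiles, stats, subfamilies
from .io_formats import (
    Alignment,
    SequenceRecord,
    read_alignment,
    read_count_table,
    read_fasta,
    read_newick,
    tree_to_newick,
    write_count_table,
    write_fasta,
    write_newick,
)
from .synthetic import _mutate, _random_seq, _to_str, simulate_yule_tree, synth_proteome

log = logging.getLogger("npsphylome")

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_bundle", "STAGES"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    The threshold defaults are the screening constants of the original
    analysis: e-value < 1 for candidate hits, >90% support for phylogenetic
    candidate screening, >30% gap masking (50% for reduced datasets), 70%
    subfamily cutoff with an 80% reduced-dataset rescue, 200 NJ bootstrap
    replicates, 1000 birth-death resamplings, significance 0.05.
    """

    # inputs
    proteome_fasta: str = ""
    seed_alignment_dir: str = ""
    taxonomy_tsv: str = ""
    species_tree: str = ""
    outgroup_fasta: str = ""
    reference_file: str = ""
    bdp_counts: str = ""          # optional; defaults to the stage-6 matrix
    output_dir: str = "npsphylome_out"
    # thresholds
    e_value_max: float = 1.0
    search_space: float = 1000.0
    degeneracy_fraction: float = 0.6
    candidate_support: float = 90.0
    mask_fraction: float = 0.30
    reduced_mask_fraction: float = 0.50
    min_domain_length: int = 150
    subfamily_cutoff: float = 70.0
    rescue_cutoff: float = 80.0
    alpha: float = 1.0
    tree_alphas: tuple = (0.5, 1.0, 2.0)  # gamma shapes of the three builders
    bootstrap_replicates: int = 200
    bdp_resamples: int = 1000
    significance: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        checks = [
            # 0 passes validation but fails at the masking stage itself
            # (mask_columns requires a fraction in (0,1])
            (0 <= self.mask_fraction <= 1, "mask_fraction in [0,1]"),
            (0 < self.reduced_mask_fraction <= 1, "reduced_mask_fraction in (0,1]"),
            (0 <= self.subfamily_cutoff <= 100, "subfamily_cutoff in [0,100]"),
            (0 <= self.rescue_cutoff <= 100, "rescue_cutoff in [0,100]"),
            (0 <= self.candidate_support <= 100, "candidate_support in [0,100]"),
            (self.e_value_max > 0, "e_value_max > 0"),
            (self.alpha > 0, "alpha > 0"),
            (self.bootstrap_replicates >= 1, "bootstrap_replicates >= 1"),
            (self.bdp_resamples >= 100, "bdp_resamples >= 100"),
            (0 < self.significance < 1, "significance in (0,1)"),
            (len(self.tree_alphas) == 3, "exactly three tree builders"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        for attr in ("proteome_fasta", "seed_alignment_dir", "taxonomy_tsv",
                     "species_tree", "outgroup_fasta", "reference_file"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise ValueError(f"invalid config: {attr} path does not exist: {p}")

    @property
    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data.pop("output_dir")  # where outputs land does not change them
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tree_alphas" in data:
            data["tree_alphas"] = tuple(data["tree_alphas"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        data["tree_alphas"] = list(data["tree_alphas"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _header(cfg: PipelineConfig, stage: str) -> str:
    return f"npsphylome stage={stage} config={cfg.config_hash} seed={cfg.seed}"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
               index: bool = False, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg, stage)}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, float_format="%.6g")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_scan(cfg: PipelineConfig, ws: Path) -> Path:
    """Build profiles from the seed alignments and scan every protein."""
    proteins = read_fasta(cfg.proteome_fasta)
    profs = []
    for aln_path in sorted(Path(cfg.seed_alignment_dir).glob("*.fasta")):
        # file name convention: <type>[_<subfamily>].fasta  (e.g. A_EAS.fasta)
        stem = aln_path.stem
        domain_type = stem.split("_")[0]
        profs.append(
            profiles.build_profile(
                read_alignment(aln_path), domain_type, seed=cfg.seed, name=stem
            )
        )
    if not profs:
        raise ValueError(f"no seed alignments (*.fasta) in {cfg.seed_alignment_dir}")
    rows = []
    for protein in proteins:
        for prof in profs:
            for h in profiles.scan_protein(
                prof, protein,
                e_value_max=cfg.e_value_max,
                search_space=cfg.search_space,
                degeneracy_fraction=cfg.degeneracy_fraction,
            ):
                rows.append(dict(
                    protein=h.protein_id, domain_type=h.domain_type,
                    start=h.start, end=h.end, bit_score=round(h.bit_score, 3),
                    e_value=h.e_value, degenerate=int(h.degenerate),
                    profile=h.profile_name, profile_start=h.profile_start,
                    profile_end=h.profile_end, profile_len=h.profile_len,
                ))
    df = pd.DataFrame(rows, columns=["protein", "domain_type", "start", "end",
                                     "bit_score", "e_value", "degenerate", "profile",
                                     "profile_start", "profile_end", "profile_len"])
    out = ws / "domain_hits.tsv"
    _write_tsv(df, out, cfg, "scan")
    return out


def _read_hits(path: Path) -> dict[str, list[profiles.DomainHit]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    by_protein: dict[str, list[profiles.DomainHit]] = {}
    for row in df.itertuples(index=False):
        by_protein.setdefault(row.protein, []).append(
            profiles.DomainHit(
                protein_id=row.protein, domain_type=row.domain_type,
                start=int(row.start), end=int(row.end),
                bit_score=float(row.bit_score), e_value=float(row.e_value),
                degenerate=bool(row.degenerate), profile_name=str(row.profile),
                profile_start=int(row.profile_start),
                profile_end=int(row.profile_end),
                profile_len=int(row.profile_len),
            )
        )
    return by_protein


def stage_architect(cfg: PipelineConfig, ws: Path) -> Path:
    proteins = {p.id: p for p in read_fasta(cfg.proteome_fasta)}
    by_protein = _read_hits(ws / "domain_hits.tsv")
    rows = []
    for pid in sorted(proteins):
        arch = profiles.call_architecture(by_protein.get(pid, []), proteins[pid])
        rows.append(dict(
            protein=pid,
            architecture=arch.architecture_string,
            module_count=arch.module_count,
            domains=";".join(
                f"{('dA' if h.degenerate and h.domain_type == 'A' else h.domain_type)}:"
                f"{h.start}-{h.end}" for h in arch.hits
            ),
        ))
    out = ws / "architectures.tsv"
    _write_tsv(pd.DataFrame(rows), out, cfg, "architect")
    return out


def _architectures_from_files(cfg: PipelineConfig, ws: Path) -> dict[str, profiles.Architecture]:
    proteins = {p.id: p for p in read_fasta(cfg.proteome_fasta)}
    by_protein = _read_hits(ws / "domain_hits.tsv")
    return {
        pid: profiles.call_architecture(by_protein.get(pid, []), proteins[pid])
        for pid in sorted(proteins)
    }


def stage_adomains(cfg: PipelineConfig, ws: Path) -> Path:
    """Extract the A-domain set, append the outgroup A domains, align (stack)
    and mask gap-dominated columns."""
    proteins = read_fasta(cfg.proteome_fasta)
    archs = _architectures_from_files(cfg, ws)
    try:
        records = msa.extract_a_domains(
            proteins, archs, include_degenerate=False,
            min_length=cfg.min_domain_length, pad_to_profile=True,
        )
    except ValueError:
        records = msa.extract_a_domains(
            proteins, archs, include_degenerate=False,
            min_length=cfg.min_domain_length,
        )
    if cfg.outgroup_fasta:
        records = records + read_fasta(cfg.outgroup_fasta)
    write_fasta(records, ws / "adomains.fasta")
    try:
        aln = msa.stack_alignment(records)
    except ValueError:
        aln = msa.align_with_mafft(records)
    result = msa.mask_columns(aln, cfg.mask_fraction)
    write_fasta(result.masked.records, ws / "adomains_masked.fasta")
    _write_tsv(
        pd.DataFrame({"kept_column": result.kept_columns}),
        ws / "mask_report.tsv", cfg, "adomains",
    )
    return ws / "adomains_masked.fasta"


def stage_trees(cfg: PipelineConfig, ws: Path) -> list[Path]:
    """Three bootstrap-annotated NJ trees (one per gamma shape), each rooted
    on the outgroup."""
    aln = read_alignment(ws / "adomains_masked.fasta")
    outgroup = [r.id for r in read_fasta(cfg.outgroup_fasta)] if cfg.outgroup_fasta else []
    paths = []
    for i, alpha in enumerate(cfg.tree_alphas, start=1):
        model = phylogeny.EvolModel(alpha=alpha)
        tree = phylogeny.bootstrap_support(
            aln, n_replicates=cfg.bootstrap_replicates, seed=cfg.seed + i, model=model
        )
        if outgroup:
            tree = phylogeny.root_with_outgroup(tree, outgroup)
        out = ws / f"tree{i}.nwk"
        with open(out, "w") as fh:
            fh.write(f"# {_header(cfg, 'trees')}\n")
            fh.write(tree_to_newick(tree))
        paths.append(out)
    return paths


def _read_stage_tree(path: Path):
    text = "".join(l for l in Path(path).read_text().splitlines(keepends=True)
                   if not l.startswith("#"))
    return read_newick(text)


def stage_subfamilies(cfg: PipelineConfig, ws: Path) -> Path:
    trees = [_read_stage_tree(ws / f"tree{i}.nwk") for i in (1, 2, 3)]
    references = [
        l.strip() for l in Path(cfg.reference_file).read_text().splitlines()
        if l.strip() and not l.startswith("#")
    ]
    outgroup = [r.id for r in read_fasta(cfg.outgroup_fasta)] if cfg.outgroup_fasta else []
    names = {}
    for ref in references:
        if "=" in ref:
            label, name = ref.split("=", 1)
            names[label.strip()] = name.strip()
    refs = [r.split("=")[0].strip() for r in references]
    calls, unplaced = subfamilies.extract_subfamilies(
        trees, refs, cutoff=cfg.subfamily_cutoff,
        rescue_cutoff=cfg.rescue_cutoff, outgroup_labels=outgroup,
        names=names or None,
    )
    rows = [
        dict(subfamily=c.name, rescued=int(c.rescued),
             support_tree1=c.supports[0], support_tree2=c.supports[1],
             support_tree3=c.supports[2],
             references=";".join(c.reference_members),
             members=";".join(sorted(c.member_labels)))
        for c in calls
    ]
    _write_tsv(pd.DataFrame(rows), ws / "subfamilies.tsv", cfg, "subfamilies")
    (ws / "unplaced_labels.txt").write_text(
        f"# {_header(cfg, 'subfamilies')}\n" + "".join(f"{l}\n" for l in unplaced)
    )
    assignments = subfamilies.assign_genes(calls, unplaced)
    arows = [
        dict(gene=a.gene, subfamily=a.subfamily, recombinant=int(a.recombinant),
             modules=";".join(f"m{k}:{v}" for k, v in sorted(a.modules.items())))
        for a in assignments
    ]
    _write_tsv(pd.DataFrame(arows), ws / "gene_assignments.tsv", cfg, "subfamilies")
    return ws / "gene_assignments.tsv"


def _species_of_gene(gene: str) -> str:
    return gene.split("_")[0]


def stage_counts(cfg: PipelineConfig, ws: Path) -> Path:
    df = pd.read_csv(ws / "gene_assignments.tsv", sep="\t", comment="#")
    tax = pd.read_csv(cfg.taxonomy_tsv, sep="\t", comment="#")
    group_of = dict(zip(tax.iloc[:, 0].astype(str), tax.iloc[:, 1].astype(str)))
    assignments = [
        subfamilies.GeneAssignment(gene=row.gene, subfamily=row.subfamily)
        for row in df.itertuples(index=False)
    ]
    species_of = {a.gene: _species_of_gene(a.gene) for a in assignments}
    cm = stats.build_count_matrix(assignments, species_of, group_of)
    write_count_table(cm, ws / "subfamily_counts.tsv", header_comment=_header(cfg, "counts"))
    return ws / "subfamily_counts.tsv"


def stage_fisher(cfg: PipelineConfig, ws: Path) -> Path:
    cm = read_count_table(ws / "subfamily_counts.tsv")
    df = stats.fisher_scan(cm, significance=cfg.significance)
    _write_tsv(df, ws / "fisher_tests.tsv", cfg, "fisher")
    return ws / "fisher_tests.tsv"


def stage_bdp(cfg: PipelineConfig, ws: Path) -> Path:
    tree = read_newick(Path(cfg.species_tree))
    counts_path = Path(cfg.bdp_counts) if cfg.bdp_counts else ws / "subfamily_counts.tsv"
    cm = read_count_table(counts_path)
    lam, results, excluded = birthdeath.analyze_families(
        tree, cm, n_resamples=cfg.bdp_resamples, seed=cfg.seed
    )
    frows = [
        dict(family=r.family, lambda_hat=lam, log_likelihood=r.log_likelihood,
             p_value=r.p_value,
             significant=int(r.p_value < cfg.significance),
             n_resamples=cfg.bdp_resamples)
        for r in results
    ]
    _write_tsv(pd.DataFrame(frows), ws / "bdp_families.tsv", cfg, "bdp")
    brows = []
    for r in results:
        for child, info in sorted(r.branch_p.items()):
            brows.append(dict(
                family=r.family, child_node=child,
                parent_count=info["parent_count"], child_count=info["child_count"],
                direction=info["direction"], branch_p=info["p"],
                significant=int(info["p"] < cfg.significance and info["direction"] != "none"),
            ))
    _write_tsv(pd.DataFrame(brows), ws / "bdp_branches.tsv", cfg, "bdp")
    arows = []
    for r in results:
        for node, count in sorted(r.ancestral_counts.items()):
            arows.append(dict(family=r.family, node=node, count=count))
    _write_tsv(pd.DataFrame(arows), ws / "bdp_ancestral_counts.tsv", cfg, "bdp")
    if excluded:
        (ws / "bdp_excluded_families.txt").write_text(
            f"# {_header(cfg, 'bdp')} (parsimony root count 0)\n"
            + "".join(f"{f}\n" for f in excluded)
        )
    return ws / "bdp_families.tsv"


STAGES = {
    "scan": stage_scan,
    "architect": stage_architect,
    "adomains": stage_adomains,
    "trees": stage_trees,
    "subfamilies": stage_subfamilies,
    "counts": stage_counts,
    "fisher": stage_fisher,
    "bdp": stage_bdp,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all, in order) and return the
    working directory.  A stage error halts the run with the stage named;
    partial outputs are retained."""
    cfg.validate()
    ws = Path(cfg.output_dir)
    ws.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(ws / "config_used.yaml")
    todo = stages or list(STAGES)
    log_lines = [f"config={cfg.config_hash} seed={cfg.seed}"]
    for name in todo:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            STAGES[name](cfg, ws)
        except Exception as exc:
            log_lines.append(f"stage={name} FAILED: {exc}")
            (ws / "run_log.txt").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        log_lines.append(f"stage={name} ok ({dt:.1f}s)")
        log.info("stage %s done in %.1fs", name, dt)
    (ws / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return ws


# ---------------------------------------------------------------------------
# Demo bundle
# ---------------------------------------------------------------------------

DEMO_TEMPLATES = {
    "EAS": "(A-T-C)x2",
    "SID": "A-T-C-dA-T-C",
    "AAR": "A-T-R",
    "NPS12": "A",
}


def make_demo_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_group_a: int = 4,
    n_group_b: int = 2,
    divergence: float = 0.10,
    eas_per_species: int = 2,
    nps12_per_species: int = 2,
    n_null_families: int = 30,
    bd_lambda: float = 0.002,
    tree_height: float = 500.0,
    n_outgroup: int = 4,
) -> PipelineConfig:
    """Write a complete synthetic input bundle and return its config.

    Group A species carry the multimodular EAS-like expansion (absent from
    group B); NPS12-like standalone A domains are group-B only; SID-like
    (with a degenerate second A domain) and AAR-like genes are universal.
    The birth-death table holds null families simulated at ``bd_lambda`` plus
    one planted family with an expansion (1 → 8) on an internal branch.
    """
    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    inputs = outdir / "inputs"
    rng = np.random.default_rng(seed)

    n_species = n_group_a + n_group_b
    species = [f"sp{i + 1}" for i in range(n_species)]
    groups = {sp: ("GroupA" if i < n_group_a else "GroupB")
              for i, sp in enumerate(species)}

    counts = {
        "EAS": {sp: (eas_per_species if groups[sp] == "GroupA" else 0) for sp in species},
        "SID": {sp: 1 for sp in species},
        "AAR": {sp: 1 for sp in species},
        "NPS12": {sp: (nps12_per_species if groups[sp] == "GroupB" else 0) for sp in species},
    }
    records, truth, seeds = synth_proteome(
        DEMO_TEMPLATES, divergence, counts, seed=int(rng.integers(2**31))
    )
    write_fasta(records, inputs / "proteomes.fasta")
    seed_dir = inputs / "seed_alignments"
    seed_dir.mkdir(exist_ok=True)
    for key, aln in seeds.items():
        write_fasta(aln.records, seed_dir / f"{key.replace(':', '_')}.fasta")

    # outgroup: a tight clade of adenylating-enzyme-like sequences unrelated
    # to every NRPS subfamily consensus (so it roots outside the radiation)
    og_rng = np.random.default_rng(seed + 101)
    og_consensus = _random_seq(og_rng, len(seeds["A:AAR"].records[0].residues))
    og_records = [
        SequenceRecord(f"OG{i + 1}", _to_str(_mutate(og_consensus, 0.05, og_rng)))
        for i in range(n_outgroup)
    ]
    write_fasta(og_records, inputs / "outgroup_adomains.fasta")

    with open(inputs / "taxonomy.tsv", "w") as fh:
        fh.write("species\tgroup\n")
        for sp in species:
            fh.write(f"{sp}\t{groups[sp]}\n")

    # references: the first gene of each subfamily, module 1
    refs = []
    for sf in DEMO_TEMPLATES:
        first = sorted(p for p, s in truth.subfamily_of.items() if s == sf)[0]
        refs.append(f"{first}|m1={sf}")
    (inputs / "references.txt").write_text("".join(r + "\n" for r in refs))

    species_tree = simulate_yule_tree(n_species, tree_height, seed + 7, prefix="sp")
    write_newick(species_tree, inputs / "species_tree.nwk")

    from .synthetic import simulate_family_counts

    cm, _anc = simulate_family_counts(
        species_tree, bd_lambda, root_count=2, n_families=n_null_families,
        seed=seed + 13, condition_on_survival=True,
    )
    # planted expansion: an internal clade reached by a short-ish edge (about
    # a tenth of the tree height, so the jump cannot be smeared across edges)
    # gets 8 copies at every tip; every other species keeps 1
    internal = [
        nd for nd in species_tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
        and 2 <= len(nd.leaf_nodes()) <= max(2, n_species // 2)
    ]
    target = min(internal, key=lambda nd: abs(nd.edge.length - 0.1 * tree_height))
    expanded_tips = {lf.taxon.label for lf in target.leaf_iter()}
    planted = {sp: (8 if sp in expanded_tips else 1) for sp in cm.species}
    counts_df = cm.counts.copy()
    counts_df["planted_expansion"] = [planted[sp] for sp in counts_df.index]
    with open(inputs / "bd_family_counts.tsv", "w") as fh:
        counts_df.to_csv(fh, sep="\t", index_label="species")

    truth_path = outdir / "demo_truth.json"
    truth_path.write_text(json.dumps({
        "subfamily_members": {
            sf: sorted(
                f"{pid}|m{k}"
                for pid, doms in truth.proteins.items()
                if truth.subfamily_of[pid] == sf
                for k, (dtype, *_rest) in enumerate(
                    [d for d in doms if d[0] in ("A", "dA")], start=1
                )
                if dtype == "A"
            )
            for sf in DEMO_TEMPLATES
        },
        "architectures": truth.architectures,
        "expanded_clade_tips": sorted(expanded_tips),
        "planted_family": "planted_expansion",
    }, indent=1))

    return PipelineConfig(
        proteome_fasta=str(inputs / "proteomes.fasta"),
        seed_alignment_dir=str(seed_dir),
        taxonomy_tsv=str(inputs / "taxonomy.tsv"),
        species_tree=str(inputs / "species_tree.nwk"),
        outgroup_fasta=str(inputs / "outgroup_adomains.fasta"),
        reference_file=str(inputs / "references.txt"),
        bdp_counts=str(inputs / "bd_family_counts.tsv"),
        output_dir=str(outdir / "results"),
        # demo problem size: enough replicates for stable supports on the
        # strongly separated planted clades while keeping the demo fast
        bootstrap_replicates=40,
        seed=seed,
    )
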