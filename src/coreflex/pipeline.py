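"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes pangenome partitioning, family alignment and
diversity/divergence, mutation annotation and compartment tallies,
selection statistics, the essentiality cross-tab, and structure contacts
on a single declarative configuration, emitting one tidy TSV per summary
artifact and a JSON run report with per-stage record counts, a parameter
echo, and a checksum for every emitted file.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import alignment as aln_mod
from . import io as cio
from . import mutations as mut_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from . import structures as struct_mod
from .pangenome import (
    ScorerConfig,
    build_panortholog_set,
    classify_core_flexible,
    reciprocal_best_hits,
    score_all_pairs,
)

logger = logging.getLogger(__name__)

KNOWN_KEYS = {
    "seed",
    "outdir",
    "reference_genome",
    "genetic_code_id",
    "site_ratio",
    "min_identity",
    "min_coverage",
    "small_indel_max_bp",
    "contact_threshold_A",
    "n_boot",
    "simulate",
    "input_dir",
    "planted_structure_distances",
}


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class RunConfig:
    seed: int
    outdir: str = "coreflex_out"
    reference_genome: str | None = None  # default: first simulated genome
    genetic_code_id: int = 11
    site_ratio: float = stats_mod.DEFAULT_SITE_RATIO
    min_identity: float = 0.5
    min_coverage: float = 0.5
    small_indel_max_bp: int = 50
    contact_threshold_A: float = struct_mod.DEFAULT_CONTACT_THRESHOLD
    n_boot: int = 1000
    simulate: dict = field(default_factory=dict)
    input_dir: str | None = None
    planted_structure_distances: list[float] = field(
        default_factory=lambda: [5.0, 12.0]
    )


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, reporting all violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    violations = []
    unknown = sorted(set(raw) - KNOWN_KEYS)
    if unknown:
        violations.append(f"unknown config keys: {unknown}")
    if "seed" not in raw:
        violations.append("missing required key: seed")
    elif not isinstance(raw["seed"], int):
        violations.append("seed must be an integer")
    if "input_dir" in raw and raw["input_dir"] is not None:
        if not Path(raw["input_dir"]).exists():
            violations.append(f"input_dir does not exist: {raw['input_dir']}")
    for key in ("min_identity", "min_coverage"):
        if key in raw and not (0.0 <= float(raw[key]) <= 1.0):
            violations.append(f"{key} must be in [0,1]")
    if "site_ratio" in raw and float(raw["site_ratio"]) <= 0:
        violations.append("site_ratio must be positive")
    if violations:
        raise ConfigError(violations)
    known = {k: v for k, v in raw.items() if k in KNOWN_KEYS}
    return RunConfig(**known)


@dataclass
class RunReport:
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    log_path: str = ""

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path)] = digest


def _write(report: RunReport, df: pd.DataFrame, path: Path) -> None:
    cio.write_tsv(df, path)
    report.register(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage on synthetic (default) or pre-generated inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("coreflex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_stages(config, outdir, report, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, outdir: Path, report: RunReport, log_path: Path) -> RunReport:
    logger.info("parameters: %s", json.dumps(report.config, sort_keys=True, default=str))

    # --- stage: synthetic inputs -----------------------------------------
    sim_cfg = sim_mod.PangenomeSimConfig(seed=config.seed, **config.simulate)
    sim = sim_mod.simulate_pangenome(sim_cfg)
    annotations = sim.annotations
    reference = config.reference_genome or sim.reference_genome_id
    if reference not in annotations:
        raise ValueError(f"reference genome {reference} not among inputs")
    inputs_dir = outdir / "inputs"
    for annot in annotations.values():
        cio.write_genome(annot, inputs_dir)
    cio.write_tsv(sim.truth, inputs_dir / "truth_pangenome.tsv")
    report.stage_counts["genomes"] = len(annotations)

    # --- stage: core genes -----------------------------------------------
    scorer = ScorerConfig(
        min_identity=config.min_identity, min_coverage=config.min_coverage
    )
    genome_ids = sorted(annotations)
    hits_by_pair = {}
    for ga, gb in itertools.permutations(genome_ids, 2):
        hits_by_pair[(ga, gb)] = score_all_pairs(
            annotations[ga].proteins(), annotations[gb].proteins(), scorer
        )
    rbh_by_pair = {
        (ga, gb): reciprocal_best_hits(hits_by_pair[(ga, gb)], hits_by_pair[(gb, ga)])
        for ga, gb in itertools.combinations(genome_ids, 2)
    }
    groups = build_panortholog_set(genome_ids, rbh_by_pair, hits_by_pair)
    partition = classify_core_flexible(annotations[reference], groups)
    cio.write_ortholog_groups(groups, outdir / "ortholog_groups.tsv")
    report.register(outdir / "ortholog_groups.tsv")
    cio.write_partition(partition, outdir / "partition.tsv")
    report.register(outdir / "partition.tsv")
    report.stage_counts["panortholog_groups"] = len(groups)
    report.stage_counts["core_genes"] = len(partition.core_gene_ids)

    # --- stage: diversity and divergence ---------------------------------
    alignments: dict[str, aln_mod.ProteinAlignment] = {}
    div_rows = []
    ref_gene_to_family: dict[str, str] = {}
    for grp in groups:
        members = grp.member_map()
        seqs = {
            g: annotations[g].genes[gene].aa_seq for g, gene in members.items()
        }
        fam_aln = aln_mod.align_family(seqs, family_id=grp.family_id)
        alignments[grp.family_id] = fam_aln
        rec = aln_mod.pairwise_aa_diversity(fam_aln)
        ref_gene = members.get(reference)
        if ref_gene:
            ref_gene_to_family[ref_gene] = grp.family_id
        div_rows.append(
            {
                "family_id": grp.family_id,
                "gene_id": ref_gene,
                "n_seqs": rec.n_seqs,
                "n_pairs": rec.n_pairs,
                "pi_aa": rec.pi_aa,
            }
        )
    diversity = pd.DataFrame(
        div_rows, columns=["family_id", "gene_id", "n_seqs", "n_pairs", "pi_aa"]
    )
    _write(report, diversity, outdir / "diversity.tsv")

    outgroup = next(g for g in genome_ids if g != reference)
    divg_rows = []
    for grp in groups:
        members = grp.member_map()
        pair_aln = aln_mod.align_family(
            {
                reference: annotations[reference].genes[members[reference]].aa_seq,
                outgroup: annotations[outgroup].genes[members[outgroup]].aa_seq,
            },
            family_id=grp.family_id,
        )
        rec = aln_mod.pairwise_divergence(pair_aln)
        divg_rows.append(
            {
                "family_id": grp.family_id,
                "gene_id": members[reference],
                "aligned_length": rec.aligned_length,
                "n_diff": rec.n_diff,
                "d": rec.d,
            }
        )
    divergence = pd.DataFrame(
        divg_rows, columns=["family_id", "gene_id", "aligned_length", "n_diff", "d"]
    )
    _write(report, divergence, outdir / "divergence.tsv")
    report.stage_counts["aligned_families"] = len(alignments)

    # --- stage: mutations -------------------------------------------------
    mut_cfg = sim_mod.MutationSimConfig(seed=config.seed, code_id=config.genetic_code_id)
    sim_mut = sim_mod.simulate_mutation_table(mut_cfg, annotations[reference], partition)
    mut_table = mut_mod.annotate_mutation_table(sim_mut.table, config.genetic_code_id)
    cio.write_tsv(mut_table, outdir / "mutations_annotated.tsv")
    report.register(outdir / "mutations_annotated.tsv")
    collapsed = mut_mod.independent_event_collapse(mut_table)
    report.stage_counts["mutation_records"] = len(mut_table)
    report.stage_counts["independent_events"] = len(collapsed)

    enr_rows = []
    for context in ("nonmutator", "mutator"):
        for snp_class in ("nonsynonymous", "synonymous"):
            core_n, flex_n = mut_mod.tabulate_compartment_counts(
                collapsed, partition, mutator_context=context, snp_class=snp_class
            )
            res = stats_mod.enrichment_test(
                stats_mod.CompartmentCounts(
                    core_n, flex_n, partition.L_core, partition.L_flex
                )
            )
            enr_rows.append(
                {
                    "mutator_context": context,
                    "snp_class": snp_class,
                    "core": core_n,
                    "flexible": flex_n,
                    "odds_ratio": res.odds_ratio,
                    "rate_ratio": res.rate_ratio,
                    "p0": res.p0,
                    "p_binomial_two_tailed": res.p_value,
                }
            )
    enrichment = pd.DataFrame(enr_rows)
    _write(report, enrichment, outdir / "enrichment_table.tsv")

    # dN/dS per compartment and context
    dnds_rows = []
    for context in ("nonmutator", "mutator"):
        row = {"mutator_context": context}
        counts = {}
        for snp_class in ("nonsynonymous", "synonymous"):
            counts[snp_class] = mut_mod.tabulate_compartment_counts(
                collapsed, partition, mutator_context=context, snp_class=snp_class
            )
        for i, comp in enumerate(("core", "flexible")):
            nonsyn = counts["nonsynonymous"][i]
            syn = counts["synonymous"][i]
            row[f"dnds_{comp}"] = (
                stats_mod.dnds_ratio(nonsyn, syn, config.site_ratio).dnds
                if syn > 0
                else float("nan")
            )
        dnds_rows.append(row)
    _write(report, pd.DataFrame(dnds_rows), outdir / "dnds.tsv")

    # --- stage: G scores --------------------------------------------------
    nonmut_nonsyn = collapsed[
        (collapsed["mutator_context"] == "nonmutator")
        & (collapsed["snp_class"].isin(["nonsynonymous", "nonsense_as_nonsynonymous"]))
    ]
    obs = nonmut_nonsyn.groupby("gene_id").size()
    ref_genes = annotations[reference].genes
    gstats = stats_mod.gscores(
        [
            (gid, ref_genes[gid].length_bp, int(obs.get(gid, 0)))
            for gid in sorted(ref_genes)
        ]
    )
    gframe = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "L": g.L, "O": g.O, "E": g.E, "G": g.G}
            for g in gstats
        ]
    )
    _write(report, gframe, outdir / "gscores.tsv")
    report.stage_counts["genes_positive_G"] = int((gframe["G"] > 0).sum())

    # --- stage: selection statistics --------------------------------------
    tests_rows = []

    def record_test(label: str, res: stats_mod.RankTestResult) -> None:
        tests_rows.append(
            {
                "comparison": label,
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "sidedness": res.sidedness,
                "n": "/".join(str(v) for v in res.n),
            }
        )

    gvd = gframe.merge(diversity[["gene_id", "pi_aa"]], on="gene_id", how="inner")
    _write(report, gvd, outdir / "gscore_vs_diversity.tsv")
    if len(gvd) >= 3 and gvd["G"].nunique() > 1 and gvd["pi_aa"].nunique() > 1:
        record_test(
            "gscore_vs_diversity", stats_mod.spearman_correlation(gvd["G"], gvd["pi_aa"])
        )
        pos = gvd.loc[gvd["G"] > 0, "pi_aa"]
        zero = gvd.loc[gvd["G"] == 0, "pi_aa"]
        if len(pos) and len(zero):
            record_test("diversity_positiveG_vs_zeroG", stats_mod.mann_whitney(pos, zero))
            for label, vals in (("positive_G", pos), ("zero_G", zero)):
                if len(vals) >= 2:
                    ci = stats_mod.bootstrap_median_ci(
                        vals, n_boot=config.n_boot, seed=config.seed
                    )
                    tests_rows.append(
                        {
                            "comparison": f"median_diversity_{label}",
                            "method": "bootstrap_median_ci",
                            "statistic": ci.median,
                            "p_value": float("nan"),
                            "sidedness": f"ci95=[{ci.ci_low:.6g},{ci.ci_high:.6g}]",
                            "n": str(len(vals)),
                        }
                    )

    gvg = gframe.merge(divergence[["gene_id", "d"]], on="gene_id", how="inner")
    _write(report, gvg, outdir / "gscore_vs_divergence.tsv")
    if len(gvg) >= 3 and gvg["G"].nunique() > 1 and gvg["d"].nunique() > 1:
        record_test(
            "gscore_vs_divergence", stats_mod.spearman_correlation(gvg["G"], gvg["d"])
        )

    # site-partition diversity at mutated residues
    sp_rows = []
    snp_events = nonmut_nonsyn[nonmut_nonsyn["category"] == "snp"]
    for gene_id, grp in snp_events.groupby("gene_id"):
        family_id = ref_gene_to_family.get(gene_id)
        if family_id is None:
            continue
        fam_aln = alignments[family_id]
        cols = sorted(
            {
                aln_mod.map_residue_to_column(fam_aln, reference, int(ri))
                for ri in grp["residue_index"].dropna()
            }
        )
        if not cols:
            continue
        part = aln_mod.partition_site_diversity(fam_aln, cols)
        sp_rows.append(
            {
                "gene_id": gene_id,
                "n_target_sites": part.n_target_sites,
                "pi_target": part.pi_target,
                "pi_rest": part.pi_rest,
            }
        )
    site_partition = pd.DataFrame(
        sp_rows, columns=["gene_id", "n_target_sites", "pi_target", "pi_rest"]
    )
    _write(report, site_partition, outdir / "site_partition.tsv")
    nonzero = site_partition[
        (site_partition["pi_target"] != site_partition["pi_rest"])
    ]
    if len(site_partition) >= 6 and len(nonzero) > 0:
        record_test(
            "site_diversity_mutated_vs_rest",
            stats_mod.wilcoxon_signed_rank(
                site_partition["pi_target"], site_partition["pi_rest"]
            ),
        )

    # --- stage: essentiality cross-tab ------------------------------------
    ess_cfg = sim_mod.EssentialitySimConfig(seed=config.seed)
    ess = sim_mod.simulate_essentiality_table(ess_cfg, partition)
    cio.write_tsv(ess, inputs_dir / "essentiality.tsv")
    core_scores = ess.loc[ess["compartment"] == "core", "essentiality_score"]
    flex_scores = ess.loc[ess["compartment"] == "flexible", "essentiality_score"]
    if len(core_scores) >= 2 and len(flex_scores) >= 2:
        record_test(
            "essentiality_core_vs_flexible",
            stats_mod.welch_t(core_scores, flex_scores, alternative="greater"),
        )

    multi_hit = obs[obs >= 2].index
    ko_events = collapsed[
        (collapsed["mutator_context"] == "nonmutator")
        & (collapsed["category"].isin(["small_indel", "is_insertion", "large_deletion"]))
    ]
    ko_flagged = set()
    for row in ko_events.itertuples(index=False):
        gene = ref_genes.get(row.gene_id)
        if gene is None:
            continue
        rec = mut_mod.MutationRecord(
            population=row.population,
            generation=int(row.generation),
            clone_id=row.clone_id,
            gene_id=row.gene_id,
            position=int(row.position),
            category=row.category,
            mutator_context=row.mutator_context,
            independent_event_id=row.independent_event_id,
            length_bp=int(row.length_bp) if pd.notna(row.length_bp) else None,
        )
        flag = mut_mod.flag_potential_knockout(
            rec, gene, small_indel_max_bp=config.small_indel_max_bp
        )
        if flag.is_potential_knockout:
            ko_flagged.add(row.gene_id)
    ess_by_gene = ess.set_index("gene_id")["essentiality_score"]
    ke_rows = []
    for gid in sorted(multi_hit):
        if gid not in ess_by_gene.index:
            continue
        ke_rows.append(
            {
                "gene_id": gid,
                "essentiality_score": int(ess_by_gene[gid]),
                "has_potential_knockout": gid in ko_flagged,
            }
        )
    ke = pd.DataFrame(
        ke_rows, columns=["gene_id", "essentiality_score", "has_potential_knockout"]
    )
    _write(report, ke, outdir / "knockout_essentiality.tsv")
    if len(ke):
        pos_ess = ke["essentiality_score"] > 0
        table = [
            [int((pos_ess & ~ke["has_potential_knockout"]).sum()),
             int((pos_ess & ke["has_potential_knockout"]).sum())],
            [int((~pos_ess & ~ke["has_potential_knockout"]).sum()),
             int((~pos_ess & ke["has_potential_knockout"]).sum())],
        ]
        record_test("knockout_vs_essentiality", stats_mod.fisher_exact_one_tailed(table))

    _write(report, pd.DataFrame(tests_rows), outdir / "tests.tsv")
    report.stage_counts["tests"] = len(tests_rows)

    # --- stage: structure contacts ----------------------------------------
    pdb_text = sim_mod.simulate_toy_structure(
        config.planted_structure_distances, seed=config.seed
    )
    (inputs_dir / "toy_structure.pdb").write_text(pdb_text)
    model = struct_mod.parse_structure(pdb_text, structure_id="toy")
    contact_rows = []
    chain_ids = sorted(c for c in model.chain_kind if c != "A")
    for chain in chain_ids:
        res = struct_mod.min_distance_to_partners(
            model, chain, 1, threshold=config.contact_threshold_A
        )
        contact_rows.append(
            {
                "structure_id": "toy",
                "query_residue": res.query_residue,
                "chain": res.target_chain,
                "residue": res.target_residue,
                "min_distance_A": res.min_distance,
                "partner_kind": res.partner_kind,
                "within_threshold": res.within_threshold,
            }
        )
    contacts = pd.DataFrame(contact_rows)
    _write(report, contacts, outdir / "contacts.tsv")
    report.stage_counts["contacts"] = len(contacts)

    report.log_path = str(log_path)
    report_path = Path(config.outdir) / "run_report.json"
    report_path.write_text(
        json.dumps(
            {
                "config": report.config,
                "stage_counts": report.stage_counts,
                "files": report.files,
                "log_path": report.log_path,
            },
            indent=2,
            default=str,
        )
    )
    return report
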