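"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes — a bacterial pangenome with
labelled core/flexible families, an experimental-evolution mutation table
with a planted core enrichment factor, a knockout-collection essentiality
score table, and toy multi-chain structures with planted inter-chain
distances — so every stage is testable without external downloads.

Sequence evolution is a star tree: each family member diverges
independently from one random ancestor, with per-codon substitutions and
occasional frame-preserving codon indels.  That is sufficient for testing
the diversity metric, which never uses tree shape.  All randomness flows
from one master seed through labelled substreams, so outputs are
byte-identical per seed and individual artifacts can be regenerated
stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import DEFAULT_CODE_ID, codon_neighbors, sense_codons
from .mutations import MUTATION_TABLE_COLUMNS, SnpClass, classify_snp
from .pangenome import CoreGenomePartition, GeneModel, GenomeAnnotation

# substream labels: stable integers per artifact
_STREAM_PANGENOME = 1
_STREAM_MUTATIONS = 2
_STREAM_ESSENTIALITY = 3
_STREAM_STRUCTURE = 4

ESSENTIALITY_SCORES = tuple(range(3, -5, -1))  # +3 (essential) .. -4 (dispensable)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class PangenomeSimConfig:
    """Desk-scale pangenome: a handful of genomes with labelled families."""

    seed: int
    n_genomes: int = 5
    n_core: int = 20
    n_flexible: int = 10
    flexible_presence_prob: float = 0.6
    gene_length_codons: tuple[int, int] = (60, 120)
    per_site_substitution_prob: float = 0.02  # per codon, per genome
    indel_prob: float = 0.1  # per gene copy
    indel_length_codons: tuple[int, int] = (1, 4)
    force_absence: bool = True
    code_id: int = DEFAULT_CODE_ID

    def validate(self) -> None:
        for p in (self.flexible_presence_prob, self.per_site_substitution_prob, self.indel_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} out of [0,1]")
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.n_core < 0 or self.n_flexible < 0:
            raise ValueError("family counts must be non-negative")
        lo, hi = self.gene_length_codons
        if lo < 10 or hi < lo:
            raise ValueError("gene_length_codons bounds invalid")


@dataclass(frozen=True)
class MutationSimConfig:
    """Mutation-table generator with a planted core enrichment factor.

    Event totals default to the structure of a 12-population experiment in
    which six populations kept the ancestral point-mutation rate and six
    evolved hypermutability; nonmutator nonsynonymous events hit core genes
    at ``core_enrichment_factor`` times the per-bp flexible rate (the
    selection signal), while synonymous events everywhere and all mutator
    events are length-proportional (hitchhiker-dominated null).
    """

    seed: int
    n_nonmutator_events: int = 194
    n_mutator_events: int = 6473
    nonsyn_fraction_nonmutator: float = 174 / 194
    nonsyn_fraction_mutator: float = 4775 / 6473
    core_enrichment_factor: float = 2.0
    knockout_event_prob: dict[str, float] = field(
        default_factory=lambda: {
            "small_indel": 0.04,
            "is_insertion": 0.02,
            "large_deletion": 0.02,
        }
    )
    duplicate_observation_prob: float = 0.1
    generation: int = 50_000
    code_id: int = DEFAULT_CODE_ID

    def validate(self) -> None:
        if self.core_enrichment_factor <= 0:
            raise ValueError("core_enrichment_factor must be > 0")
        if self.n_nonmutator_events < 0 or self.n_mutator_events < 0:
            raise ValueError("event counts must be non-negative")
        if sum(self.knockout_event_prob.values()) > 1.0:
            raise ValueError("knockout probabilities sum above 1")


@dataclass(frozen=True)
class EssentialitySimConfig:
    """Integer knockout-collection scores on the +3..-4 scale.

    Scores are drawn from compartment-specific discretised-normal weight
    vectors; the defaults plant a one-point mean shift towards essentiality
    for core genes.
    """

    seed: int
    mu_core: float = -0.5
    mu_flexible: float = -1.5
    sigma: float = 1.5

    def weights(self, mu: float) -> np.ndarray:
        scores = np.array(ESSENTIALITY_SCORES, dtype=float)
        w = np.exp(-0.5 * ((scores - mu) / self.sigma) ** 2)
        return w / w.sum()

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# pangenome simulation

@dataclass
class SimulatedPangenome:
    config: PangenomeSimConfig
    annotations: dict[str, GenomeAnnotation]
    truth: pd.DataFrame  # family_id, genome_id, gene_id, compartment
    reference_genome_id: str

    def truth_partition(self) -> CoreGenomePartition:
        """The generator's own core/flexible labels for the reference genome."""
        ref = self.annotations[self.reference_genome_id]
        rows = self.truth[self.truth["genome_id"] == self.reference_genome_id]
        core = frozenset(rows.loc[rows["compartment"] == "core", "gene_id"])
        flex = frozenset(rows.loc[rows["compartment"] == "flexible", "gene_id"])
        return CoreGenomePartition(
            reference_genome_id=self.reference_genome_id,
            core_gene_ids=core,
            flexible_gene_ids=flex,
            L_core=sum(ref.genes[g].length_bp for g in core),
            L_flex=sum(ref.genes[g].length_bp for g in flex),
        )


def _random_cds(rng: np.random.Generator, n_codons: int, code_id: int) -> list[str]:
    codons = list(sense_codons(code_id))
    idx = rng.integers(0, len(codons), size=n_codons)
    return [codons[i] for i in idx]


def _mutate_codons(
    codons: list[str], rng: np.random.Generator, p_sub: float, code_id: int
) -> list[str]:
    out = list(codons)
    sense = sense_codons(code_id)
    hits = np.nonzero(rng.random(len(out)) < p_sub)[0]
    for i in hits:
        choices = [c for c in sense if c != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def _apply_indel(
    codons: list[str],
    rng: np.random.Generator,
    length_bounds: tuple[int, int],
    code_id: int,
) -> list[str]:
    lo, hi = length_bounds
    length = int(rng.integers(lo, hi + 1))
    if rng.random() < 0.5 and len(codons) > length + 10:
        start = int(rng.integers(0, len(codons) - length))
        return codons[:start] + codons[start + length :]
    start = int(rng.integers(0, len(codons) + 1))
    return codons[:start] + _random_cds(rng, length, code_id) + codons[start:]


def simulate_pangenome(config: PangenomeSimConfig) -> SimulatedPangenome:
    """Generate genome annotations plus a family/compartment truth table.

    Core families are single-copy in every genome; each flexible family is
    present per genome with ``flexible_presence_prob`` and, unless
    ``force_absence`` is disabled, guaranteed absent from at least one
    genome so the truth labels match the panortholog definition exactly.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_PANGENOME)
    genome_ids = [f"g{i:02d}" for i in range(1, config.n_genomes + 1)]
    stop = "TAA"
    lo, hi = config.gene_length_codons

    families = []
    for f in range(config.n_core + config.n_flexible):
        is_core = f < config.n_core
        fam_id = f"fam{f + 1:04d}"
        n_codons = int(rng.integers(lo, hi + 1))
        ancestor = _random_cds(rng, n_codons, config.code_id)
        if is_core:
            presence = [True] * config.n_genomes
        else:
            presence = list(rng.random(config.n_genomes) < config.flexible_presence_prob)
            if not any(presence):
                presence[int(rng.integers(0, config.n_genomes))] = True
            if all(presence) and config.force_absence:
                presence[int(rng.integers(0, config.n_genomes))] = False
        families.append((fam_id, is_core, ancestor, presence))

    annotations = {g: GenomeAnnotation(genome_id=g) for g in genome_ids}
    truth_rows = []
    positions = {g: 1 for g in genome_ids}
    spacer = 50
    for fam_id, is_core, ancestor, presence in families:
        for gi, genome_id in enumerate(genome_ids):
            if not presence[gi]:
                continue
            codons = _mutate_codons(
                ancestor, rng, config.per_site_substitution_prob, config.code_id
            )
            if rng.random() < config.indel_prob:
                codons = _apply_indel(codons, rng, config.indel_length_codons, config.code_id)
            nt = "".join(codons) + stop
            gene_id = f"{genome_id}_{fam_id}"
            gene = GeneModel.from_cds(
                gene_id=gene_id,
                genome_id=genome_id,
                contig="chr",
                start=positions[genome_id],
                strand="+",
                nt_seq=nt,
                code_id=config.code_id,
            )
            positions[genome_id] = gene.end + spacer + 1
            annotations[genome_id].add(gene)
            truth_rows.append(
                {
                    "family_id": fam_id,
                    "genome_id": genome_id,
                    "gene_id": gene_id,
                    "compartment": "core" if is_core else "flexible",
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedPangenome(
        config=config,
        annotations=annotations,
        truth=truth,
        reference_genome_id=genome_ids[0],
    )


# ---------------------------------------------------------------------------
# mutation-table simulation

@dataclass
class SimulatedMutations:
    config: MutationSimConfig
    table: pd.DataFrame
    truth: dict


def _sample_snp(
    gene: GeneModel,
    rng: np.random.Generator,
    want_nonsyn: bool,
    code_id: int,
) -> tuple[str, str, int, int]:
    """(codon_from, codon_to, residue_index, genome_position) of one SNP.

    Candidate codon changes are rejection-sampled against the SNP
    classifier so the generated change always carries its intended label.
    """
    n_codons = len(gene.nt_seq) // 3 - 1  # exclude the stop codon
    for _ in range(200):
        ci = int(rng.integers(0, n_codons))
        codon_from = gene.nt_seq[3 * ci : 3 * ci + 3]
        neighbors = codon_neighbors(codon_from)
        ok = []
        for nb in neighbors:
            cls = classify_snp(codon_from, nb, code_id)
            if want_nonsyn and cls.counts_as_nonsynonymous:
                ok.append(nb)
            elif not want_nonsyn and cls is SnpClass.SYNONYMOUS:
                ok.append(nb)
        if not ok:
            continue
        codon_to = ok[int(rng.integers(0, len(ok)))]
        changed = next(k for k in range(3) if codon_from[k] != codon_to[k])
        pos = gene.start + 3 * ci + changed
        return codon_from, codon_to, ci + 1, pos
    raise RuntimeError(f"could not sample a SNP in {gene.gene_id}")


def simulate_mutation_table(
    config: MutationSimConfig,
    annotation: GenomeAnnotation,
    partition: CoreGenomePartition,
) -> SimulatedMutations:
    """Plant mutations on the reference genome with a known enrichment.

    Nonmutator nonsynonymous events land on genes with per-bp rate
    proportional to ``core_enrichment_factor`` in the core compartment and
    1 in the flexible compartment; synonymous events and all mutator
    events are purely length-proportional.  A fraction of nonmutator
    nonsynonymous events become knockout-category events (small indel /
    IS insertion / large deletion) instead of SNPs.
    """
    config.validate()
    if partition.L_core <= 0 or partition.L_flex <= 0:
        raise ValueError("partition is missing compartment lengths")
    rng = _rng(config.seed, _STREAM_MUTATIONS)

    genes = sorted(annotation.genes.values(), key=lambda g: g.gene_id)
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    is_core = np.array(
        [g.gene_id in partition.core_gene_ids for g in genes], dtype=bool
    )
    r = config.core_enrichment_factor
    w_nonsyn = lengths * np.where(is_core, r, 1.0)
    w_syn = lengths.copy()
    w_nonsyn /= w_nonsyn.sum()
    w_syn /= w_syn.sum()

    nonmut_pops = [f"Ara+{i}" for i in range(1, 7)]
    mut_pops = [f"Ara-{i}" for i in range(1, 7)]
    ko_cats = list(config.knockout_event_prob)
    ko_probs = np.array([config.knockout_event_prob[c] for c in ko_cats])

    rows = []
    truth_counts = {"core_nonsyn": 0, "flex_nonsyn": 0, "core_syn": 0, "flex_syn": 0}
    event_no = 0

    def emit(context: str, n_events: int, nonsyn_fraction: float, pops: list[str]) -> None:
        nonlocal event_no
        n_nonsyn = int(round(n_events * nonsyn_fraction))
        for kind, n_kind in (("nonsyn", n_nonsyn), ("syn", n_events - n_nonsyn)):
            enriched = kind == "nonsyn" and context == "nonmutator"
            weights = w_nonsyn if enriched else w_syn
            gene_idx = rng.choice(len(genes), size=n_kind, p=weights)
            for gi in gene_idx:
                gene = genes[int(gi)]
                event_no += 1
                eid = f"ev{event_no:06d}"
                pop = pops[int(rng.integers(0, len(pops)))]
                compartment = "core" if is_core[int(gi)] else "flex"
                truth_counts[f"{compartment}_{kind}"] += 1
                category = "snp"
                if kind == "nonsyn" and context == "nonmutator":
                    u = rng.random()
                    cum = np.cumsum(ko_probs)
                    for cat, edge in zip(ko_cats, cum):
                        if u < edge:
                            category = cat
                            break
                base = {
                    "population": pop,
                    "generation": config.generation,
                    "clone_id": f"{pop}_cl1",
                    "gene_id": gene.gene_id,
                    "category": category,
                    "mutator_context": context,
                    "on_line_of_descent": bool(rng.random() < 0.5),
                    "independent_event_id": eid,
                    "codon_from": pd.NA,
                    "codon_to": pd.NA,
                    "residue_index": pd.NA,
                    "length_bp": pd.NA,
                }
                if category == "snp":
                    cf, ct, ri, pos = _sample_snp(
                        gene, rng, kind == "nonsyn", config.code_id
                    )
                    base.update(
                        codon_from=cf, codon_to=ct, residue_index=ri, position=pos
                    )
                elif category == "small_indel":
                    length = int(rng.integers(1, 11))
                    base.update(
                        position=int(rng.integers(gene.start, gene.end + 1)),
                        length_bp=length,
                    )
                elif category == "is_insertion":
                    base.update(
                        position=int(rng.integers(gene.start, gene.end + 1)),
                        length_bp=1443,  # canonical IS150 element span
                    )
                else:  # large_deletion
                    base.update(position=gene.start, length_bp=gene.length_bp + 100)
                rows.append(base)
                if rng.random() < config.duplicate_observation_prob:
                    dup = dict(base)
                    dup["clone_id"] = f"{pop}_cl2"
                    rows.append(dup)

    emit("nonmutator", config.n_nonmutator_events, config.nonsyn_fraction_nonmutator, nonmut_pops)
    emit("mutator", config.n_mutator_events, config.nonsyn_fraction_mutator, mut_pops)

    table = pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS + ["length_bp"])
    truth = {
        "core_enrichment_factor": r,
        "counts": truth_counts,
        "L_core": partition.L_core,
        "L_flex": partition.L_flex,
    }
    return SimulatedMutations(config=config, table=table, truth=truth)


# ---------------------------------------------------------------------------
# essentiality-table simulation

def simulate_essentiality_table(
    config: EssentialitySimConfig, partition: CoreGenomePartition
) -> pd.DataFrame:
    """Per-gene integer essentiality scores (+3 essential .. -4 dispensable)."""
    config.validate()
    rng = _rng(config.seed, _STREAM_ESSENTIALITY)
    scores = np.array(ESSENTIALITY_SCORES)
    frames = []
    for compartment, gene_ids, mu in (
        ("core", sorted(partition.core_gene_ids), config.mu_core),
        ("flexible", sorted(partition.flexible_gene_ids), config.mu_flexible),
    ):
        drawn = rng.choice(scores, size=len(gene_ids), p=config.weights(mu))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "compartment": compartment,
                    "essentiality_score": drawn.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# toy structures

_AXES = [
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (-1.0, 0.0, 0.0),
    (0.0, -1.0, 0.0),
    (0.0, 0.0, -1.0),
]


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    x: float, y: float, z: float, element: str, hetero: bool = False,
) -> str:
    record = "HETATM" if hetero else "ATOM"
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


def simulate_toy_structure(
    planted_min_distances: list[float], seed: int = 0, atoms_per_chain: int = 3
) -> str:
    """PDB text with chains whose minimum distance to chain A is planted.

    Chain A is a single glycine CA at the origin plus decoy atoms placed
    far away off-axis; each partner chain k sits on its own coordinate
    axis with its closest atom exactly ``planted_min_distances[k]`` Å from
    the origin.  Axis-orthogonal placement keeps every partner chain's
    nearest neighbour the chain-A origin atom.  Supports up to 6 partner
    chains; larger requests are geometrically infeasible here and raise.
    """
    if not planted_min_distances:
        raise ValueError("need at least one planted distance")
    if any(d <= 0 for d in planted_min_distances):
        raise ValueError("planted distances must be positive")
    if len(planted_min_distances) > len(_AXES):
        raise ValueError("infeasible geometry: at most 6 partner chains supported")
    _ = _rng(seed, _STREAM_STRUCTURE)  # seed reserved for API stability
    dmax = max(planted_min_distances)
    lines = ["HEADER    SYNTHETIC TOY STRUCTURE"]
    serial = 1
    # chain A: contact atom at origin, decoys far away along (1,1,1)
    lines.append(_pdb_atom_line(serial, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"))
    serial += 1
    far = 2.0 * dmax + 20.0
    for k in range(1, atoms_per_chain):
        t = far + 3.0 * k
        c = t / math.sqrt(3.0)
        lines.append(_pdb_atom_line(serial, "CA", "GLY", "A", 1 + k, c, c, c, "C"))
        serial += 1
    chain_ids = "BCDEFG"
    for ci, d in enumerate(planted_min_distances):
        ax = _AXES[ci]
        chain = chain_ids[ci]
        for k in range(atoms_per_chain):
            t = d + 2.5 * k
            lines.append(
                _pdb_atom_line(
                    serial, "CA", "GLY", chain, k + 1,
                    ax[0] * t, ax[1] * t, ax[2] * t, "C",
                )
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
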