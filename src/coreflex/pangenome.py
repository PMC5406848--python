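"""Core-genome (panortholog) identification.

A panortholog is a single-copy gene with exactly one ortholog in every
genome of a collection.  The pipeline scores all protein pairs between
genomes, keeps reciprocal best hits (RBH), assembles groups that form
one-member-per-genome cliques of the RBH graph, and applies a
best-local-hit guard against recent duplications.  The reference genome's
protein-coding genes are then split into core (panorthologous) and
flexible compartments with their summed coding lengths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import AA_ALPHABET, DEFAULT_CODE_ID, translate_cds

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: CDS coordinates plus sequences.

    Coordinates are 1-based inclusive on the contig; minus-strand genes
    store the reverse-complemented (coding-strand) nucleotide sequence, so
    ``nt_seq`` always reads 5'→3' through the open reading frame.
    """

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_id}: nt_seq length {len(self.nt_seq)} does not "
                f"match coordinates [{self.start}, {self.end}]"
            )
        if len(self.nt_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_cds(
        cls,
        gene_id: str,
        genome_id: str,
        contig: str,
        start: int,
        strand: str,
        nt_seq: str,
        code_id: int = DEFAULT_CODE_ID,
    ) -> "GeneModel":
        """Build a gene model from a coding-strand CDS, translating it."""
        nt_seq = nt_seq.upper()
        return cls(
            gene_id=gene_id,
            genome_id=genome_id,
            contig=contig,
            start=start,
            end=start + len(nt_seq) - 1,
            strand=strand,
            nt_seq=nt_seq,
            aa_seq=translate_cds(nt_seq, code_id),
        )

    def validate_translation(self, code_id: int = DEFAULT_CODE_ID) -> None:
        expected = translate_cds(self.nt_seq, code_id)
        if expected != self.aa_seq:
            raise ValueError(f"{self.gene_id}: aa_seq is not the translation of nt_seq")


@dataclass
class GenomeAnnotation:
    """All gene models of one genome."""

    genome_id: str
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, g in self.genes.items():
            if g.gene_id != gid:
                raise ValueError(f"gene key {gid} != gene_id {g.gene_id}")
            if g.genome_id != self.genome_id:
                raise ValueError(f"{gid}: genome_id mismatch")

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id} in {self.genome_id}")
        if gene.genome_id != self.genome_id:
            raise ValueError(f"{gene.gene_id}: genome_id mismatch")
        self.genes[gene.gene_id] = gene

    @property
    def total_coding_length(self) -> int:
        return sum(g.length_bp for g in self.genes.values())

    def proteins(self) -> dict[str, str]:
        return {gid: g.aa_seq for gid, g in self.genes.items()}


@dataclass(frozen=True)
class SimilarityHit:
    query_gene_id: str
    subject_gene_id: str
    score: float
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity out of [0,1]")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage out of [0,1]")


@dataclass(frozen=True)
class OrthologGroup:
    family_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, gene_id), one per genome
    single_copy: bool = True

    def __post_init__(self) -> None:
        genomes = [g for g, _ in self.members]
        if len(genomes) != len(set(genomes)):
            raise ValueError(f"{self.family_id}: more than one member per genome")

    def member_map(self) -> dict[str, str]:
        return dict(self.members)


@dataclass
class CoreGenomePartition:
    """Core vs. flexible split of a reference genome's coding sequence."""

    reference_genome_id: str
    core_gene_ids: frozenset[str]
    flexible_gene_ids: frozenset[str]
    L_core: int
    L_flex: int

    def __post_init__(self) -> None:
        if self.core_gene_ids & self.flexible_gene_ids:
            raise ValueError("core and flexible sets overlap")

    @property
    def core_fraction(self) -> float:
        """Core share of the total coding length (dimensionless)."""
        return self.L_core / (self.L_core + self.L_flex)

    def compartment_of(self, gene_id: str) -> str:
        if gene_id in self.core_gene_ids:
            return "core"
        if gene_id in self.flexible_gene_ids:
            return "flexible"
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# similarity scoring

@dataclass(frozen=True)
class ScorerConfig:
    """Banded-global-alignment similarity scorer settings.

    identity = matching columns / alignment columns; coverage = query
    residues aligned against subject residues / query length.
    """

    matrix: str = "BLOSUM62"
    open_gap_score: float = -11.0
    extend_gap_score: float = -1.0
    min_identity: float = 0.5
    min_coverage: float = 0.5


def make_aligner(config: ScorerConfig | None = None) -> Align.PairwiseAligner:
    config = config or ScorerConfig()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = config.open_gap_score
    aligner.extend_gap_score = config.extend_gap_score
    return aligner


def _alignment_stats(aln) -> tuple[float, float, int]:
    """(identity, aligned query residue count, n_columns) for one alignment."""
    a, b = str(aln[0]), str(aln[1])
    n_cols = len(a)
    matches = 0
    aligned_query = 0
    for ca, cb in zip(a, b):
        if ca != "-" and cb != "-":
            aligned_query += 1
            if ca == cb:
                matches += 1
    return matches / n_cols if n_cols else 0.0, aligned_query, n_cols


def score_pair(
    query: str, subject: str, aligner: Align.PairwiseAligner
) -> tuple[float, float, float]:
    """Align one protein pair; return (score, identity, coverage)."""
    aln = aligner.align(query, subject)[0]
    identity, aligned_query, _ = _alignment_stats(aln)
    coverage = aligned_query / len(query) if query else 0.0
    return float(aln.score), identity, coverage


def score_all_pairs(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    config: ScorerConfig | None = None,
) -> list[SimilarityHit]:
    """All query-vs-subject similarity hits above the configured thresholds.

    Hits are grouped per query and sorted by descending score (subject id
    breaks exact ties), so the result is deterministic for fixed inputs.
    Records with non-residue characters are rejected with a warning.
    """
    config = config or ScorerConfig()
    aligner = make_aligner(config)

    def clean(proteins: dict[str, str]) -> dict[str, str]:
        ok = {}
        for gid, seq in proteins.items():
            if not seq or any(ch not in AA_ALPHABET for ch in seq):
                logger.warning("rejecting %s: invalid residue characters", gid)
                continue
            ok[gid] = seq
        return ok

    proteins_a = clean(proteins_a)
    proteins_b = clean(proteins_b)
    hits: list[SimilarityHit] = []
    for qid in sorted(proteins_a):
        query_hits = []
        for sid in sorted(proteins_b):
            score, identity, coverage = score_pair(proteins_a[qid], proteins_b[sid], aligner)
            if identity >= config.min_identity and coverage >= config.min_coverage:
                query_hits.append(SimilarityHit(qid, sid, score, identity, coverage))
        query_hits.sort(key=lambda h: (-h.score, h.subject_gene_id))
        hits.extend(query_hits)
    return hits


# ---------------------------------------------------------------------------
# reciprocal best hits and panortholog groups

def _best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit | None]:
    """Per query, the unique top-scoring hit, or None on a score tie."""
    best: dict[str, SimilarityHit | None] = {}
    top_score: dict[str, float] = {}
    for h in hits:
        if h.query_gene_id not in best:
            best[h.query_gene_id] = h
            top_score[h.query_gene_id] = h.score
        elif h.score == top_score[h.query_gene_id]:
            best[h.query_gene_id] = None  # tie for the top disqualifies
    return best


def reciprocal_best_hits(
    hits_ab: list[SimilarityHit], hits_ba: list[SimilarityHit]
) -> set[tuple[str, str]]:
    """(a, b) pairs where each gene is the other's unique best hit.

    A tie for the top score on either side disqualifies the query — a
    conservative guard against recent gene duplications.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = set()
    for a, hit in best_ab.items():
        if hit is None:
            continue
        back = best_ba.get(hit.subject_gene_id)
        if back is not None and back.subject_gene_id == a:
            pairs.add((a, hit.subject_gene_id))
    return pairs


def _pair_key(g1: str, g2: str) -> tuple[str, str]:
    return (g1, g2) if g1 <= g2 else (g2, g1)


def build_panortholog_set(
    genome_ids: list[str],
    rbh_by_pair: dict[tuple[str, str], set[tuple[str, str]]],
    hits_by_pair: dict[tuple[str, str], list[SimilarityHit]] | None = None,
) -> list[OrthologGroup]:
    """Assemble panortholog groups from pairwise RBH sets.

    ``rbh_by_pair`` is keyed by an ordered genome pair (gA, gB) with pairs
    (gene_in_gA, gene_in_gB); either key order is accepted.  Groups are the
    connected components of the RBH graph that contain exactly one gene
    from every genome and form a clique across all genome pairs.  When
    ``hits_by_pair`` is given (same keying; a (g, g) key carries
    within-genome hits), the best-local-hit guard additionally discards any
    group with a member whose hit to a non-partner gene — in another genome
    or its own — outscores its hit to the group partner.
    """
    genome_ids = sorted(set(genome_ids))
    n = len(genome_ids)
    if n < 2:
        raise ValueError("need at least two genomes")

    # normalise RBH keys to sorted genome order
    rbh: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for (g1, g2), pairs in rbh_by_pair.items():
        if g1 <= g2:
            rbh.setdefault((g1, g2), set()).update(pairs)
        else:
            rbh.setdefault((g2, g1), set()).update((b, a) for a, b in pairs)
    for g1, g2 in itertools.combinations(genome_ids, 2):
        if (g1, g2) not in rbh:
            raise ValueError(f"missing RBH set for genome pair ({g1}, {g2})")

    # hit score lookup: (query_genome, subject_genome) -> query gene -> hits
    score_of: dict[tuple[str, str, str, str], float] = {}
    hits_from: dict[tuple[str, str], dict[str, list[SimilarityHit]]] = {}
    if hits_by_pair:
        for (gq, gs), hits in hits_by_pair.items():
            byq = hits_from.setdefault((gq, gs), {})
            for h in hits:
                byq.setdefault(h.query_gene_id, []).append(h)
                score_of[(gq, gs, h.query_gene_id, h.subject_gene_id)] = h.score

    # union-find over (genome, gene) nodes
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    edge_set: set[frozenset[tuple[str, str]]] = set()
    for (g1, g2), pairs in rbh.items():
        for a, b in pairs:
            na, nb = (g1, a), (g2, b)
            union(na, nb)
            edge_set.add(frozenset((na, nb)))

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    groups: list[OrthologGroup] = []
    for comp in components.values():
        genomes_in = [g for g, _ in comp]
        if len(comp) != n or sorted(genomes_in) != genome_ids:
            continue  # missing genome or multi-copy
        by_genome = dict(comp)
        # clique requirement: every genome pair connected by an RBH edge
        if not all(
            frozenset(((g1, by_genome[g1]), (g2, by_genome[g2]))) in edge_set
            for g1, g2 in itertools.combinations(genome_ids, 2)
        ):
            continue
        if hits_by_pair and not _passes_best_hit_guard(
            by_genome, genome_ids, score_of, hits_from
        ):
            continue
        members = tuple(sorted(by_genome.items()))
        groups.append(OrthologGroup(family_id="", members=members))

    groups.sort(key=lambda g: g.members)
    return [
        OrthologGroup(family_id=f"fam{i:05d}", members=g.members)
        for i, g in enumerate(groups, start=1)
    ]


def _passes_best_hit_guard(by_genome, genome_ids, score_of, hits_from) -> bool:
    """No member may have a better hit anywhere than its group partners."""
    for gq in genome_ids:
        gene_q = by_genome[gq]
        partner_scores = []
        for gs in genome_ids:
            if gs == gq:
                continue
            s = score_of.get((gq, gs, gene_q, by_genome[gs]))
            if s is None:
                continue
            partner_scores.append(s)
            for h in hits_from.get((gq, gs), {}).get(gene_q, []):
                if h.subject_gene_id != by_genome[gs] and h.score > s:
                    return False
        if partner_scores:
            floor = min(partner_scores)
            for h in hits_from.get((gq, gq), {}).get(gene_q, []):
                if h.subject_gene_id != gene_q and h.score > floor:
                    return False
    return True


def classify_core_flexible(
    reference_annotation: GenomeAnnotation,
    panortholog_groups: list[OrthologGroup],
) -> CoreGenomePartition:
    """Split the reference genome's genes into core and flexible compartments."""
    ref = reference_annotation.genome_id
    if not reference_annotation.genes:
        raise ValueError(f"reference genome {ref} has no genes")
    core_ids = set()
    for grp in panortholog_groups:
        members = grp.member_map()
        if ref not in members:
            continue
        gid = members[ref]
        if gid not in reference_annotation.genes:
            raise ValueError(
                f"group {grp.family_id} names unknown reference gene {gid}"
            )
        core_ids.add(gid)
    flex_ids = set(reference_annotation.genes) - core_ids
    L_core = sum(reference_annotation.genes[g].length_bp for g in core_ids)
    L_flex = sum(reference_annotation.genes[g].length_bp for g in flex_ids)
    return CoreGenomePartition(
        reference_genome_id=ref,
        core_gene_ids=frozenset(core_ids),
        flexible_gene_ids=frozenset(flex_ids),
        L_core=L_core,
        L_flex=L_flex,
    )


# ---------------------------------------------------------------------------
# two-genome (interspecies) one-to-one calls

def one_to_one_interspecies(
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    config: ScorerConfig | None = None,
) -> set[tuple[str, str]]:
    """One-to-one ortholog pairs between two genomes by the RBH rule."""
    hits_ab = score_all_pairs(annot_a.proteins(), annot_b.proteins(), config)
    hits_ba = score_all_pairs(annot_b.proteins(), annot_a.proteins(), config)
    return reciprocal_best_hits(hits_ab, hits_ba)


def intersect_ortholog_calls(
    pairs_1: set[tuple[str, str]], pairs_2: set[tuple[str, str]]
) -> set[tuple[str, str]]:
    """Consensus pairs present in both call sets."""
    return set(pairs_1) & set(pairs_2)
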