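"""Classification and counting of experimental-evolution mutations.

Covers synonymous/nonsynonymous SNP classification (nonsense mutations are
reported distinctly but tallied as nonsynonymous), Nei–Gojobori-style
synonymous/nonsynonymous site counting, potential-knockout flags
(frameshifting small indels, IS-element insertions, large deletions), and
per-compartment mutation tallies against a core/flexible partition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .genetics import (
    DEFAULT_CODE_ID,
    codon_neighbors,
    translate_codon,
    validate_codon,
)
from .pangenome import CoreGenomePartition, GeneModel

MUTATION_TABLE_COLUMNS = [
    "population",
    "generation",
    "clone_id",
    "gene_id",
    "position",
    "category",
    "codon_from",
    "codon_to",
    "residue_index",
    "mutator_context",
    "on_line_of_descent",
    "independent_event_id",
]

CATEGORIES = {"snp", "small_indel", "is_insertion", "large_deletion", "other"}
MUTATOR_CONTEXTS = {"nonmutator", "mutator"}


class SnpClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE_AS_NONSYNONYMOUS = "nonsense_as_nonsynonymous"

    @property
    def counts_as_nonsynonymous(self) -> bool:
        return self is not SnpClass.SYNONYMOUS


@dataclass(frozen=True)
class MutationRecord:
    """One observed mutation in one sequenced clone."""

    population: str
    generation: int
    clone_id: str
    gene_id: str | None  # None marks an intergenic record
    position: int
    category: str
    mutator_context: str
    independent_event_id: str
    codon_from: str | None = None
    codon_to: str | None = None
    residue_index: int | None = None
    on_line_of_descent: bool = False
    length_bp: int | None = None  # indel/deletion span

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.mutator_context not in MUTATOR_CONTEXTS:
            raise ValueError(f"unknown mutator_context {self.mutator_context!r}")
        if self.category == "snp":
            if not (self.codon_from and self.codon_to and self.residue_index):
                raise ValueError("snp records need codon_from/codon_to/residue_index")
            if self.codon_from == self.codon_to:
                raise ValueError("snp with identical codons")


@dataclass(frozen=True)
class SiteCounts:
    """Fractional nonsynonymous/synonymous site counts for one gene."""

    gene_id: str
    n_codons: int
    nonsyn_sites: float
    syn_sites: float

    def __post_init__(self) -> None:
        if not math.isclose(
            self.nonsyn_sites + self.syn_sites, 3 * self.n_codons, abs_tol=1e-9
        ):
            raise ValueError("nonsyn_sites + syn_sites != 3 * n_codons")


@dataclass(frozen=True)
class KnockoutFlag:
    gene_id: str
    is_potential_knockout: bool
    reason: str  # small_indel | is_insertion | large_deletion | none
    near_terminal: bool = False
    distance_to_stop_codons: int | None = None

    def __post_init__(self) -> None:
        if (self.reason == "none") != (not self.is_potential_knockout):
            raise ValueError("reason must be 'none' iff flag is false")


# ---------------------------------------------------------------------------
# SNP classification and site counting

def classify_snp(
    codon_from: str, codon_to: str, code_id: int = DEFAULT_CODE_ID
) -> SnpClass:
    """Synonymous / nonsynonymous / nonsense-as-nonsynonymous for one codon change."""
    codon_from = validate_codon(codon_from)
    codon_to = validate_codon(codon_to)
    if codon_from == codon_to:
        raise ValueError("codons are identical")
    aa_from = translate_codon(codon_from, code_id)
    aa_to = translate_codon(codon_to, code_id)
    if aa_from == "*":
        raise ValueError(f"codon_from {codon_from} is a stop codon")
    if aa_to == "*":
        return SnpClass.NONSENSE_AS_NONSYNONYMOUS
    if aa_from == aa_to:
        return SnpClass.SYNONYMOUS
    return SnpClass.NONSYNONYMOUS


def codon_site_counts(codon: str, code_id: int = DEFAULT_CODE_ID) -> tuple[float, float]:
    """(nonsyn_sites, syn_sites) for one codon, equal-weight convention.

    Each of the 9 single-nucleotide changes contributes 1/3 of a site;
    stop-creating changes count as nonsynonymous, consistent with tallying
    nonsense mutations as nonsynonymous.
    """
    syn = 0
    for neighbor in codon_neighbors(codon):
        if classify_snp(codon, neighbor, code_id) is SnpClass.SYNONYMOUS:
            syn += 1
    return (9 - syn) / 3.0, syn / 3.0


def count_syn_nonsyn_sites(
    nt_seq: str, gene_id: str = "", code_id: int = DEFAULT_CODE_ID
) -> SiteCounts:
    """Per-gene fractional site counts over all coding codons.

    A trailing stop codon is excluded; an internal stop or a trailing
    partial codon is an error.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length not divisible by 3")
    codons = [nt_seq[i : i + 3] for i in range(0, len(nt_seq), 3)]
    if codons and translate_codon(codons[-1], code_id) == "*":
        codons = codons[:-1]
    nonsyn = syn = 0.0
    for i, codon in enumerate(codons):
        if translate_codon(codon, code_id) == "*":
            raise ValueError(f"{gene_id}: internal stop codon at codon {i + 1}")
        n, s = codon_site_counts(codon, code_id)
        nonsyn += n
        syn += s
    return SiteCounts(gene_id=gene_id, n_codons=len(codons), nonsyn_sites=nonsyn, syn_sites=syn)


def site_ratio(counts: list[SiteCounts]) -> float:
    """Genome-wide nonsynonymous-to-synonymous site ratio over a gene set."""
    total_n = sum(c.nonsyn_sites for c in counts)
    total_s = sum(c.syn_sites for c in counts)
    if total_s <= 0:
        raise ValueError("no synonymous sites in gene set")
    return total_n / total_s


# ---------------------------------------------------------------------------
# knockout flagging

def flag_potential_knockout(
    record: MutationRecord,
    gene: GeneModel,
    small_indel_max_bp: int = 50,
    near_terminal_codons: int = 5,
) -> KnockoutFlag:
    """Flag likely loss-of-function events for one mutation record.

    Small indels whose length is not a multiple of 3 (reading-frame
    disruption), IS-element insertions, and large deletions overlapping the
    gene all flag as potential knockouts.  Events within
    ``near_terminal_codons`` of the stop codon additionally set
    ``near_terminal`` — a frameshift in the final codons may leave the
    protein functional.
    """
    if record.gene_id != gene.gene_id:
        raise ValueError("record is not mapped to this gene")

    def dist_to_stop(pos: int) -> int:
        if gene.strand == "+":
            return max(0, (gene.end - pos) // 3)
        return max(0, (pos - gene.start) // 3)

    reason = "none"
    if record.category == "small_indel":
        length = record.length_bp or 0
        if length % 3 != 0:
            reason = "small_indel"
    elif record.category == "is_insertion":
        reason = "is_insertion"
    elif record.category == "large_deletion":
        length = record.length_bp or 0
        del_start, del_end = record.position, record.position + max(length - 1, 0)
        if del_end < gene.start or del_start > gene.end:
            raise ValueError(
                f"{record.independent_event_id}: deletion "
                f"[{del_start}, {del_end}] does not overlap gene {gene.gene_id}"
            )
        reason = "large_deletion"

    flagged = reason != "none"
    d = dist_to_stop(record.position) if flagged else None
    return KnockoutFlag(
        gene_id=gene.gene_id,
        is_potential_knockout=flagged,
        reason=reason,
        near_terminal=flagged and d is not None and d <= near_terminal_codons,
        distance_to_stop_codons=d,
    )


# ---------------------------------------------------------------------------
# table-level operations

def annotate_mutation_table(
    table: pd.DataFrame, code_id: int = DEFAULT_CODE_ID
) -> pd.DataFrame:
    """Add a ``snp_class`` column (NA for non-SNP records)."""
    out = table.copy()

    def classify(row):
        if row["category"] != "snp":
            return pd.NA
        return classify_snp(row["codon_from"], row["codon_to"], code_id).value

    out["snp_class"] = out.apply(classify, axis=1)
    return out


def tabulate_compartment_counts(
    table: pd.DataFrame,
    partition: CoreGenomePartition,
    mutator_context: str | None = None,
    snp_class: str | None = None,
) -> tuple[int, int]:
    """(core_count, flexible_count) of mutations passing the filters.

    ``snp_class`` of 'nonsynonymous' includes nonsense records (tallied as
    nonsynonymous throughout); intergenic records are excluded.  Every
    counted gene must carry a compartment label.
    """
    df = table[table["gene_id"].notna()]
    if mutator_context is not None:
        df = df[df["mutator_context"] == mutator_context]
    if snp_class is not None:
        if "snp_class" not in df.columns:
            raise ValueError("table lacks snp_class; run annotate_mutation_table first")
        if snp_class == "nonsynonymous":
            keep = {"nonsynonymous", "nonsense_as_nonsynonymous"}
        else:
            keep = {snp_class}
        df = df[df["snp_class"].isin(keep)]
    labeled = set(partition.core_gene_ids) | set(partition.flexible_gene_ids)
    unknown = sorted(set(df["gene_id"]) - labeled)
    if unknown:
        raise ValueError(f"genes without compartment label: {unknown}")
    core = int(df["gene_id"].isin(partition.core_gene_ids).sum())
    flex = len(df) - core
    return core, flex


def independent_event_collapse(table: pd.DataFrame) -> pd.DataFrame:
    """One row per independent mutational event.

    Repeated observations of one event (same ``independent_event_id``)
    collapse to the first record, with the observation count retained in an
    ``n_observations`` column.  Conflicting gene assignments within one
    event id are an error.
    """
    if table["independent_event_id"].isna().any():
        raise ValueError("independent_event_id must be populated for all records")
    for eid, grp in table.groupby("independent_event_id"):
        genes = grp["gene_id"].fillna("__intergenic__").unique()
        if len(genes) > 1:
            raise ValueError(
                f"event {eid} has conflicting gene assignments: {sorted(genes)}"
            )
    counts = table.groupby("independent_event_id").size()
    collapsed = table.drop_duplicates("independent_event_id", keep="first").copy()
    collapsed["n_observations"] = collapsed["independent_event_id"].map(counts).astype(int)
    return collapsed.reset_index(drop=True)
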