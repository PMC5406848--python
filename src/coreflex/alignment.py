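"""Protein family alignment and amino-acid diversity/divergence.

Implements an amino-acid analogue of Nei's nucleotide diversity: the mean
number of pairwise differences per site over all unordered sequence pairs
of a family alignment.  Gap conventions follow the indel rule used for the
diversity metric: a residue aligned against a gap counts as a difference
at that column (so a 10-residue indel contributes 10 differences), columns
where both members of a pair are gapped are skipped for that pair, and
each pair is normalised by its own number of compared columns before
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genetics import AA_ALPHABET, GAP
from .pangenome import ScorerConfig, make_aligner

# alignments may carry IUPAC ambiguity codes; aligner input stays strict
AA_EXTENDED = AA_ALPHABET | set("BJOUXZ")

__all__ = [
    "ProteinAlignment",
    "DiversityRecord",
    "SitePartitionDiversity",
    "DivergenceRecord",
    "align_family",
    "pairwise_aa_diversity",
    "partition_site_diversity",
    "map_residue_to_column",
    "pairwise_divergence",
]


@dataclass
class ProteinAlignment:
    """A multiple alignment of one protein family (rows keyed by genome)."""

    family_id: str
    rows: dict[str, str]
    n_columns: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.family_id}: rows have unequal lengths {lengths}")
        (n,) = lengths
        if self.n_columns and self.n_columns != n:
            raise ValueError(f"{self.family_id}: n_columns mismatch")
        self.n_columns = n
        for rid, row in self.rows.items():
            bad = set(row) - AA_EXTENDED - {GAP}
            if bad:
                raise ValueError(f"{self.family_id}/{rid}: invalid symbols {bad}")

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "")

    def matrix(self) -> tuple[list[str], np.ndarray]:
        """Row ids (sorted) and the alignment as a uint8 character matrix."""
        ids = sorted(self.rows)
        mat = np.frombuffer(
            "".join(self.rows[i] for i in ids).encode("ascii"), dtype=np.uint8
        ).reshape(len(ids), self.n_columns)
        return ids, mat


@dataclass(frozen=True)
class DiversityRecord:
    gene_id: str
    n_seqs: int
    n_pairs: int
    pi_aa: float
    per_column_diff_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_pairs != self.n_seqs * (self.n_seqs - 1) // 2:
            raise ValueError("n_pairs != n_seqs*(n_seqs-1)/2")
        if self.pi_aa < 0:
            raise ValueError("pi_aa < 0")


@dataclass(frozen=True)
class SitePartitionDiversity:
    gene_id: str
    target_columns: tuple[int, ...]  # 1-based alignment columns
    pi_target: float
    pi_rest: float
    n_target_sites: int


@dataclass(frozen=True)
class DivergenceRecord:
    gene_id: str
    aligned_length: int  # columns compared (gap-gap excluded)
    n_diff: int
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0):
            raise ValueError("d out of [0,1]")


# ---------------------------------------------------------------------------
# alignment construction

def _validate_protein(seq_id: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{seq_id}: empty sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{seq_id}: non-residue characters {bad}")


def _center_gap_runs(center_aln: str) -> dict[int, int]:
    """Gap-run lengths in the aligned center row, keyed by the number of
    center residues consumed before the run."""
    runs: dict[int, int] = {}
    consumed = 0
    run = 0
    for ch in center_aln:
        if ch == GAP:
            run += 1
        else:
            if run:
                runs[consumed] = run
                run = 0
            consumed += 1
    if run:
        runs[consumed] = run
    return runs


def _expand_row(center_aln: str, row_aln: str, master: dict[int, int], n_center: int) -> str:
    """Re-pad a pairwise row to the master gap pattern of the center."""
    out: list[str] = []
    j = 0
    total = len(center_aln)
    for i in range(n_center + 1):
        run: list[str] = []
        while j < total and center_aln[j] == GAP:
            run.append(row_aln[j])
            j += 1
        need = master.get(i, 0)
        out.extend(run)
        out.append(GAP * (need - len(run)))
        if i < n_center:
            out.append(row_aln[j])
            j += 1
    return "".join(out)


def align_family(
    sequences: dict[str, str],
    family_id: str = "",
    scorer: ScorerConfig | None = None,
) -> ProteinAlignment:
    """Progressive (center-star) global alignment of a protein family.

    The center sequence is the one with the highest summed pairwise
    alignment score against the others (for ≤ 12 sequences; beyond that,
    the longest sequence, ties broken by id).  Every other sequence is
    aligned to the center and the pairwise gap patterns are merged
    ("once a gap, always a gap").  Deterministic for fixed inputs.
    """
    if len(sequences) < 2:
        raise ValueError("align_family requires at least 2 sequences")
    for sid, seq in sequences.items():
        _validate_protein(sid, seq)

    scorer = scorer or ScorerConfig(open_gap_score=-10.0, extend_gap_score=-0.5)
    aligner = make_aligner(scorer)
    ids = sorted(sequences)

    if len(set(sequences.values())) == 1:
        return ProteinAlignment(family_id, dict(sequences))

    if len(ids) <= 12:
        totals = {
            i: sum(
                aligner.score(sequences[i], sequences[j]) for j in ids if j != i
            )
            for i in ids
        }
        center_id = max(ids, key=lambda i: (totals[i], i))
    else:
        center_id = max(ids, key=lambda i: (len(sequences[i]), i))

    center = sequences[center_id]
    pairwise: dict[str, tuple[str, str]] = {}
    master: dict[int, int] = {}
    for sid in ids:
        if sid == center_id:
            continue
        aln = aligner.align(center, sequences[sid])[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        pairwise[sid] = (c_aln, s_aln)
        for pos, cnt in _center_gap_runs(c_aln).items():
            master[pos] = max(master.get(pos, 0), cnt)

    n_center = len(center)
    rows: dict[str, str] = {}
    # center row under the master gap pattern
    center_cols: list[str] = []
    for i in range(n_center + 1):
        center_cols.append(GAP * master.get(i, 0))
        if i < n_center:
            center_cols.append(center[i])
    rows[center_id] = "".join(center_cols)
    for sid, (c_aln, s_aln) in pairwise.items():
        rows[sid] = _expand_row(c_aln, s_aln, master, n_center)

    aln_out = ProteinAlignment(family_id, rows)
    for sid in ids:
        if aln_out.ungapped(sid) != sequences[sid]:
            raise AssertionError(f"{family_id}/{sid}: ungapping does not round-trip")
    return aln_out


def load_prealigned(rows: dict[str, str], family_id: str = "") -> ProteinAlignment:
    """Wrap pre-computed aligned rows, validating lengths and symbols."""
    return ProteinAlignment(family_id, dict(rows))


# ---------------------------------------------------------------------------
# diversity / divergence

_GAP_BYTE = ord(GAP)


def _pair_diff_counts(
    row_a: np.ndarray, row_b: np.ndarray, columns: np.ndarray | None = None
) -> tuple[int, int, np.ndarray]:
    """(n_differences, n_compared_columns, per-column diff mask) for a pair."""
    if columns is not None:
        row_a = row_a[columns]
        row_b = row_b[columns]
    compared = ~((row_a == _GAP_BYTE) & (row_b == _GAP_BYTE))
    diffs = compared & (row_a != row_b)
    return int(diffs.sum()), int(compared.sum()), diffs


def pairwise_aa_diversity(alignment: ProteinAlignment) -> DiversityRecord:
    """Mean pairwise amino-acid differences per site over all pairs.

    Residue-vs-gap columns count as differences; gap-vs-gap columns are
    skipped for that pair; each pair is normalised by its own compared
    column count, then averaged over all n(n-1)/2 pairs.
    """
    ids, mat = alignment.matrix()
    n = len(ids)
    if n < 2:
        raise ValueError("diversity needs at least 2 sequences")
    per_pair = []
    col_counts = np.zeros(alignment.n_columns, dtype=int)
    for i, j in combinations(range(n), 2):
        n_diff, n_comp, diffs = _pair_diff_counts(mat[i], mat[j])
        if n_comp == 0:
            raise ValueError(
                f"pair ({ids[i]}, {ids[j]}) shares no compared columns"
            )
        per_pair.append(n_diff / n_comp)
        col_counts += diffs
    return DiversityRecord(
        gene_id=alignment.family_id,
        n_seqs=n,
        n_pairs=len(per_pair),
        pi_aa=float(np.mean(per_pair)),
        per_column_diff_counts=tuple(int(c) for c in col_counts),
    )


def _restricted_pi(mat: np.ndarray, ids: list[str], columns: np.ndarray) -> float:
    per_pair = []
    for i, j in combinations(range(len(ids)), 2):
        n_diff, n_comp, _ = _pair_diff_counts(mat[i], mat[j], columns)
        if n_comp == 0:
            continue  # pair contributes nothing on this column subset
        per_pair.append(n_diff / n_comp)
    return float(np.mean(per_pair)) if per_pair else 0.0


def partition_site_diversity(
    alignment: ProteinAlignment, target_columns: list[int]
) -> SitePartitionDiversity:
    """Diversity at target alignment columns (1-based) vs. the rest."""
    if not target_columns:
        raise ValueError("target_columns is empty")
    tset = sorted(set(target_columns))
    if tset[0] < 1 or tset[-1] > alignment.n_columns:
        raise ValueError(
            f"target column out of range 1..{alignment.n_columns}: {tset}"
        )
    ids, mat = alignment.matrix()
    target_idx = np.array([c - 1 for c in tset], dtype=int)
    rest_idx = np.array(
        [c for c in range(alignment.n_columns) if c + 1 not in set(tset)], dtype=int
    )
    pi_target = _restricted_pi(mat, ids, target_idx)
    pi_rest = _restricted_pi(mat, ids, rest_idx) if rest_idx.size else 0.0
    return SitePartitionDiversity(
        gene_id=alignment.family_id,
        target_columns=tuple(tset),
        pi_target=pi_target,
        pi_rest=pi_rest,
        n_target_sites=len(tset),
    )


def map_residue_to_column(
    alignment: ProteinAlignment, row_id: str, residue_index: int
) -> int:
    """Alignment column (1-based) holding the row's residue_index-th residue."""
    row = alignment.rows[row_id]
    if residue_index < 1:
        raise ValueError("residue_index is 1-based")
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == residue_index:
                return col
    raise ValueError(
        f"{row_id}: residue index {residue_index} beyond ungapped length {seen}"
    )


def pairwise_divergence(alignment: ProteinAlignment) -> DivergenceRecord:
    """Proportion of differing residues between a two-row alignment."""
    ids, mat = alignment.matrix()
    if len(ids) != 2:
        raise ValueError("pairwise_divergence needs exactly 2 rows")
    n_diff, n_comp, _ = _pair_diff_counts(mat[0], mat[1])
    if n_comp == 0:
        raise ValueError(f"pair ({ids[0]}, {ids[1]}) shares no compared columns")
    return DivergenceRecord(
        gene_id=alignment.family_id,
        aligned_length=n_comp,
        n_diff=n_diff,
        d=n_diff / n_comp,
    )
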