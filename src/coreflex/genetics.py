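"""Genetic-code helpers shared across modules.

The bacterial/archaeal code (NCBI translation table 11) is the default
everywhere; alternative start codons (GTG, TTG) are translated as Met when
they open a CDS, as is standard for bacterial gene products.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

DEFAULT_CODE_ID = 11


@lru_cache(maxsize=None)
def _table(code_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


@lru_cache(maxsize=None)
def stop_codons(code_id: int = DEFAULT_CODE_ID) -> frozenset[str]:
    return frozenset(_table(code_id).stop_codons)


@lru_cache(maxsize=None)
def sense_codons(code_id: int = DEFAULT_CODE_ID) -> tuple[str, ...]:
    """All non-stop codons, in a fixed deterministic order."""
    stops = stop_codons(code_id)
    return tuple(
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if a + b + c not in stops
    )


def validate_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(ch not in NUCLEOTIDES for ch in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return codon


def translate_codon(codon: str, code_id: int = DEFAULT_CODE_ID) -> str:
    """Translate one codon; returns '*' for a stop codon."""
    codon = validate_codon(codon)
    if codon in stop_codons(code_id):
        return "*"
    return _table(code_id).forward_table[codon]


def is_stop(codon: str, code_id: int = DEFAULT_CODE_ID) -> bool:
    return validate_codon(codon) in stop_codons(code_id)


def translate_cds(nt_seq: str, code_id: int = DEFAULT_CODE_ID) -> str:
    """Translate a CDS to its protein sequence.

    The trailing stop codon, if present, is dropped; a leading alternative
    start codon (GTG/TTG) translates as M. Internal stops raise ValueError.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"CDS length {len(nt_seq)} not divisible by 3")
    codons = [nt_seq[i : i + 3] for i in range(0, len(nt_seq), 3)]
    if codons and codons[-1] in stop_codons(code_id):
        codons = codons[:-1]
    aas = []
    for i, codon in enumerate(codons):
        aa = translate_codon(codon, code_id)
        if aa == "*":
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        aas.append(aa)
    if aas and codons[0] in _table(code_id).start_codons:
        aas[0] = "M"
    return "".join(aas)


def codon_neighbors(codon: str) -> list[str]:
    """The 9 codons reachable by a single-nucleotide change."""
    codon = validate_codon(codon)
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out
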