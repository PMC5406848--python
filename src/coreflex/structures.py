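"""Mapping mutated residues onto protein structures.

A mutated residue is interface-proximal when any of its atoms lies within
a distance threshold (8.0 Å by default, inclusive) of an atom belonging to
another chain — protein or nucleic acid — or to a bound ligand.  All atoms
present in the file are used; waters are dropped at load time, the first
alternate conformation is kept, and ions count as ligands.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

DEFAULT_CONTACT_THRESHOLD = 8.0

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_NUCLEIC_NAMES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    is_hetero: bool
    altloc: str


@dataclass
class StructureModel:
    structure_id: str
    atoms: list[AtomRecord]
    chain_kind: dict[str, str]  # chain_id -> protein | nucleic | ligand

    def coords(self) -> np.ndarray:
        return np.array([(a.x, a.y, a.z) for a in self.atoms], dtype=float)

    def atoms_of_residue(self, chain_id: str, residue_number: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]


@dataclass(frozen=True)
class ContactResult:
    query_residue: int
    target_chain: str
    target_residue: int
    partner_chain: str
    partner_residue: int
    partner_kind: str
    min_distance: float
    threshold: float
    within_threshold: bool


def _residue_kind(residue_name: str, is_hetero: bool) -> str:
    if residue_name in _AA3 and not is_hetero:
        return "protein"
    if residue_name in _NUCLEIC_NAMES and not is_hetero:
        return "nucleic"
    return "ligand"


def _validate_pdb_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"line {lineno}: truncated ATOM/HETATM record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                ) from None


def parse_structure(pdb_text: str, structure_id: str = "") -> StructureModel:
    """Parse fixed-column PDB text into a StructureModel.

    Waters are dropped, the first alternate location of each atom is kept,
    and chains are typed protein/nucleic/ligand from their residue content
    (any hetero-only chain is a ligand).
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    st.remove_alternative_conformations()
    atoms: list[AtomRecord] = []
    chain_residue_kinds: dict[str, set[str]] = {}
    for model in st:
        for chain in model:
            for residue in chain:
                if residue.name in _WATER_NAMES:
                    continue
                is_het = residue.het_flag == "H"
                kind = _residue_kind(residue.name, is_het)
                chain_residue_kinds.setdefault(chain.name, set()).add(kind)
                for atom in residue:
                    atoms.append(
                        AtomRecord(
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            insertion_code=residue.seqid.icode.strip(),
                            residue_name=residue.name,
                            atom_name=atom.name,
                            element=atom.element.name,
                            x=atom.pos.x,
                            y=atom.pos.y,
                            z=atom.pos.z,
                            is_hetero=is_het,
                            altloc=atom.altloc,
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError("no atoms parsed from PDB text")
    chain_kind = {}
    for cid, kinds in chain_residue_kinds.items():
        if "protein" in kinds:
            chain_kind[cid] = "protein"
        elif "nucleic" in kinds:
            chain_kind[cid] = "nucleic"
        else:
            chain_kind[cid] = "ligand"
    return StructureModel(structure_id=structure_id, atoms=atoms, chain_kind=chain_kind)


# ---------------------------------------------------------------------------
# residue mapping

@dataclass
class ResidueMapping:
    """Query-residue to structure-residue mapping from a two-row alignment.

    Built from an aligned (query, chain) sequence pair plus the chain's
    author residue numbering in sequence order.  Query residues aligned
    opposite a gap are explicitly unmapped (map to None).
    """

    chain_id: str
    query_to_structure: dict[int, int]

    @classmethod
    def from_alignment(
        cls,
        query_aln: str,
        chain_aln: str,
        chain_id: str,
        chain_residue_numbers: list[int] | None = None,
    ) -> "ResidueMapping":
        if len(query_aln) != len(chain_aln):
            raise ValueError("alignment rows have unequal lengths")
        mapping: dict[int, int] = {}
        qi = si = 0
        for qc, sc in zip(query_aln, chain_aln):
            q_res = qc != "-"
            s_res = sc != "-"
            if q_res:
                qi += 1
            if s_res:
                si += 1
            if q_res and s_res:
                num = chain_residue_numbers[si - 1] if chain_residue_numbers else si
                mapping[qi] = num
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("residue mapping is not injective")
        return cls(chain_id=chain_id, query_to_structure=mapping)

    def map_residue(self, query_residue_index: int) -> tuple[str, int] | None:
        """(chain_id, residue_number), or None when the residue is unaligned."""
        num = self.query_to_structure.get(query_residue_index)
        return None if num is None else (self.chain_id, num)


def map_residue(
    query_aln: str,
    chain_aln: str,
    chain_id: str,
    query_residue_index: int,
    chain_residue_numbers: list[int] | None = None,
) -> tuple[str, int] | None:
    """One-shot residue mapping through a two-row alignment."""
    m = ResidueMapping.from_alignment(query_aln, chain_aln, chain_id, chain_residue_numbers)
    return m.map_residue(query_residue_index)


# ---------------------------------------------------------------------------
# contact distances

def min_distance_to_partners(
    model: StructureModel,
    chain_id: str,
    residue_number: int,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    query_residue: int | None = None,
) -> ContactResult:
    """Minimum distance from a residue's atoms to any interface partner.

    Partner atoms are all atoms outside the target chain plus any ligand
    atoms (including those recorded on the target chain).  The threshold
    comparison is inclusive.
    """
    target_atoms = model.atoms_of_residue(chain_id, residue_number)
    if not target_atoms:
        raise ValueError(f"residue {chain_id}/{residue_number} not found")
    partners = [
        a
        for a in model.atoms
        if a.chain_id != chain_id
        or (
            _residue_kind(a.residue_name, a.is_hetero) == "ligand"
            and a.residue_number != residue_number
        )
    ]
    if not partners:
        raise ValueError("monomeric structure, no partners")
    t_xyz = np.array([(a.x, a.y, a.z) for a in target_atoms], dtype=float)
    p_xyz = np.array([(a.x, a.y, a.z) for a in partners], dtype=float)
    dmat = cdist(t_xyz, p_xyz)
    flat = int(np.argmin(dmat))
    _, pj = np.unravel_index(flat, dmat.shape)
    best = partners[pj]
    dmin = float(dmat.min())
    return ContactResult(
        query_residue=query_residue if query_residue is not None else residue_number,
        target_chain=chain_id,
        target_residue=residue_number,
        partner_chain=best.chain_id,
        partner_residue=best.residue_number,
        partner_kind=_residue_kind(best.residue_name, best.is_hetero),
        min_distance=dmin,
        threshold=threshold,
        within_threshold=dmin <= threshold,
    )
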