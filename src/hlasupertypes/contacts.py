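"""HLA-peptide contact detection in complex structures, and 15-residue
binding motifs from beta-chain key positions.

A residue pair is a contact when the minimal distance between any heavy atom
of one and any heavy atom of the other is at most the cutoff (default 4 A).
Hydrogens, waters and non-primary altlocs are ignored; only the first model
of a multi-model file is read. The 15 motif positions (beta 9, 11, 13, 28,
30, 37, 47, 57, 60, 61, 67, 70, 71, 74, 78) span the groove's binding
pockets; concatenating the residues found there gives a linear motif that
summarizes the binding-site composition of an allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import DEFAULT_BETA_POSITIONS, STANDARD_AAS


@dataclass
class ContactSet:
    """Residue-level contacts between an HLA chain and a peptide chain."""

    structure_id: str
    cutoff: float
    #: (hla_chain, hla_residue_number, peptide_residue_number, min_atom_distance)
    pairs: list[tuple[str, int, int, float]]

    def hla_residues(self) -> list[int]:
        return sorted({p[1] for p in self.pairs})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hla_chain\thla_residue\tpeptide_residue\tmin_distance_A\n")
            for ch, hr, pr, d in self.pairs:
                fh.write(f"{ch}\t{hr}\t{pr}\t{d:.3f}\n")


@dataclass
class BindingMotif:
    """A 15-residue linear string read off the beta-chain key positions."""

    allele_id: str
    residues: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.positions):
            raise ValueError("residues and positions lengths differ")
        bad = set(self.residues) - set(STANDARD_AAS)
        if bad:
            raise ValueError(f"non-standard residues in motif: {sorted(bad)}")


def _residue_atoms(residue) -> np.ndarray:
    """Heavy-atom coordinates of a residue, primary altloc only."""
    coords = []
    for atom in residue.get_atoms():
        if atom.element == "H":
            continue
        if atom.is_disordered():
            atom = atom.disordered_get()
        coords.append(atom.get_coord())
    return np.asarray(coords, dtype=float)


def _chain_residues(model, chain_id: str):
    if chain_id not in [c.id for c in model]:
        raise KeyError(f"chain {chain_id!r} not found in structure")
    chain = model[chain_id]
    residues = [r for r in chain if r.id[0] == " "]  # drop waters/hetero
    if not residues:
        raise ValueError(f"chain {chain_id!r} has no polymer residues")
    return residues


def find_contact_residues(structure, hla_chain: str, peptide_chain: str,
                          cutoff: float = 4.0) -> ContactSet:
    """All residue pairs between two chains whose minimal any-atom distance
    is <= ``cutoff`` (inclusive boundary).

    ``structure`` is a parsed Bio.PDB structure (or model); the first model
    is used. Swapping the two chain arguments transposes the pair set.
    """
    model = next(structure.get_models()) if hasattr(structure, "get_models") else structure
    hla_res = _chain_residues(model, hla_chain)
    pep_res = _chain_residues(model, peptide_chain)

    pairs = []
    pep_coords = [_residue_atoms(r) for r in pep_res]
    for hr in hla_res:
        hc = _residue_atoms(hr)
        if hc.size == 0:
            continue
        for pr, pc in zip(pep_res, pep_coords):
            if pc.size == 0:
                continue
            d = float(cdist(hc, pc).min())
            if d <= cutoff:
                pairs.append((hla_chain, int(hr.id[1]), int(pr.id[1]), d))
    return ContactSet(structure_id=getattr(structure, "id", "structure"),
                      cutoff=cutoff, pairs=pairs)


def build_motif(beta_sequence: str, positions: Sequence[int] = DEFAULT_BETA_POSITIONS,
                allele_id: str = "", numbering: Mapping[int, int] | None = None
                ) -> BindingMotif:
    """Read the residues at the given beta-chain positions into a motif.

    ``numbering`` maps a mature-chain position number to a 0-based index into
    ``beta_sequence``; by default position ``p`` is residue ``p`` in 1-based
    sequence order. An unresolvable position is an error naming the position
    and allele.
    """
    chars = []
    for pos in positions:
        idx = numbering[pos] if numbering is not None and pos in numbering else (
            pos - 1 if numbering is None else None)
        if idx is None or not 0 <= idx < len(beta_sequence):
            raise IndexError(f"position beta{pos} unresolvable for allele "
                             f"{allele_id or '<unnamed>'} "
                             f"(sequence length {len(beta_sequence)})")
        chars.append(beta_sequence[idx])
    return BindingMotif(allele_id=allele_id, residues="".join(chars),
                        positions=tuple(positions))


def motifs_to_fasta(motifs: Sequence[BindingMotif], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.allele_id}\n{m.residues}\n")
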