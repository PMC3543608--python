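import numpy as np
import pandas as pd
import pytest

from hlasupertypes import AffinityMatrix, BinaryBindingMatrix


@pytest.fixture
def small_affinity() -> AffinityMatrix:
    """4 alleles x 6 peptides, two loci, one missing cell."""
    vals = pd.DataFrame(
        [[100.0, 200.0, 499.0, 500.0, 501.0, 900.0],
         [50.0, 5000.0, 30.0, 4000.0, np.nan, 250.0],
         [10.0, 20.0, 1000.0, 2000.0, 3000.0, 400.0],
         [600.0, 450.0, 80.0, 90.0, 700.0, 800.0]],
        index=["DRB1*0101", "DRB1*0401", "DQB1*0201", "DQB1*0301"],
        columns=[f"pep{i}" for i in range(1, 7)])
    locus = {"DRB1*0101": "DR", "DRB1*0401": "DR",
             "DQB1*0201": "DQ", "DQB1*0301": "DQ"}
    return AffinityMatrix(values=vals, locus_of=locus)


def random_binary_matrix(rng: np.random.Generator, n_alleles: int = 6,
                         n_peptides: int = 20) -> BinaryBindingMatrix:
    """A random binary fixture over three loci (2 alleles each by default)."""
    loci = ["DR", "DQ", "DP"]
    alleles = [f"{l}B_x{i}" for l in loci for i in range(n_alleles // 3)]
    if len(alleles) < n_alleles:
        alleles += [f"DRB_y{i}" for i in range(n_alleles - len(alleles))]
    bits = pd.DataFrame(rng.integers(0, 2, size=(n_alleles, n_peptides)),
                        index=alleles, columns=[f"p{j}" for j in range(n_peptides)])
    locus_of = {a: a[:2] for a in alleles}
    return BinaryBindingMatrix(bits=bits, rule="random", locus_of=locus_of)


_PDB_ATOM = ("ATOM  {serial:>5d}  {name:<3s}{resname:>4s} {chain}{resseq:>4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n")


def write_toy_pdb(path, chains: dict) -> None:
    """Write a minimal PDB file.

    ``chains`` maps chain id -> list of residues; each residue is a
    (resname, [(atom_name, element, x, y, z), ...]) tuple.
    """
    serial = 1
    with open(path, "w") as fh:
        for chain_id, residues in chains.items():
            for resseq, (resname, atoms) in enumerate(residues, start=1):
                for name, element, x, y, z in atoms:
                    fh.write(_PDB_ATOM.format(serial=serial, name=name,
                                              resname=resname, chain=chain_id,
                                              resseq=resseq, x=x, y=y, z=z,
                                              element=element))
                    serial += 1
        fh.write("END\n")


def parse_pdb(path):
    from Bio.PDB import PDBParser
    return PDBParser(QUIET=True).get_structure("toy", str(path))
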