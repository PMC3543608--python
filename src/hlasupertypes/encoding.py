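"""Numeric encoding of peptides and motifs via amino-acid indices.

Each equal-length sequence becomes a row of L x K features (position-major:
all K index values for position 1, then position 2, ...), where K is the
number of indices in the table. With the default 24-index table and 15-mer
sequences this is the 360-feature representation used for both motif
clustering and peptide classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import IndexTable, STANDARD_AAS


@dataclass
class FeatureMatrix:
    """Items x (L*K) real-valued descriptors with named columns."""

    features: pd.DataFrame  # index = item ids, columns = "p{pos}_{index_id}"

    @property
    def item_ids(self) -> list[str]:
        return list(self.features.index)

    def to_numpy(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)


def homogenize_length(peptides: Sequence[str], target_len: int = 15,
                      conservation: Sequence[Sequence[float]] | None = None
                      ) -> list[str]:
    """Trim peptides down to ``target_len`` by removing terminal residues.

    With a per-peptide ``conservation`` profile (one score per residue),
    whichever terminus currently carries the lower score is removed first at
    each step. Without a profile the fallback policy applies: trim from the
    C-terminus first, then the N-terminus, alternating. Peptides shorter
    than ``target_len`` are an error.
    """
    out = []
    for i, pep in enumerate(peptides):
        if len(pep) < target_len:
            raise ValueError(f"peptide {i} ({pep!r}) shorter than target "
                             f"length {target_len}")
        prof = list(conservation[i]) if conservation is not None else None
        if prof is not None and len(prof) != len(pep):
            raise ValueError(f"conservation profile length mismatch for peptide {i}")
        s, e = 0, len(pep)  # active window [s, e)
        trim_c_next = True
        while e - s > target_len:
            if prof is not None:
                if prof[s] <= prof[e - 1]:
                    s += 1
                else:
                    e -= 1
            else:
                if trim_c_next:
                    e -= 1
                else:
                    s += 1
                trim_c_next = not trim_c_next
        out.append(pep[s:e])
    return out


def encode(sequences: Sequence[str], table: IndexTable,
           item_ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Encode equal-length sequences as concatenated per-position index values.

    Row i, feature block for position p, is the K index values of residue
    ``sequences[i][p]``. Any character outside the 20 standard amino acids is
    an error naming the sequence and position.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to encode")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have equal length")
    aa_set = set(STANDARD_AAS)
    for i, s in enumerate(seqs):
        for p, ch in enumerate(s):
            if ch not in aa_set:
                raise ValueError(f"non-standard residue {ch!r} in sequence "
                                 f"{i} at position {p + 1}")

    # K x 20 lookup -> L*K features per sequence, position-major
    tbl = table.values  # index ids x amino acids
    aa_to_col = {aa: j for j, aa in enumerate(tbl.columns)}
    arr = tbl.to_numpy(dtype=float)  # K x 20
    rows = np.empty((len(seqs), L * tbl.shape[0]))
    for i, s in enumerate(seqs):
        cols = [aa_to_col[ch] for ch in s]
        rows[i] = arr[:, cols].T.ravel()  # position-major: (L, K) flattened

    ids = list(item_ids) if item_ids is not None else [f"seq{i}" for i in range(len(seqs))]
    names = [f"p{p + 1}_{idx}" for p in range(L) for idx in tbl.index]
    return FeatureMatrix(features=pd.DataFrame(rows, index=ids, columns=names))


def scale_for_kernel(features: FeatureMatrix) -> FeatureMatrix:
    """Rescale a feature matrix by 1/sqrt(n_features).

    With standardized indices, squared Euclidean distances between raw
    encodings grow linearly with the L*K feature count (~2*360 for unrelated
    15-mers), which pushes an RBF kernel with gamma around 0.5 into its
    degenerate near-identity regime. Dividing by sqrt(n_features) puts
    typical squared distances on an O(1) scale where such kernel widths are
    informative; relative geometry (and scale-free classifiers) are
    unaffected.
    """
    f = features.features
    return FeatureMatrix(features=f / np.sqrt(f.shape[1]))
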