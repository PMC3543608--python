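"""Turn IC50 affinity matrices into binary binder/non-binder matrices.

Two rules are supported, matching the two datasets' conventions:

* per-allele quantile — the lowest-IC50 fraction of each allele's measured
  peptides (default 20 %) are binders;
* fixed threshold — IC50 strictly below a cutoff (default 500 nM; 1000 nM is
  the more permissive class II convention) is a binder.

Missing affinities always map to 0, with the count recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AffinityMatrix


@dataclass
class BinaryBindingMatrix:
    """0/1 binding events, alleles x peptides, plus the rule that produced it."""

    bits: pd.DataFrame
    rule: str
    locus_of: dict[str, str]
    n_missing: int = 0

    def __post_init__(self) -> None:
        arr = self.bits.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        self.bits = self.bits.astype(np.int8)
        missing = set(self.bits.index) - set(self.locus_of)
        if missing:
            raise ValueError(f"locus_of missing for alleles: {sorted(missing)}")

    @property
    def allele_ids(self) -> list[str]:
        return list(self.bits.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.bits.columns)


def binarize_by_quantile(aff: AffinityMatrix, fraction: float = 0.20) -> BinaryBindingMatrix:
    """Mark, per allele, the ``floor(fraction * n_present)`` lowest-IC50
    peptides as binders.

    Ties at the boundary are broken by ascending IC50 then lexicographic
    peptide id, so the result is deterministic. An allele with no measured
    values at all is an error.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    vals = aff.values
    bits = pd.DataFrame(0, index=vals.index, columns=vals.columns, dtype=np.int8)
    for allele, row in vals.iterrows():
        present = row.dropna()
        if present.empty:
            raise ValueError(f"allele {allele!r} has no measured affinities")
        k = math.floor(fraction * len(present))
        if k:
            order = sorted(present.items(), key=lambda kv: (kv[1], kv[0]))
            bits.loc[allele, [pid for pid, _ in order[:k]]] = 1
    n_missing = int(vals.isna().to_numpy().sum())
    return BinaryBindingMatrix(bits=bits, rule=f"quantile({fraction})",
                               locus_of=dict(aff.locus_of), n_missing=n_missing)


def binarize_by_threshold(aff: AffinityMatrix, cutoff_nM: float = 500.0) -> BinaryBindingMatrix:
    """Binder iff IC50 is strictly below ``cutoff_nM``; the boundary value and
    missing cells are non-binders."""
    if cutoff_nM <= 0:
        raise ValueError(f"cutoff_nM must be positive, got {cutoff_nM}")
    vals = aff.values.to_numpy(dtype=float)
    bits = pd.DataFrame((vals < cutoff_nM).astype(np.int8),
                        index=aff.values.index, columns=aff.values.columns)
    return BinaryBindingMatrix(bits=bits, rule=f"fixed({cutoff_nM}nM)",
                               locus_of=dict(aff.locus_of),
                               n_missing=int(np.isnan(vals).sum()))
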