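"""Consensus between functional and motif clusterings, and peptide
promiscuity / locus-specificity statistics.

A *stable* (consensus) cluster is an allele set found inside one functional
cluster and one motif cluster simultaneously — computed here as all pairwise
intersections of size >= min_size. Promiscuity statistics classify each
peptide with at least one binding event as cross-locus (events in >= 2 loci)
or locus-exclusive, and report per-locus binding-event densities relative to
the maximum theoretically possible number of events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .binarize import BinaryBindingMatrix
from .clustering import ClusterSet


@dataclass
class ConsensusResult:
    stable_pairs: list[tuple[frozenset, frozenset, frozenset]]
    consensus_clusters: list[frozenset]


def consensus(func_clusters: ClusterSet, motif_clusters: ClusterSet,
              min_size: int = 2) -> ConsensusResult:
    """All deduplicated functional x motif cluster intersections of size
    >= ``min_size``, each reported with its parent clusters. Symmetric in its
    two arguments up to pair orientation."""
    fu, mu = func_clusters.universe, motif_clusters.universe
    if fu and mu and not (fu & mu):
        raise ValueError("cluster sets cover disjoint allele universes")
    pairs = []
    seen: set[frozenset] = set()
    consensus_clusters = []
    for fc in func_clusters.clusters:
        for mc in motif_clusters.clusters:
            inter = fc & mc
            if len(inter) >= min_size:
                pairs.append((fc, mc, inter))
                if inter not in seen:
                    seen.add(inter)
                    consensus_clusters.append(inter)
    return ConsensusResult(stable_pairs=pairs, consensus_clusters=consensus_clusters)


@dataclass
class PromiscuityReport:
    """Cross-locus vs locus-exclusive peptide statistics.

    Percentages are over peptides with at least one binding event, so
    ``cross_locus_percent + locus_exclusive_percent == 100`` whenever any
    event exists. ``density_percent`` maps each locus to the binding events
    of locus-exclusive peptides in that locus as a percent of the maximum
    theoretical count (denominator controlled by ``density_denominator``).
    """

    n_peptides_binding_any: int
    cross_locus_count: int
    cross_locus_percent: float
    locus_exclusive_count: int
    locus_exclusive_percent: float
    density_percent: dict[str, float]
    density_denominator: str
    per_peptide_locus_counts: pd.DataFrame  # peptides x loci binding-event counts
    defined: bool = True


def promiscuity(binary: BinaryBindingMatrix,
                density_denominator: str = "all_peptides") -> PromiscuityReport:
    """Classify binding peptides as cross-locus or locus-exclusive and
    compute per-locus binding densities.

    ``density_denominator``: ``"all_peptides"`` uses (alleles in locus) x
    (all peptides); ``"exclusive_peptides"`` uses (alleles in locus) x
    (locus-exclusive peptides of that locus).
    """
    if density_denominator not in ("all_peptides", "exclusive_peptides"):
        raise ValueError(f"unknown density_denominator {density_denominator!r}")
    bits = binary.bits
    loci = sorted(set(binary.locus_of.values()))
    by_locus = pd.DataFrame(
        {loc: bits.loc[[a for a in bits.index if binary.locus_of[a] == loc]].sum(axis=0)
         for loc in loci})
    n_loci_hit = (by_locus > 0).sum(axis=1)
    binding = n_loci_hit >= 1
    cross = n_loci_hit >= 2
    exclusive = n_loci_hit == 1
    n_bind = int(binding.sum())
    if n_bind == 0:
        return PromiscuityReport(0, 0, float("nan"), 0, float("nan"),
                                 {loc: float("nan") for loc in loci},
                                 density_denominator, by_locus, defined=False)
    density = {}
    for loc in loci:
        n_alleles = sum(1 for a in bits.index if binary.locus_of[a] == loc)
        excl_here = exclusive & (by_locus[loc] > 0)
        events = int(by_locus.loc[excl_here, loc].sum())
        if density_denominator == "all_peptides":
            denom = n_alleles * bits.shape[1]
        else:
            denom = n_alleles * int(excl_here.sum())
        density[loc] = 100.0 * events / denom if denom else float("nan")
    return PromiscuityReport(
        n_peptides_binding_any=n_bind,
        cross_locus_count=int(cross.sum()),
        cross_locus_percent=100.0 * cross.sum() / n_bind,
        locus_exclusive_count=int(exclusive.sum()),
        locus_exclusive_percent=100.0 * exclusive.sum() / n_bind,
        density_percent=density,
        density_denominator=density_denominator,
        per_peptide_locus_counts=by_locus)


def locus_exclusive_matrix(binary: BinaryBindingMatrix) -> pd.DataFrame:
    """The binding matrix restricted to events of locus-exclusive peptides
    (all other cells zeroed)."""
    rep = promiscuity(binary)
    by_locus = rep.per_peptide_locus_counts
    excl = (by_locus > 0).sum(axis=1) == 1
    out = binary.bits.copy()
    out.loc[:, ~excl] = 0
    return out


def heatmap_export(binary: BinaryBindingMatrix, out_prefix,
                   ordering: Sequence[str] | None = None) -> dict[str, str]:
    """Write full and locus-exclusive-only binding heat maps.

    Produces ``<prefix>_full.tsv`` / ``.png`` and ``<prefix>_exclusive.tsv``
    / ``.png``. ``ordering`` (e.g. dendrogram leaf order) permutes the allele
    rows. Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    full = binary.bits
    if ordering is not None:
        full = full.loc[list(ordering)]
    excl = locus_exclusive_matrix(binary)
    if ordering is not None:
        excl = excl.loc[list(ordering)]
    paths = {}
    for tag, mat in (("full", full), ("exclusive", excl)):
        tsv = f"{out_prefix}_{tag}.tsv"
        png = f"{out_prefix}_{tag}.png"
        mat.to_csv(tsv, sep="\t")
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.imshow(mat.to_numpy(), aspect="auto", interpolation="nearest",
                  cmap="cividis")
        ax.set_xlabel("peptide")
        ax.set_ylabel("HLA allele")
        ax.set_yticks(range(len(mat.index)))
        ax.set_yticklabels(mat.index, fontsize=4)
        fig.savefig(png, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths[tag] = tsv
    return paths
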