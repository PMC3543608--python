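"""Synthetic affinity matrices, binding motifs and null data with planted,
exported ground truth.

The generator emulates the shape of the study system: a 27-allele HLA class
II panel (15 DR, 6 DQ, 6 DP beta-chain alleles) measured against 636
peptides, with a two-level planted hierarchy — the three loci at the top and
intra-locus allele blocks below — plus log-normal IC50 noise. Every stage of
the pipeline (binarization, distance, bootstrap clustering, extraction,
promiscuity, labeling, classification) can therefore be exercised offline
against known truth.

Generative model (per locus, binding data): a per-peptide binder probability
vector q defines the locus; the locus base profile is Bernoulli(q); each
block prototype re-draws a fraction ``cluster_divergence`` of positions from
q; each allele re-draws a fraction ``allele_divergence`` from its block
prototype. Binder cells get IC50 ~ LogNormal(ln 50 nM, sigma), non-binders
~ LogNormal(ln 5000 nM, sigma): the two centres straddle the 500 nM cutoff
symmetrically in log space, so the noise-free limit binarizes back to the
exact planted truth.

``promiscuous`` mode plants a shared "sticky" peptide pool bound by every
locus (and makes it the *only* thing DP binds, mirroring the near-absence of
DP-exclusive binding events); ``locus_pure`` mode gives each locus a private
third of the peptide panel, so every binding peptide is locus-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AffinityMatrix, STANDARD_AAS


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the real panel: 27 alleles over three loci, 636 peptides,
    ~20 % binders per allele, log-IC50 noise sigma = 0.7 (about 0.3 log10
    units, typical competition-assay variability).
    """

    n_alleles_per_locus: dict = field(
        default_factory=lambda: {"DR": 15, "DQ": 6, "DP": 6})
    blocks_per_locus: dict = field(
        default_factory=lambda: {"DR": (5, 5, 5), "DQ": (2, 2, 2), "DP": (6,)})
    n_peptides: int = 636
    binder_rate: float = 0.20
    promiscuous_fraction: float = 0.22
    pool_stickiness: float = 0.85
    dp_pool_stickiness: float = 0.85
    cluster_divergence: float = 0.25
    allele_divergence: float = 0.04
    ic50_noise: float = 0.7
    promiscuity_mode: str = "promiscuous"
    binder_ic50_nM: float = 50.0
    nonbinder_ic50_nM: float = 5000.0
    motif_length: int = 15
    motif_locus_positions: int = 4   # private diverged positions per locus
    motif_block_positions: int = 1   # private diverged positions per block
    motif_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for locus, n in self.n_alleles_per_locus.items():
            blocks = self.blocks_per_locus.get(locus)
            if blocks is None or sum(blocks) != n:
                raise ValueError(f"blocks_per_locus[{locus!r}] must partition "
                                 f"{n} alleles, got {blocks}")
        for name in ("binder_rate", "promiscuous_fraction", "pool_stickiness",
                     "dp_pool_stickiness",
                     "cluster_divergence", "allele_divergence",
                     "motif_mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ic50_noise < 0:
            raise ValueError("ic50_noise must be >= 0")
        if self.promiscuity_mode not in ("promiscuous", "locus_pure"):
            raise ValueError(f"unknown promiscuity_mode {self.promiscuity_mode!r}")


@dataclass
class GroundTruth:
    """Planted structure exported alongside every simulated dataset."""

    locus_of: dict[str, str]
    block_of: dict[str, str]          # allele -> planted intra-locus block id
    binder_bits: pd.DataFrame | None  # planted binary truth (binding data only)
    motifs: dict[str, str] | None = None

    def locus_partition(self, allele_ids: Sequence[str]) -> list[int]:
        loci = sorted(set(self.locus_of.values()))
        return [loci.index(self.locus_of[a]) for a in allele_ids]

    def block_partition(self, allele_ids: Sequence[str]) -> list[int]:
        blocks = sorted(set(self.block_of.values()))
        return [blocks.index(self.block_of[a]) for a in allele_ids]

    def to_json_dict(self) -> dict:
        out = {"locus_of": self.locus_of, "block_of": self.block_of}
        if self.binder_bits is not None:
            out["binder_bits"] = {a: self.binder_bits.loc[a].tolist()
                                  for a in self.binder_bits.index}
        if self.motifs is not None:
            out["motifs"] = self.motifs
        return out


_PREFIX = {"DR": "DRB", "DQ": "DQB", "DP": "DPB"}


def _allele_names(config: SimConfig) -> dict[str, list[str]]:
    return {locus: [f"{_PREFIX[locus]}_sim{i + 1:02d}" for i in range(n)]
            for locus, n in config.n_alleles_per_locus.items()}


def _locus_prob_vectors(config: SimConfig, rng) -> dict[str, np.ndarray]:
    """Per-locus per-peptide binder probability q (see module docstring)."""
    P = config.n_peptides
    loci = list(config.n_alleles_per_locus)
    if config.promiscuity_mode == "promiscuous":
        pool = np.zeros(P, dtype=bool)
        pool[rng.choice(P, size=int(round(config.promiscuous_fraction * P)),
                        replace=False)] = True
        f = pool.mean()
        stick = config.pool_stickiness
        # per-allele expected binder rate = f*stick + (1-f)*specific
        specific = max(0.0, (config.binder_rate - f * stick) / (1 - f))
        q = {}
        for locus in loci:
            v = np.where(pool, stick, specific)
            if locus == "DP":
                # DP binds only the shared pool: DP-exclusive binding events
                # are then (nearly) absent, as in the real panel
                v = np.where(pool, config.dp_pool_stickiness, 0.0)
            q[locus] = v
        return q
    # locus_pure: private contiguous slice of the panel per locus
    bounds = np.linspace(0, P, len(loci) + 1).astype(int)
    q = {}
    rate = min(1.0, config.binder_rate * len(loci))
    for k, locus in enumerate(loci):
        v = np.zeros(P)
        v[bounds[k]:bounds[k + 1]] = rate
        q[locus] = v
    return q


def _redraw(bits: np.ndarray, fraction: float, q: np.ndarray, rng) -> np.ndarray:
    """Re-draw a random ``fraction`` of positions from Bernoulli(q)."""
    out = bits.copy()
    mask = rng.random(bits.shape[0]) < fraction
    out[mask] = rng.random(mask.sum()) < q[mask]
    return out


def simulate_affinity(config: SimConfig | None = None
                      ) -> tuple[AffinityMatrix, GroundTruth]:
    """Simulate an alleles x peptides IC50 matrix with planted structure.

    Returns the noisy affinity matrix plus the ground truth (locus and block
    partitions and the exact planted binder matrix). Fully determined by
    ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    names = _allele_names(config)
    q = _locus_prob_vectors(config, rng)
    P = config.n_peptides
    peptide_ids = [f"pep{i + 1:04d}" for i in range(P)]

    locus_of, block_of = {}, {}
    rows, allele_ids = [], []
    for locus, alleles in names.items():
        base = (rng.random(P) < q[locus]).astype(np.int8)
        i = 0
        for b, size in enumerate(config.blocks_per_locus[locus]):
            proto = _redraw(base, config.cluster_divergence, q[locus], rng)
            for _ in range(size):
                bits = _redraw(proto, config.allele_divergence, q[locus], rng)
                allele = alleles[i]
                rows.append(bits)
                allele_ids.append(allele)
                locus_of[allele] = locus
                block_of[allele] = f"{locus}_b{b + 1}"
                i += 1
    truth_bits = pd.DataFrame(np.vstack(rows), index=allele_ids,
                              columns=peptide_ids, dtype=np.int8)

    mu = np.where(truth_bits.to_numpy(dtype=bool),
                  np.log(config.binder_ic50_nM), np.log(config.nonbinder_ic50_nM))
    ic50 = np.exp(mu + config.ic50_noise * rng.standard_normal(mu.shape))
    aff = AffinityMatrix(values=pd.DataFrame(ic50, index=allele_ids,
                                             columns=peptide_ids),
                         locus_of=dict(locus_of))
    return aff, GroundTruth(locus_of=locus_of, block_of=block_of,
                            binder_bits=truth_bits)


def simulate_motifs(config: SimConfig | None = None
                    ) -> tuple[dict[str, str], GroundTruth]:
    """Simulate 15-mer binding-site motifs with the same planted hierarchy.

    All motifs descend from one ancestor sequence, mirroring the shared
    origin of the class II beta-chain genes: each locus substitutes a private
    block of ``motif_locus_positions`` positions, each intra-locus block a
    further private block of ``motif_block_positions`` positions, and each
    allele then mutates every position independently with probability
    ``motif_mutation_rate``. Private position sets are disjoint, so locus
    prototypes are exactly equidistant (and likewise blocks within a locus)
    — divergence between groups carries no accidental topology of its own.
    Returns allele -> motif plus ground truth.
    """
    config = config or SimConfig()
    # independent stream from the binding data, same master seed
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    names = _allele_names(config)
    aas = np.array(list(STANDARD_AAS))
    L = config.motif_length
    loci = list(names)
    lpp, bpp = config.motif_locus_positions, config.motif_block_positions
    max_blocks = max(len(config.blocks_per_locus[l]) for l in loci)
    need = len(loci) * lpp + max_blocks * bpp
    if need > L:
        raise ValueError(f"motif length {L} too short for {len(loci)} loci x "
                         f"{lpp} + {max_blocks} blocks x {bpp} private positions")

    def substitute(seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = seq.copy()
        for p in positions:
            choices = aas[aas != out[p]]
            out[p] = choices[rng.integers(0, len(choices))]
        return out

    ancestor = aas[rng.integers(0, len(aas), size=L)]
    motifs, locus_of, block_of = {}, {}, {}
    for k, locus in enumerate(loci):
        locus_proto = substitute(ancestor, np.arange(k * lpp, (k + 1) * lpp))
        i = 0
        for b, size in enumerate(config.blocks_per_locus[locus]):
            start = len(loci) * lpp + b * bpp
            proto = substitute(locus_proto, np.arange(start, start + bpp))
            for _ in range(size):
                allele = names[locus][i]
                mask = rng.random(L) < config.motif_mutation_rate
                seq = proto.copy()
                seq[mask] = aas[rng.integers(0, len(aas), size=int(mask.sum()))]
                motifs[allele] = "".join(seq)
                locus_of[allele] = locus
                block_of[allele] = f"{locus}_b{b + 1}"
                i += 1
    truth = GroundTruth(locus_of=locus_of, block_of=block_of, binder_bits=None,
                        motifs=dict(motifs))
    return motifs, truth


def simulate_null(n_items: int, n_features: int, seed: int = 0) -> pd.DataFrame:
    """Exchangeable items x features matrix of i.i.d. standard normals —
    calibration input with no cluster structure."""
    if n_items < 1 or n_features < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n_items, n_features)),
                        index=[f"item{i + 1:02d}" for i in range(n_items)],
                        columns=[f"f{j + 1}" for j in range(n_features)])


def simulate_peptides(n: int, length: int = 15, seed: int = 0,
                      longer_fraction: float = 0.1) -> list[str]:
    """Random peptide panel; a fraction are 16/17-mers so that length
    homogenization has work to do."""
    rng = np.random.default_rng(seed)
    aas = np.array(list(STANDARD_AAS))
    out = []
    for _ in range(n):
        L = length
        if rng.random() < longer_fraction:
            L = length + int(rng.integers(1, 3))
        out.append("".join(aas[rng.integers(0, len(aas), size=L)]))
    return out


def simulate_anchor_peptides(n: int, length: int = 15, seed: int = 0,
                             binder_fraction: float = 0.5,
                             anchor_positions: tuple[int, ...] = (4, 6, 9),
                             anchor_aas: str = "FYWILV"
                             ) -> tuple[list[str], np.ndarray]:
    """Peptides whose binder status is determined by sequence composition.

    Binders carry bulky hydrophobic residues at the canonical anchor
    positions (1-based; default 4, 6 and 9, the positions that coordinate
    the class II binding pockets); non-binders violate at least one anchor.
    Returns (peptides, 0/1 labels) — a learnable benchmark for the
    sequence-based binder classifiers.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(STANDARD_AAS))
    anchors = np.array(list(anchor_aas))
    non_anchors = np.array([a for a in STANDARD_AAS if a not in anchor_aas])
    peptides, labels = [], []
    for i in range(n):
        seq = aas[rng.integers(0, len(aas), size=length)]
        binder = rng.random() < binder_fraction
        if binder:
            for p in anchor_positions:
                seq[p - 1] = anchors[rng.integers(0, len(anchors))]
        else:
            # break one random anchor so no non-binder satisfies all three
            p = anchor_positions[rng.integers(0, len(anchor_positions))]
            seq[p - 1] = non_anchors[rng.integers(0, len(non_anchors))]
        peptides.append("".join(seq))
        labels.append(int(binder))
    return peptides, np.array(labels, dtype=int)


def export_ground_truth(truth: GroundTruth, path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
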