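# Methods

This note records the models, numerical choices and known limitations behind
`hlasupertypes`. It documents what the code computes and why the defaults
are what they are; every number quoted as an observation is produced by the
test suite or by `scripts/acceptance.py`.

## Binarization of IC50 matrices

Two rules convert an alleles × peptides IC50 matrix (nM) into binding
events. The **quantile rule** marks, per allele, the `floor(f · n_present)`
peptides with the lowest IC50 as binders (default f = 0.20, computed over
measured values only; missing cells never count as binders). Ties at the
boundary are broken by ascending IC50 and then lexicographic peptide id, so
the result is reproducible. The **fixed rule** marks IC50 strictly below a
cutoff (default 500 nM; 1000 nM, the more permissive class II convention, is
available through the parameter). The strict inequality means a peptide at
exactly the cutoff is a non-binder. Both rules are monotone: raising the
cutoff, or the fraction, can only add binders.

## Binding motifs and contacts

Contact detection reports every residue pair between an HLA chain and a
peptide chain whose minimal heavy-atom distance is ≤ 4.0 Å (boundary
inclusive). Hydrogens, waters and secondary altlocs are ignored; only the
first model of a multi-model file is used. The 15 motif positions (β9 … β78)
are treated as given input — the bundled list — rather than re-derived,
and `build_motif` is a pure positional lookup over an explicit numbering
map (default: 1-based mature-chain numbering). Making the map explicit
avoids silent off-by-one errors between sequence numbering conventions.

## Amino-acid-index encoding

Sequences of equal length L are encoded position-major as L·K features,
K index values per position. The bundled index table is a **synthetic
stand-in**: four well-known scales (Kyte–Doolittle hydropathy, molecular
weight, net charge, residue volume) plus twenty seeded pseudo-random
indices, clearly labeled in the file header. Any AAindex-style 20-column
TSV can be supplied instead. Each index is standardized to mean 0 / sd 1
across the 20 amino acids at load time, so no index dominates Euclidean
distances by its units; because indices are not injective over amino acids
(Leu and Ile share a molecular weight), a single substitution changes *up
to* K features.

For the kernel classifiers the encoded vectors are additionally divided by
√(L·K) (`scale_for_kernel`). With standardized indices the expected squared
distance between unrelated 15-mers is ≈ 2·360, which drives an RBF kernel
with γ ≈ 0.5 into its near-identity regime (every point orthogonal to every
other); on the rescaled O(1) distances the reported kernel parameters are
informative. Scale-free learners (random forest, naive Bayes) are unaffected.

**Length homogenization** trims peptides to 15 residues, removing terminal
residues only. Given a per-residue conservation profile, the terminus with
the currently lower score is trimmed first; without one, a deterministic
fallback trims C-terminus first, then N-terminus, alternating. Internal
multiple alignment is deliberately out of scope — profiles are inputs.

## Multiscale bootstrap AU support

For an items × features matrix, feature columns are resampled with
replacement at scales r ∈ {0.5, 0.6, …, 1.4} (resample size round(r·n)),
B replicates per scale (default 1000). Distances are recomputed from the
resampled columns — not resampled from the distance matrix — and the tree
is rebuilt per replicate with the same metric and linkage. For each internal
edge of the observed tree, BP_r is the fraction of replicates in which the
exact leaf set recurs as a clade.

Per edge, z_r = Φ⁻¹(1 − BP_r) is fit by weighted least squares to
z(r) = v·√r + c/√r, with weights from the binomial variance of BP_r mapped
through the delta method (w_r = B·φ(z_r)²/(BP_r(1 − BP_r))). Then
AU = 1 − Φ(v − c), the model BP at scale 1 is 1 − Φ(v + c), and
se(AU) = φ(v − c)·√(Σ_vv + Σ_cc − 2Σ_vc) from the WLS covariance. Scales
with BP_r ∈ {0, 1} carry no quantile information and are dropped; if fewer
than two informative scales remain the edge is *degenerate*: AU is clamped
to the majority side (0 or 1) with se flagged NaN rather than raising —
with small B this is common and expected for very stable or very unstable
clades. The closed-form check (BP_r generated exactly from v = 1, c = 0.2
recovers AU = 1 − Φ(0.8) to 10⁻³; BP ≡ 0.5 gives AU = 0.5 exactly) and a
null calibration (i.i.d. data, ≤ 15 % of edges at AU ≥ 0.95) are part of
the test suite.

**Agglomeration** is implemented in-package via Lance–Williams updates
(average default; complete, single, Ward available) with a fixed tie-break:
item ids are sorted lexicographically, each active cluster is represented by
its smallest member index, and among minimum-distance candidate pairs the
lexicographically smallest representative pair merges. Counting exact clade
matches across thousands of replicates requires this determinism across
platforms; a from-scratch brute-force agglomerator serves as the test
oracle, and scipy's implementation is cross-checked on tie-free instances.
Jaccard and Euclidean distances themselves come from
`scipy.spatial.distance`; two all-zero binary rows are at distance 0.

## Cluster extraction, tree cuts, and consensus

`extract_clusters` scans the annotated tree with cutoffs
α_k = 0.95 − 0.1k (default 5 iterations). Per iteration, edges with
AU ≥ α_k that do not touch an already accepted cluster are candidates, and
only maximal candidates are accepted, so accepted clusters are pairwise
disjoint; the root is never a cluster. This "maximal significant edge" rule
means that on data with a clean two-level hierarchy the procedure stops at
whatever level first reaches the cutoff — typically the coarser one. The
three-locus structure of the full panel is therefore read off the
three-group **cut** of the tree (`cut_tree`, the "true cluster plot" view),
while AU-guided extraction is applied where finer structure is the question:
re-clustering the alleles of one locus recovers the planted intra-locus
blocks. A realized asymmetry between inter-locus distances can make a
two-locus superclade genuinely significant, in which case maximal extraction
on the full panel reports it — the cut, not extraction, is the right
instrument for the top level.

`consensus` intersects every functional cluster with every motif cluster and
keeps deduplicated intersections of size ≥ 2. The operation is symmetric
and purely algorithmic; judging which consensus groups are biologically
meaningful is left to the user.

## Promiscuity statistics

A peptide with ≥ 1 binding event is **cross-locus** if its events span ≥ 2
loci, otherwise **locus-exclusive**; percentages are over binding peptides,
so the two classes sum to 100 %. Peptides with no events are excluded from
the denominator. Per-locus density is the number of binding events of
locus-exclusive peptides within a locus divided by a "maximum theoretical"
denominator — either (alleles in locus) × (all peptides) or (alleles in
locus) × (that locus's exclusive peptides); both are implemented because the
appropriate normalization is a modeling choice.

## PPA labeling and classifier benchmark

PPA_i = 100 · count_i / max_j count_j over the binary matrix columns;
activity is 1 iff PPA strictly exceeds the threshold (default 30 %), so
n_pos is non-increasing in the threshold. Random subsampling splits each
class 4:1 train:test independently, without replacement, three times
(the per-class ratio statement is taken as authoritative over the rougher
"two-thirds training" description; a `train_fraction` parameter covers the
alternative). LOOCV pools the n single-holdout predictions into one
confusion matrix. Metrics are computed directly from confusion counts
(precision, recall, specificity, accuracy, F1 = 2PR/(P+R)); zero
denominators yield NaN, not 0. AUC uses the SVM decision function or class
probabilities otherwise. Unstated architecture choices are conventional and
recorded in every report: ANN = one hidden layer of 10 logistic units,
k-NN k = 5, random forest 500 trees.

## The synthetic generator

`simulate_affinity` plants, per locus, a per-peptide binder-probability
vector q; the locus base profile is Bernoulli(q); each block prototype
re-draws 25 % of positions from q (`cluster_divergence`); each allele
re-draws 4 % from its block prototype (`allele_divergence`). Binder cells
get IC50 ~ LogNormal(ln 50 nM, σ), non-binders LogNormal(ln 5000 nM, σ),
σ = 0.7 (≈ 0.3 log10 units, typical competition-assay variability); the
centres straddle the 500 nM cutoff symmetrically in log space, so σ → 0
binarizes back to the exact planted truth. Defaults mirror the study
conditions: 15 DR + 6 DQ + 6 DP alleles, 636 peptides, ~20 % binders per
allele, blocks (5,5,5)/(2,2,2)/(6).

In **promiscuous** mode a shared pool of 22 % of peptides is bound by every
locus with probability 0.85, DR and DQ additionally bind private peptides at
a low rate, and DP binds *only* the pool — reproducing both the observed
preponderance of cross-locus binding (the pool fraction was calibrated once
so the preset yields ≈ 75 % cross-locus peptides at the 500 nM cut) and the
near-absence of DP-exclusive binding events. In **locus_pure** mode each
locus binds only a private third of the panel, so locus-exclusive peptides
dominate. `simulate_motifs` descends all motifs from one ancestor 15-mer —
echoing the common origin of the class II β-chain genes — with each locus
substituting a private set of 4 positions and each block 1 further private
position before per-position allele mutation (rate 0.05); disjoint private
sets make the locus prototypes exactly equidistant, so the planted topology
carries no accidental sub-structure. `simulate_anchor_peptides` labels
peptides binder/non-binder by a sequence rule (bulky hydrophobic residues at
anchor positions 4, 6 and 9), giving the classifiers a learnable target.

**What the generator does not emulate.** Real binding matrices are richer:
in the real panel essentially every peptide binds at least one allele,
whereas the preset leaves most peptides unbound, so *counts* of exclusive
peptides are smaller than real ones even where the *percentage* split
matches. Sequence content and binding are independent except in the
anchor-peptide benchmark; there are no position-specific binding motifs for
the peptides, no allele-frequency structure, and no assay censoring.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure under realistic noise — not predictive
performance on real immunological data. Likewise, many synthetic tree edges
are genuinely borderline, so the distribution of AU standard errors is
wider than on strongly structured real data.

## Problem sizes and runtimes

Defaults for analysis are B = 1000 replicates per scale (the reference
toolchain's default). The test suite and the acceptance script use B = 200
for the 27-allele recovery experiments, B = 500 for the null calibration,
636 peptides for labeling/benchmark and 100 items for LOOCV; the full suite
runs in well under a minute and the acceptance script in about one minute on
a single CPU.
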