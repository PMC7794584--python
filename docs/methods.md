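# Methods

## Scope and data model

`mtcooc` analyses an *aligned* cohort: equal-length sequences over
`{A, C, G, T, N, -}` with a map from alignment columns to 1-based
reference coordinates. Alignment itself is out of scope (use Clustal
Omega / MAFFT upstream); inputs are assumed linearized at reference
position 1, so the circular-genome wrap is not handled in the alignment.
A designated reference record (e.g. the rCRS, NC_012920.1) provides the
coordinate map: columns where the reference holds a gap are insertions
and are excluded from site extraction, so at most 16,569 reference
positions exist for human mtDNA. The reference row is excluded from all
group statistics.

Samples are stratified into eight altitude groups. Bins are half-open
`[low, high)` in metres with default cut points
500, 1000, 1500, 2000, 2500, 3000, 4000 and group 8 = ≥ 4000 m. An
altitude equal to a cut point starts its upper bin. The published
500 m stratification is internally ambiguous about the top two bins
(eight 500 m bins cannot span 0 to > 4000 m), so the cut points are
configuration (`altitude_bins`), not code.

## Missing data and site calling

Any character outside `{A, C, G, T, -}` is normalized to `N` on input,
and `N`/`-` are treated as missingness throughout: excluded from allele
counts, from MAF denominators, and from all three counts of the
co-occurrence frequency. The rationale is that an ambiguity code is a
failed base call, not evidence for or against co-occurrence. A column
whose remaining alleles number < 2 is not a variable site.

Major alleles are called within the group; ties break toward the
reference allele when known, else lexicographically — stable,
reference-anchored calls that make results independent of sample order.
Multi-allelic sites keep every minor allele; each (major, minor) pair
contributes one transition/transversion class to Ts:Tv (the published
handling of multi-allelic sites in that ratio is unstated; per-pair
counting is the convention that keeps the ratio defined site-wise).
"Coding" in site summaries means the 13 protein-coding genes; control
region, tRNA, rRNA and intergenic positions count as non-coding, and a
site in overlapping features is deliberately counted in every covering
feature (so coding + non-coding ≥ total).

## Co-occurrence networks

`C(i,j) = N(x_i y_j)² / (N(x_i) N(y_j))` is evaluated per allele pair.
Only minor alleles seed motifs: the major-allele background never forms
edges. Per sample, the motif network joins the sample's minor-allele
sites where `C ≥ C_th`; the group master network is the deduplicated
union over samples, with node universe = all variable sites of the group
(so degree-0 nodes are meaningful "isolated" sites). Edges are stored
with their allele pair; node-level views collapse parallel allele edges,
and `Nc` counts distinct position pairs. At `C_th = 1` an edge exists
iff two carrier sets coincide, which implies connected components are
cliques; star-like or path topologies only appear at lower thresholds.
Higher-order motifs are derivable as cliques of the master network and
are not separately enumerated.

`<k> = 2 Nc / |nodes|` is reported over two universes — all variable
sites (default) and connected nodes only — because tabulated mean
degrees in the literature are ambiguous about the denominator.

## Node categories

Scope (local / mixed / global) is defined by *variable-site presence*
across groups; connectivity (connected / isolated) is per group, from the
master network. The two axes are tracked independently and intersected on
demand: "global connected" (connected in every group) and "global
isolated" are separate accessors. Both connectivity classes use the same
cross-group universe. Removing a group can only narrow scope
(global→mixed→local), a property the tests enforce.

## Gene–gene interaction networks

Every master link contributes 1 to each (feature_i, feature_j)
combination of its endpoints' covering features. Overlapping genes
(ATP8/ATP6, ND4L/ND4, the ATP6/CO3 shared boundary) are double-counted
on purpose; positions in no feature map to "intergenic" so no link is
silently dropped; self-pairs (CYB–CYB, CR–CR) are retained; tRNAs are
first-class nodes. This makes the conservation identity

    Σ weights = Σ_links |features_i| · |features_j|

exact on every input — it is asserted in the tests and recomputed by the
acceptance script. The rCRS feature table (37 genes + control region =
16024–16569 ∪ 1–576) ships inside the package as a versioned TSV.

## Null models

For each sample, `G(N, p)` is drawn over the sample's real motif-network
node labels with `p = 2 Nc / (N(N−1))` matched to that sample's node and
link counts; per replicate the draws are merged and gene-mapped exactly
like the real data. Defaults: 100 replicates (configurable; recorded in
output metadata), population SD (ddof = 0) across replicates — the band
is descriptive, not an inferential test, so no df correction or p-value
calibration is applied. A gene pair never seen in any replicate has
mean = SD = 0, so any real occurrence is flagged "above"; this sharp-band
consequence is intended and documented rather than smoothed away.
Degree-preserving (configuration-model) nulls are out of scope.

## Group comparison

The two-proportion Z-test uses the pooled proportion of local connected
nodes over the two groups' total variable-site counts and a two-sided
normal p-value (the 1.96 cut at α = 0.05). Pairs with pooled proportion
0 or 1 have zero variance; the API raises, and the pipeline records NaN
for such pairs instead of aborting. Jaccard similarity defaults to each
group's *connected* node sets (motif-participating sites); `node_set="all"`
and `exclude_global=True` are exposed because the published account is
ambiguous about whether clustering used shared (mixed) nodes only —
neither option is silently chosen. Clustering is agglomerative on
`1 − J`; linkage defaults to average (UPGMA) since no linkage method is
named in the source analyses; the tree is rooted at the last merge with
deterministic leaf order and written as Newick.

## Synthetic cohorts

The generator emulates the statistical fingerprint of an
altitude-stratified mtDNA cohort, under fixed reference conditions:

| parameter | default | why |
|---|---|---|
| genome_length | 2000 | large enough for distinct gene blocks, small enough for fast exact tests |
| group_sizes | 8 × 30 | ~240 samples, the order of a multi-group GenBank cohort per group |
| planted_pairs | 20 (4 global, 8 mixed, 8 local) | all three scopes; mixed pairs split 1–4 vs 5–8 to plant the altitude bifurcation |
| carrier_fraction | 0.1 | 3 carriers per group: realistic minor-haplotype frequency, exactly representable MAF |
| singleton_rate | 0.02 | sparse independent variants, ~40 per genome |
| hotspot | first tenth, 5× rate, MAF 0.2–0.45 | control-region analogue: elevated mutation rate and high-MAF independent variants |
| transition_fraction | 0.9 | the ~90% transition bias of mtDNA |
| triallelic_rate | 0.02 | a handful of tri-allelic sites per cohort |
| ambiguous_rate | 0.001 | occasional failed base calls |

Two constructions make truth-based tests exact at `C_th = 1`: planted
pairs within a group receive mutually disjoint carrier sets and every
allele-level carrier set in a group is kept distinct from all others
(since `C = 1` requires two carrier sets to *coincide*, distinctness
guarantees zero false-positive edges and isolated singletons); and
ambiguity codes are injected only at positions with no planted variant
(a flag allows injection anywhere), so masking cannot perturb carrier
sets at variant positions. The toy annotation partitions the genome into
contiguous blocks including a CR block, a tRNA block and one overlapping
gene pair, exercising double counting.

What the generator does **not** emulate: phylogenetic descent (carrier
sets are drawn independently, so there is no haplotype tree structure or
linkage beyond the planted pairs), recombination, haplogroup topology,
alignment gaps/indels, or sequencing-error correlation. Passing tests
therefore demonstrate correctness of the network algebra and statistics
under known ground truth — not that real GenBank cohorts will show any
particular biological signal. In particular, the published headline
counts for the 673-genome GenBank cohort (3,829 variable sites, 72
deviating gene pairs, …) depend on that exact accession list and its
alignment and are not reproducible from synthetic data.

## Determinism and seeds

Seeded pseudo-randomness (`numpy.random.default_rng`) is the only source
of randomness; no time-based seeding. A pipeline run derives every
stage seed from the single run seed: the generator uses the seed itself,
the null ensemble of group *g* uses `(seed + 100 + g) mod 2³¹`. The run
manifest (config hash, seed, versions) suffices to reproduce a bundle
byte-for-byte; output paths are excluded from the hash.

## Problem sizes in the acceptance script

The acceptance script checks the brute-force oracle on 200 random
alignments of ≤ 20 samples × ≤ 12 columns (where exhaustive enumeration
is exact and fast), planted-pair recovery on 3 cohorts under the
reference conditions, null calibration with 1000 draws at
(N, Nc) = (50, 100) and (200, 400), and the similarity stage over a
20-seed sweep — sizes chosen so every check recomputes from scratch in
seconds while keeping the binomial standard errors tight.

## Known limitations

- At `C_th = 1` the analysis is brittle to missingness at variant
  positions in real data: one `N` in a carrier changes a carrier set and
  can delete a motif. Real-data runs may prefer `C_th` slightly below 1.
- Carrier-set distinctness is a generator guarantee, not a pipeline
  assumption; on real data, coincidentally identical carrier sets are
  genuine perfect co-occurrence and are reported as such.
- Per-variant functional annotation (CADD, HmtVar) is an external join:
  the exported site and catalog TSVs carry the positions to join on, but
  no scores are fetched.
- The Z-test treats sites as independent observations, as in the source
  formulation; linkage between sites makes the nominal α anti-conservative.
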