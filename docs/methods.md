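# Methods

## The replicability model

Two atlases measure the same tissue with different protocols. We assume
each cluster is a sample of cells from a latent expression program, and that
a cluster replicates when cells of its counterpart in the other atlas are
its nearest transcriptomic neighbors *and vice versa*. Nearness is Spearman
correlation over highly variable genes: rank-based similarity is invariant
to monotone distortions, which absorbs the depth, normalization and
capture-efficiency differences between protocols without explicit batch
correction.

Formally, each cell is the vector of within-cell mid-ranks of its
log(CPM+1) HVG expression, mean-centered and unit-normalized; zeros tie at
the shared minimum rank. Inner products of these vectors are exactly
Spearman correlations, so the mean similarity of a target cell to a
reference cluster ("vote") equals the inner product with the cluster's mean
vector. This centroid formulation is a mathematical identity with averaging
the full cell-cell correlation matrix, not an approximation; a brute-force
oracle test enforces agreement to 1e-8.

Replicability scores are one-vs-all AUROCs of the votes (positives: the
target cluster's cells; negatives: all other cells of the *target* dataset,
so the score is internally calibrated per atlas). The symmetric score is
the mean of the two directions. Reciprocal top hits are mutual argmaxes of
the symmetric table, with ties broken toward the smallest cluster label and
logged. Because a cluster facing two interchangeable sibling clusters still
has an argmax, reciprocity alone cannot flag non-replicable fine splits;
the *best-vs-next* AUROC (votes restricted to the two most similar target
clusters) with a two-sided rank-sum test, Bonferroni-corrected within each
atlas's family of reference clusters, provides that filter. A reciprocal
pair is **confident** when both sides pass at α = 0.05. Planted sibling
splits in the generator are reciprocal with one of their siblings almost by
construction, but almost never confident — which is exactly the behaviour
the filter exists to produce.

## Statistical primitives

- AUROC: mid-rank Mann–Whitney formulation; ties count ½.
- Rank-sum test: exact, tie-conditioned null distribution by
  dynamic-programming convolution over doubled mid-ranks for combined
  samples below 20 (the exact path scales to ~100 if requested); otherwise
  the normal approximation with tie correction. The two agree within 0.02
  at 25 observations per group.
- Hypergeometric overlap: upper tail P(X ≥ k); Fisher's exact test uses the
  standard two-sided convention (sum of table probabilities ≤ observed);
  odds ratio is ad/bc with the ∞/0 conventions recorded.
- Multiple testing: Bonferroni or Benjamini–Hochberg.
- Permutation set-overlap test: each replicate redraws every set as a
  uniform random same-size subset of the cluster universe; the statistic is
  the size of the common intersection; p carries the +1 correction so it is
  never zero. Clusters are treated as exchangeable labels — a declared,
  seeded choice, since conditioning on unobserved structure (class
  membership, cluster size) would change the null.

## Synthetic paired atlases

The generator defines the study conditions; its defaults are fixed and the
tests run against them.

| parameter | default | meaning |
|---|---|---|
| n_types / n_genes | 40 / 1500 | shared latent types; gene universe |
| cells_per_type (A, B) | 60, 60 | cells sampled per cluster |
| depth_a / depth_b | 5000 / 2500 | mean library size (counts/cell); B emulates nuclei |
| libsize_sigma | 0.3 | log-normal library-size spread |
| nb_dispersion | 0.5 | negative-binomial dispersion (Var = μ + φμ²) |
| program_effect_sd | 1.2 | log-scale between-type expression spread |
| retention_frac / retention_range | 0.3 / (0.2, 0.8) | fraction of genes attenuated in B and the retention factor range |
| n_split_types | 0 (40 in `split_config`) | shared types represented by two perturbed siblings in B |
| split_shift_sd | 0.25 | log-scale sibling perturbation |
| n_unique_a / n_unique_b | 0 (3 in `split_config`) | atlas-private types |
| n_regions / n_slices | 8 / 5 | dissection regions; tissue slices |
| region_fidelity | 0.8 | probability a cell keeps its type's region label |
| spatial_sd | 0.25 mm | Gaussian scatter around the type's spatial center |
| markers_per_cluster | 4 | catalog size per cluster (the median marker-list size in real atlas catalogs) |

Counts are gamma-Poisson around per-type programs μ(t,g) = baseline(g) ×
effect(t,g) (both log-normal), normalized per type. Atlas B multiplies a
random 30% of genes by a retention factor before sampling, emulating
cytoplasmic transcript loss in nuclear protocols; at equal library size a
retention of 0.5 halves a gene's expected count (verified by Monte Carlo).
Markers are the top fold-change genes against all *non-sibling* clusters,
so sibling splits share markers — deliberately recreating the regime in
which a handful of markers identifies a cluster against the whole tissue
(global AUROC ≈ 0.99) but not against its nearest neighbor (local AUROC ≈
0.5–0.6). One global seed fans out to named substreams (programs, per-atlas
sampling, spatial placement) so stages can be regenerated independently.

What the generator does **not** emulate: real atlas scale (millions of
cells, thousands of clusters), hierarchical taxonomy structure, ambient
RNA/doublets, batch effects within an atlas, realistic cluster-size
skew, and spatially overlapping cell-type territories (each type owns one
Gaussian spatial field). Passing tests therefore demonstrate correctness
and calibration of the machinery under a favorable, controlled signal
regime — not performance guarantees on real atlases, where AUROCs and
recovery rates will be lower and threshold choices matter more.

## HVG selection

The two atlases' genes are intersected; per dataset, genes are split into
10 equal-size bins by mean log-CPM and flagged when their variance exceeds
the bin's 0.75 quantile; the HVG set is the intersection of flags across
datasets, ordered by gene id, with parameters stored as provenance. This
is a deliberately simple, parameterized binned-variance procedure: the
analysis downstream only requires that the feature set be variance-informative
and shared, and every statistic consuming it is rank-based.

## Spatial cell calling

Cells are assigned to the most Pearson-correlated cluster centroid in
log(CPM+1) space over 100 random gene subsamples (80% of the shared panel
each round, configurable); the call is the modal winner (ties: higher mean
winning correlation, then smallest label) and a cell passes when its mean
winning correlation is ≥ 0.5. Cells *below* 0.5 are treated as unassigned —
where source descriptions of this procedure disagree on the direction of
the 0.5 rule, we follow the reading under which low-correlation cells
cannot be confidently called, which is also the only calibration under
which structureless control cells are rejected (≤ 5% pass) while planted
cells pass at ≥ 95%. Pearson on log-CPM (not Spearman) is used here because
the procedure correlates against dense cluster centroids on a reduced gene
panel, where centroid magnitudes are informative.

Concordance asks whether a cell's two calls (one per atlas reference) land
on the two sides of one reciprocal pair; per-slice proportions, distinct-
cluster counts, subsampling-equalized diversity mismatch, log2 region
enrichment (regions with < 50 cells suppressed) and 3-D paired centroid
distances (slice index × 0.2 mm spacing supplies the third coordinate)
summarize the spatial agreement.

## Coordinated expression

Genes used for matching (the HVG set) are excluded. For the remaining
shared genes, the per-gene Spearman correlation between the two atlases'
centroid profiles across matched pairs measures coordination; specificity
compares the same-gene correlation with all correlations between that gene
and any other (both directions pooled), reported as a mid-rank percentile
and a strict is-top flag. All pairwise correlations are computed at once as
a rank-matrix product; a looped oracle enforces equality to 1e-10.
Constant centroid rows are excluded from numerator and comparison sets.
Pair-column subsampling curves (20 replicates per fraction) probe
sensitivity to atlas size; gene-set summaries intersect flat GMT sets with
scored genes (sets outside 15–150 genes dropped) and test in-set vs
out-of-set percentiles with a one-sided rank-sum test, BH-adjusted. GMT
parsing is done in-package — the format is one line per set — to keep the
enrichment path free of heavyweight dependencies.

## Numerical and design choices

- log base: natural by default and configurable; every downstream statistic
  is rank- or correlation-based, hence base-invariant (asserted on a
  fixture).
- z-scores use sample SD (ddof 1); zero-variance genes map to 0 rather
  than NaN so marker averages stay finite.
- Degenerate (constant-expression) cells get zero vectors and are excluded
  from AUROC positives/negatives with a logged count; minimum cluster size
  for AUROC participation is 2 cells overall (≥1 positive, ≥1 negative).
- Argmax ties everywhere break toward the smallest cluster label, logged.
- All-zero cells stay all-zero after normalization, with a warning.
- Marker genes absent from a dataset are dropped from the set (not
  zero-filled), with a warning; a fully absent set is an error.
- Marker-overlap Bonferroni is exposed in two variants — all cross-atlas
  pairs |A|·|B|, or per-atlas max(|A|, |B|) — because the appropriate
  family depends on how the pairing is read; both are reported.
- The reciprocal-hit enrichment 2×2 table compares assigned best matches
  (reciprocal vs not) against the availability of reciprocal clusters in
  the model — a standard enrichment-against-availability construction,
  declared here because the test is conventional but the table is not
  uniquely determined by "Fisher's exact test".
- The pretrained-model path re-centers and re-normalizes both centroids and
  re-ranked target cells on the shared gene subset; per-cluster rescaling
  is monotone, so at full overlap the AUROC table equals training-time
  one-vs-all exactly (asserted to 1e-8).
- Empirical p-values use the +1 correction.

## Problem sizes

The test suite and acceptance script run the default conditions above
(two 2,400-cell atlases of 1,500 genes; an 83-cluster split fixture; a
~2,600-cell spatial panel of 500 genes; a 109-gene transfer panel): sizes
chosen so the full pipeline exercises every code path in about a minute on
one CPU while keeping Monte-Carlo margins (null calibration within ±0.02,
permutation percentile within ±3) statistically meaningful.

## Known limitations

- Reciprocity is computed on the symmetric AUROC table; a
  directional-agreement variant (both directional argmaxes mutual) is not
  exposed as an option beyond inspecting the two directional tables.
- The exact rank-sum path conditions on the observed tie pattern; p-values
  under heavy ties are exact for the permutation null given those ties,
  not for an unconditional continuous model.
- Cluster-merging searches, high-confidence sub-thresholds, cross-species
  ortholog mapping and anatomical (CCF) registration are out of scope;
  inputs must arrive in a shared gene namespace and region vocabulary
  (a two-column region map handles the latter).
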