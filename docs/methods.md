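# Methods

This note documents the models and procedures implemented in `xylolink`,
the defaults that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Normalization

Per-cell total-count normalization: counts divided by the cell's total UMI
count and multiplied by a scale factor (default 1000), so every non-empty
cell row sums to the scale factor; all-zero cells stay all-zero rather than
becoming NaN.  log2(x + pseudocount) is a separate, explicit step (default
pseudocount 1) used for plotting and PC computation, never implicitly.

Cell QC keeps cells with total UMI ≥ `min_umi`, inclusive (default 500,
the droplet convention; plate-based assays conventionally use 100).

## Differential expression (NB exact test, sSeq style)

* **Size factors** `s_i = total_i / median(total)` over the cells entering
  the comparison.
* **Dispersion**: per-gene method-of-moments on size-factor-normalized
  counts, `phi_g = max(0, (var - mean) / mean^2)` over genes with positive
  mean.
* **Shrinkage**: toward the `zeta_quantile` (default 0.995) quantile `zeta`
  of the `phi_g`, with the MSE-minimizing plug-in weight
  `delta = [Σ(phi_g - mean(phi))² / (G-1)] / [Σ(phi_g - zeta)² / (G-2)]`
  clipped to [0, 1]; `delta = 1` when the denominator degenerates (G < 3 or
  all dispersions at the target).  A mean-target variant of this plug-in
  degenerates to near-total shrinkage (`delta → (G-2)/(G-1)`), which is why
  the quantile target is used.
* **Exact test**: gene group sums are modeled NB(mean `s·mu`, dispersion
  `phi/s`) with `mu` the pooled rate; the two-sided p-value sums the
  probabilities of all splits of the pooled count that are no more likely
  than the observed one, normalized by the total over all splits
  (conditioning on the pooled count).  Ties use a relative tolerance of
  1e-7, the convention of classical exact two-sided tests.  With `phi = 0`
  and equal size factors this reduces exactly to a two-sided binomial test
  conditional on the total — the enumeration oracle used in the tests.
* **Beta switch**: when a gene's summed counts exceed 900 in *both* groups,
  the conditional split fraction is approximated by
  Beta(`s_A·mu/(1+phi·mu)`, `s_B·mu/(1+phi·mu)`) and the two-sided p doubles
  the smaller tail with a 0.5 continuity correction.  The 900 threshold is
  applied to per-group *sums* (per-group means are the other defensible
  reading; sums are what the group-level NB model tests).
* **log2FC** on size-factor-normalized group means with pseudocount 1
  (configurable).  Genes with zero counts in both groups are skipped
  (p = NaN) and excluded from the BH `m`.
* **BH** step-up implemented directly (NaN pass-through); tested against
  the brute-force definition and statsmodels.
* **DEG cutoffs**: adjusted p < 0.05 and |log2FC| ≥ 1; a focal group needs
  ≥ 5 cells, otherwise the call is empty and flagged ineligible.

Null calibration at the defaults (NB mean 5, dispersion 0.1, 50 vs 50
cells): the raw p < 0.05 fraction is ≈ 0.04–0.05 (slightly conservative, as
expected for a discrete conditional test).

## LCM anchoring

Per-cell Pearson correlation against each LCM cell type's mean TPM over the
gene intersection, both sides linear (normalized UMI vs mean TPM; a
log-space option exists but is off by default — with correlations taken on
raw abundances the anchoring is scale-free anyway, since Pearson r is
invariant to positive affine rescaling of either side).  Clusters are
annotated to the argmax of the per-type mean correlation; exact ties go to
the declared type order and are flagged; all-NaN clusters are
"undetermined".

Bulk up-genes of a focal type: mean TPM > 4 and log2FC ≥ 1 (pseudocount 1)
against *every* other type.  Bulk-side significance testing is consumed as
an optional externally computed adjusted-p column (filtered at 0.05 when
present) — this module does not refit a bulk NB GLM.  scUPlcmUP sets are
plain intersections of a cluster's up-DEGs with its matched type's bulk
up-genes, restricted to the shared gene universe when one is supplied.

## Cross-species comparison

Ortholog transcript abundance is the sum of member-gene counts per ortholog
group (all gene copies summed; no best-copy selection); normalization
(per-cell total × 1000) happens *after* aggregation.  Cluster profiles are
per-cluster means of normalized ortholog abundance over the groups shared
by both species (linear, matching the within-species convention);
correlations are all-against-all Pearson, with named exclusions and an
automatic < 5-cell exclusion.  Best hits are row/column argmaxes; a pair is
mutual when the argmaxes reciprocate; exact ties are flagged and broken by
label order.  Differentially expressed ortholog groups appearing in several
clusters are assigned to the cluster with the largest log2FC (declared
tie-break; without fold-change information the group is left unresolved and
flagged).

## Distribution overlap

Pipeline: Euclidean MST → remove cross-species edges (count `k`;
`#subgraphs = k + 1` exactly) → per-subgraph closeness center → weighted
per-species KDE → combined density at every cell → normalize → bin → 
`O = 1 − p_lowest_bin`.

Numerical choices:

* MST via `scipy.sparse.csgraph.minimum_spanning_tree` on the dense
  distance matrix (distances shifted by +1 so duplicate points' zero-length
  edges survive sparsification, then shifted back).  Edge list sorted by
  (length, i, j) for determinism.  Duplicate coordinates are legal.
* Center = node minimizing the sum of within-subgraph tree-path distances
  (Euclidean edge weights; paths in a tree are unique), computed in O(n)
  per component by two-pass re-rooting
  (`S(child) = S(parent) + (n_comp − 2·subtree(child))·w`).  Near-ties
  (relative 1e-9) go to the lowest cell index.  Singletons are their own
  center.
* KDE bandwidths: per axis, `1.06 · min(sd, IQR/1.349) · m^(−1/5)` from the
  center nodes (the kde2d-style normal-reference rule).  If a species has a
  single center or zero spread, the dispersion term falls back to that
  species' cells (warning).  Because the rule is per-axis, the overlap is
  exactly invariant to translation and uniform rescaling but only
  approximately invariant to rotation (observed ±2–3 percentage points at
  n = 300).
* The density is evaluated at cell coordinates by direct kernel evaluation;
  the 250×250 grid (margin = max(5% of range, 4 bandwidths), so each KDE
  keeps ≈ unit mass on it) exists only for map output and plots.
* Normalization: `Z` is the sum of the combined density over the *reference
  species'* cells (default: the first species).  `mode="self"` rescales to
  [0, 1] by the pair's own maximum; `mode="reference"` divides by supplied
  `(Z_ref, max_ref)` from a designated reference pair and clips to [0, 1],
  so multi-pair panels share one scale.  Binning: 500 equal-width bins on
  [0, 1]; the lowest bin is [0, 1/500); bin proportions are proportions of
  *cells*, which makes the disjoint limit behave correctly (nearly all
  cells in the lowest bin on a reference scale).
* Monotonicity experiments (separation steps, divergence levels) use
  reference mode anchored at the coincident / zero-divergence
  configuration; in self mode the statistic deliberately re-scales every
  pair to its own maximum and is therefore not comparable across pairs.

## Lineage tools

* PC-space smoother: `L_ic = Σ_j K(||x_c − x_j||/h) v_ij / Σ_j K`, Gaussian
  kernel, self-weight included, distances in top-10-PC space.  Default
  bandwidth: median distance to the 30th nearest neighbor (no bandwidth is
  dictated by the method itself; this adapts to embedding scale and is
  recorded in the output).  Relative abundance `r_ic = L_ic / mean_c(L_ic)`
  averages to exactly 1 per gene; a gene set's score is the mean `r_ic`
  over its genes (duplicates deduplicated with a warning, absent genes
  reported).
* Nadaraya–Watson regression of expression on pseudotime, Gaussian kernel;
  default bandwidth Silverman's rule on the pseudotime values; queries
  beyond kernel support (all weights underflow) fall back to the nearest
  observation with a warning.
* Moving averages: cells ordered by pseudotime (ties broken by stable cell
  index), window of 21 cells slid one cell at a time — `n − 20` windows —
  with per-feature max and mean over the lineage emitted for display
  rescaling.

## Synthetic generator

`simulate_two_species` emulates the inputs the pipeline consumes, with
planted truth.  Defaults (the study conditions for every recovery test):

| parameter | default | meaning |
|---|---|---|
| clusters | 8 | fusiform FuO→FuEP→FuIP→V, fiber side branch F, ray RO→RP→R |
| cells/cluster/species | 100 | ≥ 5 required (DEG eligibility) |
| ortholog groups | 600 | 25 markers per cluster, 400 background |
| gene copies per group | 1–3 | Dirichlet(5)-split expression |
| marker fold | 8× | smooth logistic pulse over the cluster's pseudotime span |
| marker base level | lognormal(1.0, 0.5) | background lognormal(0, 1); markers emulate well-expressed genes (what makes a gene a usable marker) |
| NB dispersion | U(0.05, 0.3) per group | counts via gamma–Poisson |
| library size | lognormal, median 2000, sigma 0.4 | per-cell totals |
| divergence ε | 0 | fraction of fusiform-program groups re-randomized in species B (nested sets) + proportional embedding displacement |
| embedding noise | 0.35 | around the three branch curves |
| LCM | 3 replicates, lognormal noise 0.15 | terminal-cluster mean profiles on a TPM scale |

The 2D embedding is generated directly from the branch geometry (not via an
embedding algorithm), so overlap tests do not depend on an external
embedding's quirks; the 10-PC coordinates *are* computed from the simulated
counts (PCA of log-normalized expression).  Randomness uses independent
child streams per component (programs, each species' counts, embedding,
LCM), so enlarging one component does not perturb the others; everything is
bit-for-bit reproducible given the seed.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects beyond library-size shifts, dropout beyond NB sampling, realistic
gene-length or GC biases, or non-smooth expression programs.  Passing
recovery tests therefore demonstrates correctness of the pipeline's logic
under NB noise with smooth branch-structured programs — not robustness to
every artifact of real droplet or plate data.

## Known limitations

* The overlap statistic is defined for exactly two labels; multi-species
  panels are handled pairwise against a reference pair's scale constants.
* The exact test enumerates all splits of a gene's pooled count when either
  group's sum is ≤ 900; genes with very large pooled counts concentrated in
  one group are the slowest case.
* Rotation invariance of the overlap is approximate (per-axis bandwidths).
* Bulk (LCM-side) differential significance is consumed, not computed.
* Trajectory inference (pseudotime, lineage curves) and cross-species
  embedding integration are inputs, not outputs, of this package.
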