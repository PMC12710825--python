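# Methods

## Model and procedure

A regulatory element module is a set of CREs on one chromosome whose
accessibility co-varies across cell states. Discovery assumes (i) a
CRE-by-experiment signal matrix whose rows separate broad regulatory
classes, (ii) a CRE-by-pseudobulk-cluster accessibility matrix dense
enough for pairwise Pearson correlations to be meaningful (≥3 clusters),
and (iii) optional binned observed/expected chromatin contacts. The two
stages are deliberately asymmetric: the broad stage uses global signal
similarity with the modularity objective (few, large clusters), the
subclustering stage uses the locality-aware score S = R × (C + D) with
the Constant Potts Model (many small, dense communities — CPM does not
dilute small communities the way modularity does).

### Broad clustering

Per-experiment values above the experiment's 90th percentile are clipped
to it. The clip threshold is computed over the *nonzero* entries of each
column: signal tracks that are mostly zero would otherwise be clipped to
zero wholesale, and for dense columns the two definitions coincide.
Columns are then divided by TMM scaling factors, log(1+x)-transformed,
and projected to ≤50 PCs (features centered, not unit-scaled). The
50-NN graph in PC space becomes an SNN graph whose edge weight is the
Jaccard overlap of the two endpoints' neighbour sets (each set includes
the point itself, so duplicated CREs get weight 1); zero-overlap edges
are dropped. Leiden with the modularity objective and a fixed seed
labels the CREs.

### TMM scaling factors

`tmm_factors` follows the classic recipe — reference column with 75th
percentile closest to the mean of 75th percentiles; per column, a
trimmed (30% per tail on M, 5% per tail on A), precision-weighted mean
of log2 ratios against the reference — but computes the ratios on raw
column values, so the factor absorbs sequencing depth as well as
composition (it equals the classic effective library size up to the
final geometric-mean centring). Dividing a column by its factor is then
a complete normalization step. Two proportional columns with a 2×
depth difference get factors (1/√2, √2).

### Subclustering

Candidate pairs are same-chromosome pairs within 1 Mb, inside one broad
cluster. The window matches the contact cap and the kernel bandwidth
(D < 0.14 beyond 1 Mb); enumerating all pairs per broad cluster would be
quadratic without adding usable signal. R is the Pearson correlation of
the two CREs' pseudobulk rows with negatives and zero-variance rows set
to 0; C is the prepared contact value at the bin pair containing the two
midpoints (0 if absent); D = exp(−x²/2σ²) with σ = 500 kb on the
midpoint distance. Per node the 30 highest-S incident edges are kept,
ties at the cutoff resolved toward the smaller partner index, and the
kept sets are **unioned** (an edge survives if either endpoint kept it;
union preserves more planted structure than intersection and never
creates duplicate weights). Leiden-CPM at resolution 0.5 partitions each
graph; CREs in no graph become singleton modules, so the assignment is a
total function and no module spans chromosomes.

### Contact preparation

Per dataset and chromosome, stored oe entries above their 90th-percentile
quantile are clipped to it (quantile over stored entries — the
unstored zeros of a sparse contact list are not part of the population).
Entries are averaged across datasets with missing entries counted as 0,
min-max scaled per chromosome (a degenerate max = min range maps to 0
everywhere), and pairs beyond 1 Mb dropped. CREs are assigned to 5 kb
bins by midpoint. Scaling is idempotent when re-applied with
clip quantile 1.

### Quantification

Each fragment contributes insertion sites at `start` and `end − 1`
(fragment files are assumed already Tn5-adjusted). Insertion counting
adds the record's duplicate count once per insertion site inside a
region; paired insertion counting adds it at most once per region —
specifically when at least one of the two sites falls inside. A fragment
overlapping two regions of the same group in PIC mode is counted once
per region and the counts are summed into the group feature. Region
lookup uses a per-chromosome array sorted by start with a running
maximum of ends bounding the backward scan. TSS enrichment follows the
±1000 bp window definition (signal: central ±100 bp, background: the
outermost 100 bp of each flank) with a pseudocount of one insertion on
the flank total so the score stays finite; 0 central insertions give 0.

### Annotation

Accessibilities are binarized per cell type at the value where the
descending cumulative sum first reaches 90% of the total; ties at the
threshold are set to 1 (the binarization rule leaves equality open; ≥ is
the stable choice). τ = Σ(1−xᵢ)/(N−1). A CRE binarized to 0 in every
cell type would give τ = N/(N−1) > 1 under the raw formula; such rows
carry no specificity evidence and are assigned τ = 0, which keeps
τ ∈ [0, 1], makes "τ = 1 iff exactly one xᵢ = 1" exact, and removes them
from the weighted sums. Deciles are per cell type: zeros map to 0,
nonzero values to ceil(10·rank/n)/10 with average ranks for ties; decile
transformation happens before duplicate-cell-type averaging (the order
the procedure states them). The module × term score is the τ-weighted
sum of member-CRE deciles, columns of the same ontology term averaged;
each module keeps its top 5 terms whose score is strictly above the 10th
percentile of all (module, term) scores — the strict reading of "the top
90% of scores", which also assigns nothing when every score is zero.

Preranked enrichment is the classic weighted Kolmogorov–Smirnov recipe:
modules sorted by r = sign(log2FC)·(−log10 p) (p floored at 1e-300 to
keep r finite), running-sum with weight |r|, ES the deviation of maximal
magnitude. The null is n_perm random same-size module sets; NES divides
ES by the mean |null ES| of matching sign and the permutation p-value is
(exceedances+1)/(same-sign nulls+1). The multilevel p-value refinement
of modern implementations is not reproduced; at the n_perm used here the
permutation estimate is calibrated (type-I error 0.03–0.07 at α = 0.05
over random term sets, verified in the acceptance suite). BH adjustment
runs across terms; results sort by NES descending, then adjusted p.

### Embedding and metrics

log-normalization: ln(1 + 10⁴·count/cell_total); TF-IDF:
ln(1 + 10⁴·TF·IDF) with IDF = n_cells/n_cells_with_feature (the
log-scaled variant standard for LSI). All-zero cells or features are
left all-zero with a warning rather than dropped, preserving barcode and
feature alignment for downstream joins. Mean–variance feature selection
fits a LOESS (local quadratic, tricube weights, span 0.3) of log10
variance on log10 mean over up to 2,000 features sampled evenly across
the log-mean rank range; residuals are evaluated for all features and
the largest are kept. The LOESS is written in-package because the
selection needs degree-2 local fits. PCA uses a truncated SVD with the
feature means removed inside the matrix–vector products, so the dense
centered matrix never exists; component signs are fixed by making the
largest-magnitude loading positive; LSI is the same SVD without
centering (the depth-correlated first LSI dimension is *not*
auto-dropped — callers choose dimensions). Silhouette and the
Calinski–Harabasz index come from scikit-learn behind this module's
surface (brute-force oracles verify them in the tests); kNN purity is
computed exactly (no approximate search) with ties at the k-th distance
broken by index, and all three metrics are reported per cluster to
counter unbalanced cell type proportions. Singleton clusters get
silhouette 0.

### Linkage statistics

`link_peaks` scores CRE–gene candidates (midpoint within 5×10⁵ bp of any
of the gene's TSS, ≥500 bp from every TSS, detected in ≥10 cells) by the
Pearson correlation across cells, standardized against 200 background
CREs drawn from the same mean-accessibility decile; z is converted to a
two-sided normal p. The original background matching also uses GC
content; GC requires a genome sequence, so matching here is on mean
accessibility only — the generator's synthetic CREs have no defined GC.
Per-dataset link tables combine by keeping, per (cre, gene), the row
with the highest r among significant (p < 0.05) entries, carrying that
dataset's p. The same-gene model is a per-chromosome logistic regression
of same-module on natural-log distance (floored at 1 bp) and a shared-
gene indicator over linked-CRE pairs within 1 Mb; perfect separation is
flagged rather than reported as a coefficient. The pairwise odds ratio
cannot be planted through a module assignment directly, so recovery
checks feed the fitting entry point (`same_gene_logit(pair_table=…)`)
with pair-level simulations. The unlinked ratio is
P(unlinked | single-CRE module)/P(unlinked) from the 2×2 table.

## Synthetic data generator

`generate_world` emulates lineage-specific regulation. Each module draws
a primary cell type with intensity 2 + Gamma(3, 1) and secondary
on-cell-types with probability 0.25 and intensity Gamma(2, 0.5); CREs in
a module share the profile plus N(0, noise_sd) noise (default 0.05),
clipped at 0. Within modules CRE midpoints are spaced
uniform(5 kb, 250 kb); consecutive modules are separated by
uniform(1.1, 1.6) Mb, beyond the 1 Mb candidate window, so modules are
genomically distinct regulatory neighbourhoods. Cells draw a type
uniformly; per-(cell, CRE) fragment counts are Poisson with rates scaled
to a target depth (defaults: 200 cells, 500 fragments/cell, 800 CREs);
fragments place both insertions inside the CRE. Contacts are
Exponential(1) oe values, ×5 within modules, over the bin pairs of CRE
pairs within 1 Mb plus background pairs, drawn independently per
dataset. ChIP-like experiments (3 per cell type) are the cell type's
accessibility column times a log-normal depth factor plus noise. One
gene per module has its TSS 10 kb upstream of the first CRE; expression
is Poisson around the mean accessibility of the planted linked CREs. All
draws descend from one `SeedSequence`, with one child generator per
component, so any output is reproducible in isolation; gzip output is
written with a fixed mtime so files are byte-identical across runs.

What the generator does **not** emulate: Tn5 sequence bias, GC bias,
doublets, overlapping or nested CREs, between-module co-accessibility at
short range, batch effects, or realistic genome geometry. Passing tests
therefore demonstrate algorithmic correctness and recovery under the
stated planted conditions, not performance on real atlas data.

A `profile_mode="one_hot"` option gives each module exactly one active
cell type; with `noise_sd=0` profiles are disjoint and discovery is
expected to recover the planted partition exactly (ARI = 1), which the
acceptance suite asserts.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| σ (distance kernel) | 500,000 bp | Gaussian bandwidth on midpoint distance |
| candidate window / contact cap | 1 Mb | maximal pair span considered |
| contact bin size | 5,000 bp | oe table resolution |
| clip quantile | 0.90 | per-experiment / per-dataset outlier clipping |
| top-k edges | 30 | per-node edge budget in the S graph |
| CPM resolution | 0.5 | Leiden subclustering granularity |
| broad kNN / PCs | 50 / 50 | neighbourhood and PCA size, stage one |
| binarization target | 0.90 | cumulative-sum fraction for τ |
| retention quantile | 0.10 | global cutoff under the top-5 terms |
| normalization scale | 10,000 | log-normalize / TF-IDF scale factor |
| variable features | 20,000 | residual-variance selection budget |
| LOESS span / degree / downsample | 0.3 / 2 / 2,000 | mean–variance fit |
| kNN purity k | 20 | neighbours per cell |
| link distance / min distance / min cells / background | 5×10⁵ / 500 / 10 / 200 | linkage candidates and null |

## Numerical choices and degenerate inputs

- Genomic distance is midpoint-to-midpoint: symmetric and stable under
  small boundary changes (edge-to-edge was the alternative; midpoint
  keeps D continuous when regions resize).
- Population variance (denominator n, zeros included) in streaming
  matrix statistics; sample variance (n−1) in feature selection, where
  the dispersion residual is compared within one matrix and the
  convention cancels.
- Degenerate min-max ranges scale to 0; zero-variance rows correlate to
  0; 0/0 ratios (TSS enrichment, nucleosome signal) are 0.
- Logistic fits with a one-class response or non-finite standard errors
  are returned with a `separated` flag instead of coefficients.
- All seeded stages (world generation, SVD start vector, Leiden,
  background sampling, permutations) are bit-reproducible given the
  seed.

## Problem sizes

The test and acceptance workloads use the generator defaults (800 CREs,
200 modules, 10 cell types, 200 cells), 500-replicate calibration runs
at 500 permutations, 20,000 simulated pairs for the odds-ratio recovery,
and oracle comparisons up to 10⁴ fragments × 10³ regions — sizes at
which every brute-force oracle is exact and the full suite runs in well
under a minute of compute per module.

## Known limitations

- The broad stage's Leiden resolution is the library default; very large
  or very flat signal matrices may need tuning.
- PIC semantics ("counted once per region if either insertion lies
  inside") is one of several variants in circulation; it is
  oracle-tested but not bit-compatible with other tools.
- The enrichment p-value floor is the permutation resolution 1/(n+1);
  very small p-values require raising n_perm.
- Contact preparation consumes pre-binned oe tables; `.hic`/`.cool`
  readers and matrix balancing are out of scope.
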