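# Methods

## Overview

`invscan` implements a genotype-based procedure for locating and
validating candidate chromosomal inversions: (1) a windowed local-PCA /
MDS scan for regions whose relatedness structure departs from the
genome-wide background, (2) karyotype validation of candidate regions by
region-restricted PCA plus heterozygosity contrasts, and (3) EM-based
linkage-disequilibrium analysis in pooled, karyotype-stratified and
network forms. A synthetic-data generator plants inversions with known
truth so every stage is testable without external data.

## Local PCA windows and distances

Windows contain a fixed number of SNPs (default 15) and never span
chromosomes; trailing remainders are dropped. Within a window,
genotypes (0/1/2 alternate-allele dosages) are mean-imputed per locus,
centered, and the sample × sample covariance `C = X Xᵀ` is scaled by
`1/trace(C)` so each window carries unit total variance — without this,
high-diversity windows dominate every distance. The window summary is
the rank-2 truncation `C₂ = λ₁v₁v₁ᵀ + λ₂v₂v₂ᵀ`.

The distance between windows is the Frobenius norm `‖A₂ − B₂‖_F`
between rank-2 reconstructions, computed as
`‖A‖² + ‖B‖² − 2‖W_AᵀW_B‖²_F` with `W = V√Λ` so the n×n matrices are
never formed. This is the only reading of "distance between the first
two principal components" that is invariant to eigenvector sign and to
rotation within degenerate eigenspaces; distances between raw PC
coordinate vectors are not.

Windows whose loci are all monomorphic (zero trace) are flagged
degenerate and excluded from the distance matrix with a log entry.

## Classical MDS and outlier windows

The window distance matrix (genome-wide, all chromosomes jointly) is
embedded by Torgerson scaling: `B = −½ J D² J`, eigendecomposition,
coordinates `v√λ` on the top 4 axes. Negative eigenvalues among the
leading axes are truncated to zero with a warning. Axis signs are fixed
deterministically (largest-magnitude loading positive) so repeated runs
are byte-identical.

Outliers per axis use Tukey fences at hinges ∓/± 1.5 × hinge spread,
with hinges computed exactly as R's `fivenum`/`boxplot.stats` (medians
of sorted halves including the overall median position when n is odd,
averaging straddling order statistics at half-integer positions); a
value is an outlier only when strictly outside a fence, so a constant
vector yields none. Fences are computed genome-wide per axis — every
window competes against the whole-genome background.

A candidate region is a run of outlier windows on one axis and
chromosome with more than `min_outliers` members (default 4, i.e. ≥ 5,
the strict reading of "more than four"), spanning from the first
outlier window's start to the last one's end. Runs tolerate up to
`max_gap_windows` intervening non-outlier windows.

**Gap tolerance default.** The gap parameter exists to keep a single
narrowly non-outlier interior window from splitting a region; its
default here is 1. During null calibration (below) we found that larger
tolerances (e.g. 5) merge *scattered, unrelated* noise outliers into
formal "runs" on compact genomes — with ~32 windows per chromosome a
tolerance of 5 lets almost any five same-axis outliers on one
chromosome form a region, producing false candidates on structure-free
data in roughly 40% of simulations. A tolerance of 1 implements the
stated motivation exactly and restores a clean null (zero candidate
regions in 20/20 null simulations at the default region rule).

**Region rule vs. small regions.** `min_outliers` is exposed because
the "> 4 outlier windows" rule presumes regions that span many windows.
A region containing ~26 SNPs has an expected footprint of two 15-SNP
windows and is *structurally invisible* at the default rule; scans
targeting such regions should use `min_outliers = 1` (≥ 2 outlier
windows). The tests and the acceptance script use exactly that setting
for planted-region recovery, and the default rule for null calibration.
Low-threshold scans also surface short noise runs (the genome-wide MDS
axes are heavy-tailed, a known property of local-PCA distances); the
validation stage is what separates those from real variants.

## Karyotype validation

Region PCA: mean-imputed, centered genotypes restricted to the region's
loci (≥ 5 polymorphic loci required); PC1 oriented so alternate-allele
dosage increases with PC1 (the reference-matching majority group sits
at negative PC1).

PC1 is partitioned into three clusters by *exact* 1-D k-means
(dynamic programming, O(kn²)) — deterministic and initialization-free.
Lloyd-style k-means with fixed percentile initialization was rejected:
with karyotype frequencies near (0.69, 0.28, 0.03), the 90th percentile
of PC1 falls inside the HET cluster, two initial centers land in the
REF cluster, and Lloyd converges to a split of REF with HET and ALT
merged. Exact k-means has no initialization, but its SSE objective
still refuses to isolate a 1–2 sample homokaryote cluster whenever
splitting the large diffuse REF cluster costs less; when the optimal
partition fails the acceptance gate below, a largest-gaps ("natural
breaks") partition is tried instead, which isolates singleton clusters
readily.

**Heterozygosity gate.** A candidate partition is accepted only when
the central cluster's mean heterozygosity exceeds 1.5 × the larger
flank-cluster mean. Heterokaryotypes are heterozygous at essentially
every arrangement-differentiated site, so genuine inversions show
multi-fold excess (≈ 2.5–3× in simulations at default divergence); on
structure-free data, chance excesses of a random tri-partition are a
few percent, and a strict `>` comparison alone passed by luck in about
half of null simulations. The 1.5× margin accepts every true planted
inversion we simulate while rejecting null and sweep-like regions; both
failures return all samples UNASSIGNED with a diagnostic rather than an
error — "outlier region, karyotype validation failed" is itself the
informative outcome for sweep-like candidates.

The flank cluster whose per-locus consensus genotypes are most often
homozygous-reference is labelled REF_HOM. Summaries report counts,
frequencies among assigned samples, group heterozygosity means, and the
arrangement allele frequency `q = (2·n_ALT + n_HET) / (2·n_assigned)`.

**Individual heterozygosity** is the number of the sample's observed
heterozygous calls in the region divided by the number of region loci
heterozygous in at least one cohort member. The cohort-level
denominator makes the statistic a fraction in [0, 1] comparable across
samples; a per-sample non-missing denominator is available via
`het_rates(..., denominator="sample")`.

## Linkage disequilibrium

`r2_em` computes maximum-likelihood gametic haplotype frequencies from
unphased genotype pairs by EM over the 3×3 genotype table: all cells
except the double heterozygote resolve to known haplotypes; the
double-het mass is split between coupling (AB/ab) and repulsion (Ab/aB)
phases in proportion to current frequency estimates. Initialization is
linkage equilibrium; convergence when max |Δfreq| < 1e-8 (cap 1000
iterations, `converged` flag reported). From the converged frequencies,
`D = p_AB − p_A p_B` and `r² = D²/(p_A p_a p_B p_b)`. Pairs with a
locus monomorphic among jointly observed samples are undefined (NaN)
and excluded downstream with reported counts. The batch implementation
vectorizes the EM across all pairs; it agrees with the single-pair
routine to the convergence tolerance and with an independent
grid-search likelihood maximizer to < 1e-4 (the grid search is 1-D in
p_AB because every haplotype resolution preserves observed allele
counts, so any stationary point keeps allele frequencies at their
sample values).

**Stratified LD.** Region mean r² is computed pooled and within each
homokaryote group (groups under 5 samples skipped with a warning).
Undefined pairs are excluded — important within homokaryote subsets,
where many region alleles are fixed; a group in which *every* pair is
monomorphic is reported as having no estimate, the extreme form of
absent within-group LD. Means are reported raw and bias-adjusted
(`max(mean − 1/(2n_group), 0)`): the sampling expectation of r̂²
between independent loci is ≈ 1/(2n) for n diploids, which dominates
raw means in small homokaryote groups (a 5-sample group has a bias
floor of 0.1). The validator's pooled-vs-within criterion
(pooled ≥ 3 × each within mean) uses the adjusted means.

**LD network.** Edges connect pairs with r² ≥ 0.4; nodes in LD with
fewer than 4 others are pruned *iteratively* until stable — single-pass
pruning leaves nodes that violate the stated criterion; the stable
result is the graph's 4-core (computed via networkx). Connected
components are reported with genomic spans. Note the fixed 0.4 edge
threshold presumes near-diagnostic SNPs (arrangement-specific allele
frequency differences close to 1); at the generator's default
divergence (δ = 0.8, see below) pairwise region r² tops out near 0.25
and the network is legitimately empty, so the validator treats the
network as supporting evidence rather than a veto. At δ = 0.95 the
region forms a single component matching the planted loci (Jaccard
≈ 0.9).

## Synthetic data generator

The generator emulates the *post-genotyping* state of a
reduced-representation dataset; there is no coalescent machinery,
because arrangement-conditional independent allele draws already
produce every signal the detection procedure uses.

Defaults: 142 diploid samples; 3 chromosomes × ~494 SNPs × 25 Mb;
one region (chr1:12.54–13.7 Mb, 26 SNPs) where a derived arrangement
segregates at q = 0.17; fraction d = 0.9 of region loci
arrangement-differentiated with allele-frequency gap δ = 0.8;
within-arrangement minor-allele-frequency scales θ_anc = 0.15 (older,
more diverse, reference-matching arrangement) and θ_inv = 0.05
(younger); uniform 2% missing calls.

Mechanics: background loci draw allele frequencies ~ U(0.05, 0.5) and
genotypes Binomial(2, p) independently (HWE, linkage equilibrium).
Each sample draws two arrangement haplotypes Bernoulli(q); region
haplotypes draw alleles independently from their own arrangement's
frequencies — free recombination within arrangements, none between.
At differentiated loci the slack 1 − δ is partitioned between the two
arrangements' minor-allele frequencies in proportion to the θ scales
(derived side smaller), so p_inv − p_anc = δ holds exactly while the
ancestral arrangement stays the more polymorphic — this single
construction yields the heterozygosity ordering HET > REF_HOM >
ALT_HOM and pins the alternate allele to the derived arrangement. At
δ = 0 both arrangements share identical frequencies and the region is
statistically indistinguishable from background (the null
configuration). Positions are uniform within chromosomes, background
positions excluded from the region interval.

A hard-sweep surrogate (`simulate_sweep_region`) puts a single
low-diversity haplotype at fixation in the region — no karyotype
classes — as the negative control for the validation gate.

What the generator does **not** emulate: background LD decay (no stage
depends on it), genotyping error beyond uniform missingness, population
substructure, and the allele-frequency heterogeneity of real diagnostic
SNP panels. Consequently, passing tests demonstrate the pipeline's
behavior under its own model assumptions, not performance on real
cohorts with, e.g., related individuals or batch effects.

## Calibration and problem sizes

All stochastic claims are checked over 20 independent simulations at
the defaults above: planted-region recovery within ±1 window with
karyotype accuracy ≥ 95% in ≥ 18/20 runs (observed 18–20/20 across
batches; the residual failures are draws in which zero or one
ALT-homokaryote was sampled — at q² ≈ 2.9% and n = 142 the third
cluster occasionally does not exist to find — or a marginal noise
outlier adjacent to the region stretching a boundary by two windows);
null calibration (δ = 0) with zero candidate regions at the default
region rule in ≥ 18/20 (observed 20/20). The EM-vs-grid oracle runs
200 random tables of 50 samples. The acceptance script performs all of
the above in ~30 s on one CPU; genome sizes (3 × 494 SNPs, with one
39-chromosome configuration for the genome-wide-PCA dilution check)
were chosen to keep a full multi-seed calibration in that budget while
preserving the per-chromosome SNP density of the motivating datasets.

## Known limitations

- The first/last-outlier-window region rule inherits the scale of
  windows: boundaries are resolved to ±1 window at best, and a noise
  outlier adjacent to a true region can stretch a boundary.
- Karyotype validation needs all three karyotypes present; cohorts in
  which the rare homokaryote is unsampled are reported UNASSIGNED by
  design (the variant is detectable, its karyotypes are not).
- r² estimates in groups of ≲ 5 samples are bias-dominated even after
  adjustment; within-group LD statements for the rare homokaryote are
  weak evidence at realistic sample sizes.
- Inter-chromosomal LD is supported by the estimator but off by default
  for tractability; within-chromosome tables are the analysis surface.
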