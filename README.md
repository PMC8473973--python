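# invscan

Discovery and validation of candidate chromosomal inversions (and other
recombination-suppressing structural variants) from diploid SNP
genotypes, as produced by RAD-seq / GBS genotyping pipelines.

A polymorphic inversion suppresses recombination in heterokaryotypes, so
the two arrangements diverge and leave a characteristic multi-signal
footprint in population genotype data:

- **Local PCA / MDS outliers.** The genome is cut into non-overlapping
  windows of 15 SNPs; each window's sample relatedness is summarized by
  the rank-2 (top two PCs) reconstruction of its trace-normalized
  covariance matrix. Frobenius distances between window summaries are
  embedded by classical (Torgerson) MDS into four axes, and windows
  falling outside the Tukey fences (hinges ± 1.5 × IQR, R
  `boxplot.stats` convention) on any axis are flagged. A run of more
  than `min_outliers` outlier windows on one chromosome becomes a
  candidate region spanning first-to-last outlier window.
- **Three karyotype clusters.** PCA restricted to the region separates
  samples into the two arrangement homozygotes and the heterokaryotypes.
  PC1 is clustered with an exact (dynamic-programming) 1-D 3-means, and
  the labelling is accepted only if the central cluster's mean
  heterozygosity clearly exceeds both flanks — the gate that tells an
  inversion apart from a selective sweep.
- **Heterozygosity.** Per sample, the fraction of the region's
  heterozygous sites at which the sample is heterozygous:
  HET > REF_HOM > ALT_HOM is expected when the derived arrangement is
  younger (less diverse) than the ancestral one.
- **Linkage disequilibrium.** Gametic r² = D²/(p_A p_a p_B p_b) is
  estimated from unphased genotypes by EM over the 3×3 genotype table.
  Pooled across karyotypes, region LD is strongly elevated; within each
  homokaryotype group it collapses to background. An LD network
  (edges r² ≥ 0.4, nodes kept while in LD with ≥ 4 others) localizes
  high-LD clusters along a chromosome.

A synthetic-data generator plants an inversion with known truth
(karyotype labels, arrangement allele frequencies, region coordinates),
so the entire pipeline is testable end to end without external data.

## Worked example

```sh
python examples/01_simulate_and_scan.py
```

```
simulated 142 samples x 1482 SNPs; planted region chr1:12591884-13668485
after MAF >= 0.05 filter: 1461 SNPs

96 windows scanned; 5 candidate region(s):
chrom    start      end axis  n_outlier_windows overlapping_axes
 chr1 12461490 13783909 MDS1                  2             MDS2
 chr1 12461490 13783909 MDS2                  2             MDS1
 ...
```

The MDS1/MDS2 candidate matches the planted region to within one window
on each side. Karyotyping that region (`examples/02_karyotype_region.py`)
prints:

```
karyotype counts: {'REF_HOM': 94, 'HET': 46, 'ALT_HOM': 2, 'UNASSIGNED': 0}
arrangement allele frequency q = 0.1761 (simulated 0.17)
group mean heterozygosity: {'REF_HOM': 0.277, 'HET': 0.751, 'ALT_HOM': 0.038}
accuracy vs simulator truth: 100.0%
```

i.e. karyotype frequencies near the Hardy–Weinberg proportions for
q = 0.17, with the heterokaryotype group ~2.7× more heterozygous than
either homokaryote group. The LD contrast (`examples/03_ld_contrast.py`):

```
pooled   n=142  mean r2 = 0.1665 (adjusted 0.1630; 325 defined pairs)
REF_HOM  n= 94  mean r2 = 0.0118 (adjusted 0.0065; 325 defined pairs)
background chromosome mean r2 = 0.0076 (121771 pairs)
```

Pooled region LD is ~20× the within-karyotype and background level —
elevated LD that disappears once karyotypes are separated.

The same stages are available from the shell:

```sh
invscan simulate --outdir fixture --seed 1
invscan scan fixture/genotypes.vcf --min-outliers 1 --max-gap-windows 1
invscan validate fixture/genotypes.vcf --chrom chr1 \
    --start 12540000 --end 13700000
invscan ld fixture/genotypes.vcf --chrom chr1 --min-r2-report 0.3 --out ld.tsv
```

`invscan validate` prints a per-criterion report (three clusters, het
ordering, pooled ≫ within LD, LD network span) and an overall verdict:
`SV-consistent`, `sweep-like/ambiguous`, or `under-resolution`.

## Scope

Input is a VCF of biallelic SNP genotypes (GT only; phase ignored).
Upstream read processing, alignment and genotype calling, and downstream
gene annotation are out of scope. See `docs/methods.md` for the model,
parameter defaults, numerical choices and known limitations.
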