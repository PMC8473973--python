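"""Karyotype a candidate region and check it against simulator truth.

Region PCA separates samples into three clusters (the two arrangement
homozygotes and the heterokaryotypes); assignments are accepted only
when the central cluster shows a clear heterozygosity excess.
"""

import numpy as np

import invscan as iv

gm, truth = iv.simulate_dataset(iv.SimConfig(seed=1))
region = iv.CandidateRegion(
    chrom=truth.chrom, start=truth.region_start, end=truth.region_end,
    axis="MDS1", member_windows=[], n_outlier_windows=0,
)

coords = iv.region_pca(gm, region)
region_gm = iv.subset_region(gm, region.chrom, region.start, region.end)
assignments, diag = iv.assign_karyotypes(coords, region_gm)
summary = iv.summarize_karyotypes(assignments)

acc = np.mean([a.karyotype.value == t for a, t in zip(assignments, truth.karyotypes)])
print("karyotype counts:", summary.counts)
print("frequencies     :", {k: round(v, 3) for k, v in summary.frequencies.items()})
print(f"arrangement allele frequency q = {summary.q:.4f} (simulated 0.17)")
print("group mean heterozygosity:",
      {k: round(v, 3) for k, v in summary.mean_het.items()})
print(f"accuracy vs simulator truth: {100 * acc:.1f}%")
print("\nThe three frequencies approximate HWE proportions (1-q)^2, 2q(1-q),",
      "q^2, and the HET group's heterozygosity far exceeds both homokaryote",
      "groups — the inversion signature the validation gate requires.")
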