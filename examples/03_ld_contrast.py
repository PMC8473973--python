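"""Pooled vs within-karyotype linkage disequilibrium in the region.

Suppressed recombination between arrangements makes region LD high when
all samples are pooled, while within each homokaryotype group loci
recombine freely and LD stays at background level. Means are shown raw
and bias-adjusted (subtracting the ~1/(2n) sampling floor of r2-hat).
"""

import invscan as iv

gm, truth = iv.simulate_dataset(iv.SimConfig(seed=1))
assignments = [
    iv.KaryotypeAssignment(s, 0.0, 0.0, iv.Karyotype(k), 0.0)
    for s, k in zip(gm.samples, truth.karyotypes)
]

strat = iv.stratified_ld(gm, truth.region_locus_indices, assignments)
for name, g in strat["groups"].items():
    print(f"{name:8s} n={g['n_samples']:3d}  mean r2 = {g['mean_r2']:.4f} "
          f"(adjusted {g['mean_r2_adjusted']:.4f}; "
          f"{g['n_pairs_defined']} defined pairs)")
for name in strat["skipped"]:
    print(f"{name:8s} skipped (fewer than 5 samples)")

bg = iv.chromosome_ld(gm, "chr3")  # a background-only chromosome
print(f"\nbackground chromosome mean r2 = {bg.attrs['mean_r2']:.4f} "
      f"({len(bg)} pairs)")
print("\nPooled region LD sits far above both the within-karyotype and the",
      "background means — elevated LD that vanishes once karyotypes are",
      "separated is the expected footprint of a segregating inversion.")
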