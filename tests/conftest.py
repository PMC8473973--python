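import numpy as np
import pytest

import invscan as iv


@pytest.fixture(scope="session")
def default_sim():
    """One default-conditions simulation shared across read-only tests."""
    gm, truth = iv.simulate_dataset(iv.SimConfig(seed=1))
    return gm, truth


@pytest.fixture(scope="session")
def filtered_sim(tmp_path_factory, default_sim):
    """Default simulation pushed through the VCF + MAF-filter path."""
    gm, truth = default_sim
    path = tmp_path_factory.mktemp("fixture") / "sim.vcf"
    iv.write_vcf(gm, path)
    return iv.read_vcf(path, min_maf=0.05), truth


def truth_assignments(gm, truth):
    """Karyotype assignments built directly from simulator truth labels."""
    return [
        iv.KaryotypeAssignment(s, 0.0, 0.0, iv.Karyotype(k), 0.0)
        for s, k in zip(gm.samples, truth.karyotypes)
    ]


def window_ordinal(ws, chrom, bp):
    """Ordinal (within-chromosome) window position containing/bracketing bp."""
    wins = [w for w in ws.windows if w.chrom == chrom]
    for k, w in enumerate(wins):
        if w.start_bp <= bp <= w.end_bp:
            return k
    for k, w in enumerate(wins):
        if bp < w.start_bp:
            return k - 0.5
    return len(wins) - 0.5


def recover_planted_region(seed, min_outliers=1, max_gap_windows=1):
    """Full pipeline run on one simulated dataset (VCF round trip included).

    Returns (recovered_within_1_window, karyotype_accuracy, n_regions).
    Recovery means: some reported candidate region overlaps the planted
    region with both boundaries within one window of truth.
    """
    import tempfile
    from pathlib import Path

    gm0, truth = iv.simulate_dataset(iv.SimConfig(seed=seed))
    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "sim.vcf"
        iv.write_vcf(gm0, p)
        gm = iv.read_vcf(p, min_maf=0.05)
    res = iv.run_scan(
        iv.PipelineConfig(min_outliers=min_outliers, max_gap_windows=max_gap_windows),
        gm=gm,
    )
    best = None
    for r in res.regions:
        if r.chrom != truth.chrom:
            continue
        if r.start > truth.region_end or r.end < truth.region_start:
            continue
        e1 = abs(
            window_ordinal(res.window_set, r.chrom, r.start)
            - window_ordinal(res.window_set, r.chrom, truth.region_start)
        )
        e2 = abs(
            window_ordinal(res.window_set, r.chrom, r.end)
            - window_ordinal(res.window_set, r.chrom, truth.region_end)
        )
        if e1 <= 1 and e2 <= 1:
            if best is None or r.n_outlier_windows > best.n_outlier_windows:
                best = r
    if best is None:
        return False, float("nan"), len(res.regions)
    region_gm = iv.subset_region(gm, best.chrom, best.start, best.end)
    assignments, _ = iv.assign_karyotypes(iv.region_pca(gm, best), region_gm)
    acc = float(
        np.mean([a.karyotype.value == t for a, t in zip(assignments, truth.karyotypes)])
    )
    return True, acc, len(res.regions)
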