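import numpy as np
import pytest
from sklearn.metrics import silhouette_score

import invscan as iv
from invscan.karyotype import ckmeans_1d, gap_split_1d, _consensus_ref_fraction


def _region_gm_with_het_middle(n_ref=70, n_het=25, n_alt=5, n_loci=12, seed=0):
    """Three genotype blocks: 0s, 1s, 2s at every locus (idealized region)."""
    rng = np.random.default_rng(seed)
    calls = np.vstack(
        [np.zeros((n_ref, n_loci)), np.ones((n_het, n_loci)),
         np.full((n_alt, n_loci), 2)]
    ).astype(np.int8)
    n = n_ref + n_het + n_alt
    loci = [iv.Locus("chr1", 100 + 10 * j) for j in range(n_loci)]
    gm = iv.GenotypeMatrix([f"S{i}" for i in range(n)], loci, calls)
    pc1 = np.concatenate(
        [rng.normal(-1, 0.01, n_ref), rng.normal(0, 0.01, n_het),
         rng.normal(1, 0.01, n_alt)]
    )
    return gm, pc1


class TestClustering1D:
    def test_ckmeans_point_masses(self):
        x = np.concatenate([np.full(70, -1.0), np.zeros(25), np.ones(5)])
        x += np.linspace(0, 1e-6, 100)  # break exact ties deterministically
        labels = ckmeans_1d(x, 3)
        assert np.bincount(labels).tolist() == [70, 25, 5]

    def test_gap_split_isolates_singleton(self):
        x = np.concatenate([np.random.default_rng(0).normal(-1, 0.2, 94),
                            np.random.default_rng(1).normal(1, 0.2, 45), [3.5]])
        labels = gap_split_1d(x, 3)
        assert (labels == 2).sum() == 1 and labels[-1] == 2

    def test_labels_ordered_by_center(self):
        x = np.array([5.0, -5.0, 0.1, 4.9, -4.8, 0.0, 0.2, 5.1, -5.2, -0.1])
        for fn in (ckmeans_1d, gap_split_1d):
            labels = fn(x, 3)
            centers = [x[labels == c].mean() for c in range(3)]
            assert centers == sorted(centers)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            ckmeans_1d(np.array([1.0, 1.0, 2.0, 2.0]), 3)


class TestRegionPca:
    def test_identical_samples_embed_at_origin(self):
        gm = iv.GenotypeMatrix(
            ["A", "B", "C"],
            [iv.Locus("chr1", 100 + i) for i in range(6)],
            np.ones((3, 6), dtype=np.int8),
        )
        assert np.allclose(iv.region_pca(gm), 0.0)

    def test_three_clusters_in_region_but_not_genome_wide(self):
        # full-genome geometry (39 chromosomes x ~494 SNPs) so the 26
        # region SNPs are diluted as they are in a real RAD-seq dataset
        gm, truth = iv.simulate_dataset(iv.SimConfig(seed=1, n_chromosomes=39))
        region = iv.CandidateRegion(
            chrom=truth.chrom, start=truth.region_start, end=truth.region_end,
            axis="MDS1", member_windows=[], n_outlier_windows=0,
        )
        labels = np.array(truth.karyotypes)
        region_coords = iv.region_pca(gm, region)
        assert silhouette_score(region_coords[:, :1], labels) > 0.8
        genome_coords = iv.region_pca(gm)
        assert silhouette_score(genome_coords[:, :1], labels) < 0.3

    def test_pc1_oriented_by_alt_dosage(self, filtered_sim):
        gm, truth = filtered_sim
        region = iv.CandidateRegion(
            chrom=truth.chrom, start=truth.region_start, end=truth.region_end,
            axis="MDS1", member_windows=[], n_outlier_windows=0,
        )
        pc1 = iv.region_pca(gm, region)[:, 0]
        k = np.array(truth.karyotypes)
        assert pc1[k == "REF_HOM"].mean() < pc1[k == "HET"].mean()
        assert pc1[k == "HET"].mean() < pc1[k == "ALT_HOM"].mean()

    def test_under_resolution_region_errors(self, default_sim):
        gm, _ = default_sim
        region = iv.CandidateRegion(
            chrom="chr2", start=1, end=2, axis="MDS1",
            member_windows=[], n_outlier_windows=0,
        )
        with pytest.raises(ValueError, match="resolution"):
            iv.region_pca(gm, region)


class TestHeterozygosity:
    def test_fully_het_sample_rate_one(self):
        gm, _ = _region_gm_with_het_middle()
        assert iv.individual_heterozygosity(gm, "S70") == 1.0

    def test_no_het_calls_rate_zero(self):
        gm, _ = _region_gm_with_het_middle()
        assert iv.individual_heterozygosity(gm, "S0") == 0.0

    def test_denominator_is_cohort_level(self):
        # locus 2 has het calls in nobody -> excluded from denominator
        calls = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8)
        gm = iv.GenotypeMatrix(
            ["A", "B", "C"], [iv.Locus("chr1", p) for p in (10, 20, 30)], calls
        )
        rates = iv.het_rates(gm)
        np.testing.assert_allclose(rates, [1.0, 0.5, 0.0])

    def test_group_ordering_on_simulated_inversion(self, default_sim):
        gm, truth = default_sim
        region_gm = gm.take_loci(truth.region_locus_indices)
        rates = iv.het_rates(region_gm)
        k = np.array(truth.karyotypes)
        means = {g: rates[k == g].mean() for g in ("REF_HOM", "HET", "ALT_HOM")}
        # heterokaryotypes most heterozygous; ancestral homokaryotypes
        # more diverse than the younger derived arrangement
        assert means["HET"] > means["REF_HOM"] > means["ALT_HOM"]


class TestAssignment:
    def test_point_mass_split_70_25_5(self):
        gm, pc1 = _region_gm_with_het_middle()
        assignments, diag = iv.assign_karyotypes(np.column_stack([pc1, pc1 * 0]), gm)
        counts = {k: sum(a.karyotype == k for a in assignments) for k in iv.Karyotype}
        assert counts[iv.Karyotype.REF_HOM] == 70
        assert counts[iv.Karyotype.HET] == 25
        assert counts[iv.Karyotype.ALT_HOM] == 5

    def test_no_het_excess_means_unassigned(self):
        gm, pc1 = _region_gm_with_het_middle()
        calls = gm.calls.copy()
        calls[70:95] = 0  # strip the central group's heterozygosity
        gm2 = iv.GenotypeMatrix(gm.samples, gm.loci, calls)
        assignments, diag = iv.assign_karyotypes(np.column_stack([pc1, pc1 * 0]), gm2)
        assert all(a.karyotype == iv.Karyotype.UNASSIGNED for a in assignments)
        assert "heterozygosity" in diag["gate"]

    def test_accuracy_on_simulated_inversion(self, filtered_sim):
        gm, truth = filtered_sim
        region = iv.CandidateRegion(
            chrom=truth.chrom, start=truth.region_start, end=truth.region_end,
            axis="MDS1", member_windows=[], n_outlier_windows=0,
        )
        region_gm = iv.subset_region(gm, truth.chrom, truth.region_start,
                                     truth.region_end)
        assignments, _ = iv.assign_karyotypes(iv.region_pca(gm, region), region_gm)
        acc = np.mean(
            [a.karyotype.value == t for a, t in zip(assignments, truth.karyotypes)]
        )
        assert acc >= 0.95

    def test_labels_invariant_to_sign_flip_and_permutation(self):
        gm, pc1 = _region_gm_with_het_middle()
        coords = np.column_stack([pc1, pc1 * 0])
        base, _ = iv.assign_karyotypes(coords, gm)
        flipped, _ = iv.assign_karyotypes(-coords[:, [0, 1]] * [1, -1], gm)
        assert [a.karyotype for a in base] == [a.karyotype for a in flipped]
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(pc1))
        gm_p = iv.GenotypeMatrix(
            [gm.samples[i] for i in perm], gm.loci, gm.calls[perm]
        )
        permuted, _ = iv.assign_karyotypes(coords[perm], gm_p)
        by_sample = {a.sample: a.karyotype for a in permuted}
        assert all(a.karyotype == by_sample[a.sample] for a in base)

    def test_null_region_not_karyotyped(self):
        gm, truth = iv.simulate_dataset(iv.SimConfig(seed=5, delta=0.0))
        region_gm = gm.take_loci(truth.region_locus_indices)
        region = iv.CandidateRegion(
            chrom=truth.chrom, start=truth.region_start, end=truth.region_end,
            axis="MDS1", member_windows=[], n_outlier_windows=0,
        )
        assignments, _ = iv.assign_karyotypes(iv.region_pca(gm, region), region_gm)
        assert all(a.karyotype == iv.Karyotype.UNASSIGNED for a in assignments)

    def test_consensus_ref_fraction(self):
        calls = np.array([[0, 2, 0], [0, 2, 1], [0, 2, 0]], dtype=np.int8)
        assert _consensus_ref_fraction(calls) == pytest.approx(2 / 3)


class TestSummary:
    def test_frequencies_and_q_exact(self):
        gm, pc1 = _region_gm_with_het_middle()
        assignments, _ = iv.assign_karyotypes(np.column_stack([pc1, pc1 * 0]), gm)
        s = iv.summarize_karyotypes(assignments)
        assert s.frequencies == {"REF_HOM": 0.70, "HET": 0.25, "ALT_HOM": 0.05}
        assert s.q == (2 * 5 + 25) / 200  # 0.175 exactly

    def test_all_ref_hom_gives_q_zero(self):
        assignments = [
            iv.KaryotypeAssignment(f"S{i}", -1.0, 0.0, iv.Karyotype.REF_HOM, 0.0)
            for i in range(12)
        ]
        assert iv.summarize_karyotypes(assignments).q == 0.0

    def test_recovered_q_near_simulated_frequency(self, filtered_sim):
        gm, truth = filtered_sim
        region = iv.CandidateRegion(
            chrom=truth.chrom, start=truth.region_start, end=truth.region_end,
            axis="MDS1", member_windows=[], n_outlier_windows=0,
        )
        region_gm = iv.subset_region(gm, truth.chrom, truth.region_start,
                                     truth.region_end)
        assignments, _ = iv.assign_karyotypes(iv.region_pca(gm, region), region_gm)
        s = iv.summarize_karyotypes(assignments)
        # binomial 95% CI around q=0.17 with 2n=284 draws
        half = 1.96 * np.sqrt(0.17 * 0.83 / 284)
        assert abs(s.q - 0.17) <= half + 1e-9
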