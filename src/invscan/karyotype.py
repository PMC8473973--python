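"""Karyotype validation of a candidate region.

A genuine inversion (or similar recombination-suppressing variant)
segregating at frequency q produces three PCA clusters over the region's
loci — the two homokaryotype groups and the heterokaryotypes between
them — plus a heterozygosity excess in the central (HET) cluster. This
module runs the region PCA, clusters PC1 with an exact 1-D k-means, and
only accepts the three-group labelling when the central cluster really
is the most heterozygous; otherwise every sample is returned UNASSIGNED,
which is how sweep-like outlier regions are told apart from true
structural variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .outliers import CandidateRegion


class Karyotype(str, Enum):
    REF_HOM = "REF_HOM"
    HET = "HET"
    ALT_HOM = "ALT_HOM"
    UNASSIGNED = "UNASSIGNED"


@dataclass
class KaryotypeAssignment:
    sample: str
    pc1: float
    pc2: float
    karyotype: Karyotype
    het_rate: float


@dataclass
class KaryotypeSummary:
    """Counts, frequencies, arrangement allele frequency q, group het means.

    ``q = (2 n_ALT + n_HET) / (2 n_assigned)`` — the frequency of the
    alternative arrangement among assigned samples. Frequencies are over
    assigned samples and sum to 1.
    """

    counts: dict[str, int]
    frequencies: dict[str, float]
    q: float
    mean_het: dict[str, float]
    n_assigned: int


# ----------------------------------------------------------------------


def region_pca(
    gm: GenotypeMatrix, region: CandidateRegion | None = None
) -> np.ndarray:
    """First two PCs of the samples over region loci (or all loci).

    Genotypes are mean-imputed per locus and centered; PCs are
    eigenvectors of the sample covariance scaled by the singular values,
    so PC1/PC2 are the usual score coordinates. PC1 is oriented so that
    samples carrying more alternate alleles score higher (the
    reference-matching majority group sits at negative PC1); PC2's sign
    is fixed by its largest-magnitude loading.

    Requires >= 5 polymorphic loci when a region is given.
    """
    from .genotypes import subset_region

    sub = subset_region(gm, region.chrom, region.start, region.end) if region else gm
    X = sub.calls.astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    Xc = X - X.mean(axis=0)
    poly = (Xc.std(axis=0) > 0).sum()
    if region is not None and poly < 5:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} has only "
            f"{poly} polymorphic loci; below karyotyping resolution (need >= 5)"
        )
    if Xc.size == 0 or not Xc.any():
        return np.zeros((sub.n_samples, 2))
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, len(s))
    coords = np.zeros((sub.n_samples, 2))
    coords[:, :k] = U[:, :k] * s[:k]
    # orientation: PC1 increases with alternate-allele dosage
    dosage = X.mean(axis=1)
    if np.cov(coords[:, 0], dosage)[0, 1] < 0:
        coords[:, 0] = -coords[:, 0]
    col = coords[:, 1]
    if col.any() and col[np.argmax(np.abs(col))] < 0:
        coords[:, 1] = -col
    return coords


# ----------------------------------------------------------------------


def ckmeans_1d(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Exact (optimal within-cluster-SSE) 1-D k-means by dynamic programming.

    Deterministic and initialization-free; clusters are contiguous in
    sorted order, so labels are returned ordered by cluster center
    (label 0 = lowest). O(k n^2).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if len(np.unique(x)) < k:
        raise ValueError(f"need >= {k} distinct values for {k} clusters")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    pre = np.concatenate([[0.0], np.cumsum(xs)])
    pre2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i: int, j: int) -> float:  # cost of segment xs[i..j] inclusive
        s = pre[j + 1] - pre[i]
        s2 = pre2[j + 1] - pre2[i]
        m = j - i + 1
        return s2 - s * s / m

    INF = np.inf
    D = np.full((k, n), INF)
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        D[0, j] = sse(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = INF, c
            for i in range(c, j + 1):
                v = D[c - 1, i - 1] + sse(i, j)
                if v < best:
                    best, arg = v, i
            D[c, j] = best
            back[c, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n - 1
    for c in range(k - 1, -1, -1):
        i = back[c, j] if c > 0 else 0
        labels_sorted[i : j + 1] = c
        j = i - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


# ----------------------------------------------------------------------


def gap_split_1d(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Partition 1-D values at the k-1 largest gaps between sorted values.

    Deterministic "natural breaks" clustering: robust to extreme cluster
    size imbalance (it happily isolates a singleton cluster, which
    SSE-optimal k-means refuses to do when a large diffuse cluster can
    be split instead). Labels are ordered by cluster center.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if len(np.unique(x)) < k:
        raise ValueError(f"need >= {k} distinct values for {k} clusters")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    gaps = np.diff(xs)
    cuts = np.sort(np.argsort(gaps)[-(k - 1):])  # cut after these sorted indices
    labels_sorted = np.zeros(n, dtype=int)
    for c in cuts:
        labels_sorted[c + 1:] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def individual_heterozygosity(region_gm: GenotypeMatrix, sample: str) -> float:
    """Fraction of the region's heterozygous sites at which ``sample`` is het.

    Numerator: this sample's observed het (code 1) calls among region
    loci. Denominator: the number of region loci heterozygous in at
    least one sample (cohort-level, sample-independent), so rates are
    comparable across individuals and lie in [0, 1]. Returns NaN when
    no region locus shows any het call.
    """
    i = region_gm.samples.index(sample)
    return float(het_rates(region_gm)[i])


def het_rates(
    region_gm: GenotypeMatrix, denominator: str = "cohort"
) -> np.ndarray:
    """Per-sample region heterozygosity rates (vectorized).

    ``denominator="cohort"`` (default): region loci het in >= 1 sample.
    ``denominator="sample"``: each sample's own non-missing locus count.
    """
    if region_gm.n_loci == 0:
        return np.full(region_gm.n_samples, np.nan)
    het = region_gm.calls == 1
    if denominator == "cohort":
        denom_loci = het.any(axis=0)
        d = int(denom_loci.sum())
        if d == 0:
            return np.full(region_gm.n_samples, np.nan)
        return het[:, denom_loci].sum(axis=1) / d
    if denominator == "sample":
        nm = (region_gm.calls != MISSING).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(nm > 0, het.sum(axis=1) / nm, np.nan)
    raise ValueError("denominator must be 'cohort' or 'sample'")


# ----------------------------------------------------------------------


def _consensus_ref_fraction(calls: np.ndarray) -> float:
    """Fraction of loci whose within-group consensus genotype is hom-ref."""
    n_loci = calls.shape[1]
    ref_like = 0
    for j in range(n_loci):
        col = calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=3)
        if counts.argmax() == 0:
            ref_like += 1
    return ref_like / max(n_loci, 1)


def assign_karyotypes(
    coords: np.ndarray,
    region_gm: GenotypeMatrix,
    het_excess_factor: float = 1.5,
) -> tuple[list[KaryotypeAssignment], dict]:
    """Cluster PC1 into three groups and validate them as karyotypes.

    Clustering is exact 1-D 3-means (deterministic); if its partition
    fails the gate below, a largest-gaps partition is tried instead
    (SSE-optimal k-means will not isolate a 1-2 sample homokaryotype
    cluster when splitting the large diffuse REF cluster costs less).
    The central cluster is accepted as HET only if its mean
    heterozygosity strictly exceeds both flank clusters' means;
    otherwise all samples come back UNASSIGNED with a diagnostic — the
    gate that keeps sweep-like or unstructured regions from being
    karyotyped. The flank whose
    consensus genotypes best match the reference alleles is REF_HOM.

    Returns (assignments, diagnostics dict).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1 and coords.shape[1] > 2:
        coords = coords.T
    pc1 = coords[:, 0]
    pc2 = coords[:, 1] if coords.shape[1] > 1 else np.zeros_like(pc1)
    n = len(pc1)
    if n < 10:
        raise ValueError("karyotype assignment needs >= 10 samples")
    if n != region_gm.n_samples:
        raise ValueError("coordinate count does not match sample count")

    rates = het_rates(region_gm)
    diag: dict = {"gate": None}

    def unassigned(reason: str) -> tuple[list[KaryotypeAssignment], dict]:
        diag["gate"] = reason
        out = [
            KaryotypeAssignment(s, float(pc1[i]), float(pc2[i]),
                                Karyotype.UNASSIGNED, float(rates[i]))
            for i, s in enumerate(region_gm.samples)
        ]
        return out, diag

    labels = None
    first_diag = None
    for method in (ckmeans_1d, gap_split_1d):
        try:
            cand = method(pc1, k=3)
        except ValueError as e:
            return unassigned(f"clustering degenerate: {e}")
        def _group_het(c):
            vals = rates[cand == c]
            vals = vals[np.isfinite(vals)]
            return float(vals.mean()) if vals.size else np.nan

        mean_het = np.array([_group_het(c) for c in range(3)])
        if mean_het[1] > het_excess_factor * max(mean_het[0], mean_het[2]):
            labels = cand
            diag["cluster_method"] = method.__name__
            diag["cluster_mean_het"] = mean_het.tolist()
            diag["cluster_sizes"] = np.bincount(cand, minlength=3).tolist()
            break
        if first_diag is None:
            first_diag = mean_het
    if labels is None:
        return unassigned(
            "central PC1 cluster lacks heterozygosity excess "
            f"(group het means {np.round(first_diag, 4).tolist()}, requires "
            f"{het_excess_factor}x both flanks); three-cluster karyotype "
            "structure not supported"
        )

    ref0 = _consensus_ref_fraction(region_gm.calls[labels == 0])
    ref2 = _consensus_ref_fraction(region_gm.calls[labels == 2])
    if ref0 == ref2:  # tie-break on mean dosage
        d0 = region_gm.calls[labels == 0]
        d2 = region_gm.calls[labels == 2]
        ref_label = 0 if np.mean(d0[d0 != MISSING]) <= np.mean(d2[d2 != MISSING]) else 2
    else:
        ref_label = 0 if ref0 > ref2 else 2
    mapping = {
        ref_label: Karyotype.REF_HOM,
        1: Karyotype.HET,
        2 - ref_label: Karyotype.ALT_HOM,
    }
    diag["ref_consensus_fractions"] = {"low_cluster": ref0, "high_cluster": ref2}
    out = [
        KaryotypeAssignment(s, float(pc1[i]), float(pc2[i]),
                            mapping[labels[i]], float(rates[i]))
        for i, s in enumerate(region_gm.samples)
    ]
    return out, diag


def summarize_karyotypes(assignments: list[KaryotypeAssignment]) -> KaryotypeSummary:
    """Counts, frequencies, q and group het means over assigned samples."""
    if not assignments:
        raise ValueError("no assignments given")
    assigned = [a for a in assignments if a.karyotype != Karyotype.UNASSIGNED]
    counts = {k.value: 0 for k in Karyotype}
    for a in assignments:
        counts[a.karyotype.value] += 1
    n = len(assigned)
    if n == 0:
        raise ValueError("all samples UNASSIGNED; nothing to summarize")
    freqs = {
        k: counts[k] / n
        for k in (Karyotype.REF_HOM.value, Karyotype.HET.value, Karyotype.ALT_HOM.value)
    }
    q = (2 * counts[Karyotype.ALT_HOM.value] + counts[Karyotype.HET.value]) / (2.0 * n)
    mean_het = {}
    for k in (Karyotype.REF_HOM, Karyotype.HET, Karyotype.ALT_HOM):
        vals = [a.het_rate for a in assigned if a.karyotype == k and np.isfinite(a.het_rate)]
        mean_het[k.value] = float(np.mean(vals)) if vals else float("nan")
    return KaryotypeSummary(
        counts=counts, frequencies=freqs, q=q, mean_het=mean_het, n_assigned=n
    )


def assignments_to_frame(assignments: list[KaryotypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [a.sample for a in assignments],
            "PC1": [a.pc1 for a in assignments],
            "PC2": [a.pc2 for a in assignments],
            "karyotype": [a.karyotype.value for a in assignments],
            "het_rate": [a.het_rate for a in assignments],
        }
    )
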