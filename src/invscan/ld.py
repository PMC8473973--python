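"""Linkage disequilibrium from unphased genotypes via the EM algorithm.

For each locus pair the four gametic haplotype frequencies are the
maximum-likelihood estimates under random mating, obtained by EM over
the 3x3 genotype table: every genotype combination except the double
heterozygote resolves to known haplotypes; the double-het mass is split
between the coupling (AB/ab) and repulsion (Ab/aB) phases in proportion
to the current frequency estimates each iteration. From the converged
frequencies, ``D = pAB - pA pB`` and ``r2 = D^2 / (pA pa pB pb)`` — the
gametic r2 that phased-haplotype LD tools report.

The module also provides chromosome-wide LD tables, karyotype-stratified
region LD (the inversion signature: LD pooled across karyotypes is high,
LD within each homokaryotype group is low), and the LD network filter
(edges at r2 >= 0.4, nodes kept while in LD with >= 4 others).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class LDResult:
    """EM haplotype-frequency estimate for one locus pair."""

    hap_freqs: np.ndarray  # (pAB, pAb, paB, pab); A/B = alternate alleles
    D: float
    r2: float
    n_used: int
    converged: bool
    defined: bool


def _em_tables(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM over a batch of 3x3 genotype tables.

    ``counts`` has shape (P, 3, 3); cell [a, b] is the number of samples
    with a alternate alleles at locus 1 and b at locus 2. Returns
    ``(hap_freqs (P,4), D, r2, converged, defined)``; r2 is NaN where
    undefined (a locus monomorphic among the jointly observed samples).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim == 2:
        c = c[None]
    P = c.shape[0]
    n_ind = c.sum(axis=(1, 2))
    n2 = 2.0 * n_ind
    # known haplotype contributions (everything but the double het)
    k11 = 2 * c[:, 2, 2] + c[:, 2, 1] + c[:, 1, 2]
    k10 = 2 * c[:, 2, 0] + c[:, 2, 1] + c[:, 1, 0]
    k01 = 2 * c[:, 0, 2] + c[:, 1, 2] + c[:, 0, 1]
    k00 = 2 * c[:, 0, 0] + c[:, 0, 1] + c[:, 1, 0]
    dh = c[:, 1, 1]

    with np.errstate(invalid="ignore", divide="ignore"):
        pa = (k11 + k10 + dh) / n2  # alt-allele freq, locus 1
        pb = (k11 + k01 + dh) / n2
    defined = (n_ind >= 2) & (pa > 0) & (pa < 1) & (pb > 0) & (pb < 1)

    # linkage-equilibrium initialization
    p11 = pa * pb
    p10 = pa * (1 - pb)
    p01 = (1 - pa) * pb
    p00 = (1 - pa) * (1 - pb)
    converged = np.zeros(P, dtype=bool)
    active = defined.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        num = p11 * p00
        den = num + p10 * p01
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        n11 = (k11 + dh * w) / n2
        n10 = (k10 + dh * (1 - w)) / n2
        n01 = (k01 + dh * (1 - w)) / n2
        n00 = (k00 + dh * w) / n2
        delta = np.max(
            np.abs(np.stack([n11 - p11, n10 - p10, n01 - p01, n00 - p00])), axis=0
        )
        p11, p10, p01, p00 = n11, n10, n01, n00
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly

    hap = np.stack([p11, p10, p01, p00], axis=1)
    D = p11 - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = np.where(defined, D * D / np.where(denom > 0, denom, np.nan), np.nan)
    r2 = np.clip(r2, 0.0, 1.0)
    D = np.where(defined, D, np.nan)
    return hap, D, r2, converged & defined, defined


def genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 joint genotype table over samples with both calls observed."""
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    ok = (ga != MISSING) & (gb != MISSING)
    c = np.zeros((3, 3))
    np.add.at(c, (ga[ok], gb[ok]), 1)
    return c


def r2_em(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDResult:
    """EM estimate of gametic LD between two genotype columns.

    Samples missing either call are excluded. If either locus is
    monomorphic among the jointly observed samples, r2 is undefined
    (NaN, ``defined=False``); such pairs are excluded downstream.
    """
    counts = genotype_counts(geno_a, geno_b)
    hap, D, r2, conv, defined = _em_tables(counts[None], tol=tol, max_iter=max_iter)
    return LDResult(
        hap_freqs=hap[0],
        D=float(D[0]),
        r2=float(r2[0]),
        n_used=int(counts.sum()),
        converged=bool(conv[0]),
        defined=bool(defined[0]),
    )


def loglik_table(counts: np.ndarray, hap_freqs: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under random mating.

    Genotype-cell probabilities are sums over haplotype-pair resolutions
    of products of gametic frequencies.
    """
    p11, p10, p01, p00 = hap_freqs
    H = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])  # alt counts (a, b) per hap
    f = np.array([p11, p10, p01, p00])
    cell = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            cell[H[i, 0] + H[j, 0], H[i, 1] + H[j, 1]] += f[i] * f[j]
    with np.errstate(divide="ignore"):
        lp = np.log(np.where(cell > 0, cell, 1.0))
    if np.any((counts > 0) & (cell <= 0)):
        return -np.inf
    return float(np.sum(counts * lp))


# ----------------------------------------------------------------------
# pairwise tables


def _pair_counts(calls: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Joint 3x3 tables for pairs (idx_a[k], idx_b[k]) via indicator products."""
    obs = calls != MISSING
    A = [(calls == g) & obs for g in range(3)]  # (n_samples, n_loci) each
    out = np.zeros((len(idx_a), 3, 3))
    for a in range(3):
        Xa = A[a][:, idx_a].astype(float)
        for b in range(3):
            Xb = A[b][:, idx_b].astype(float)
            out[:, a, b] = np.einsum("sk,sk->k", Xa, Xb)
    return out


def pairwise_r2(
    gm: GenotypeMatrix,
    locus_indices: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """EM r2 for all pairs among ``locus_indices`` (default: all loci).

    Returns one row per pair with columns ``i, j`` (locus indices into
    ``gm``), coordinates, ``n_used, D, r2, converged, defined``.
    """
    idx = (
        np.arange(gm.n_loci)
        if locus_indices is None
        else np.asarray(locus_indices, dtype=np.intp)
    )
    ii, jj = np.triu_indices(len(idx), k=1)
    ia, ib = idx[ii], idx[jj]
    if len(ia) == 0:
        return pd.DataFrame(
            columns=["i", "j", "chrom_a", "pos_a", "chrom_b", "pos_b",
                     "n_used", "D", "r2", "converged", "defined"]
        )
    counts = _pair_counts(gm.calls, ia, ib)
    _, D, r2, conv, defined = _em_tables(counts, tol=tol, max_iter=max_iter)
    return pd.DataFrame(
        {
            "i": ia,
            "j": ib,
            "chrom_a": gm.chrom[ia],
            "pos_a": gm.pos[ia],
            "chrom_b": gm.chrom[ib],
            "pos_b": gm.pos[ib],
            "n_used": counts.sum(axis=(1, 2)).astype(int),
            "D": D,
            "r2": r2,
            "converged": conv,
            "defined": defined,
        }
    )


def chromosome_ld(
    gm: GenotypeMatrix, chrom: str, min_r2_report: float = 0.0
) -> pd.DataFrame:
    """All within-chromosome pairwise r2 (undefined pairs logged, dropped).

    Rows with ``r2 < min_r2_report`` are omitted from the returned table
    (0 reports everything, the chromosome-wide default). The mean r2
    over defined pairs is attached as ``DataFrame.attrs['mean_r2']``.
    """
    idx = gm.chrom_indices(chrom)
    df = pairwise_r2(gm, idx)
    n_undef = int((~df["defined"]).sum())
    if n_undef:
        log.info("chromosome_ld(%s): %d undefined pairs excluded", chrom, n_undef)
    df = df[df["defined"]].copy()
    mean_r2 = float(df["r2"].mean()) if len(df) else float("nan")
    df = df[df["r2"] >= min_r2_report].reset_index(drop=True)
    df.attrs["mean_r2"] = mean_r2
    df.attrs["n_undefined"] = n_undef
    return df


# ----------------------------------------------------------------------
# karyotype-stratified LD


def _mean_r2(gm: GenotypeMatrix, sample_mask: np.ndarray,
             locus_indices: np.ndarray) -> tuple[float, int, int]:
    sub = GenotypeMatrix(
        samples=[s for s, m in zip(gm.samples, sample_mask) if m],
        loci=[gm.loci[i] for i in locus_indices],
        calls=gm.calls[np.ix_(sample_mask, locus_indices)],
    )
    df = pairwise_r2(sub)
    defined = df[df["defined"]]
    mean = float(defined["r2"].mean()) if len(defined) else float("nan")
    return mean, int(len(defined)), int((~df["defined"]).sum())


def stratified_ld(
    gm: GenotypeMatrix,
    locus_indices: np.ndarray,
    assignments: list,
    min_group: int = 5,
) -> dict:
    """Region mean r2 pooled and within each homokaryotype group.

    Pairs with undefined r2 (monomorphic within the stratum — common
    inside homokaryotype subsets, where many region alleles are fixed)
    are excluded from means; their counts are reported. Groups smaller
    than ``min_group`` samples are skipped with a warning.

    Besides raw means, bias-adjusted means ``max(mean - 1/(2 n_group),
    0)`` are reported: the sampling expectation of r2-hat between
    independent loci is ~1/(2n) for n diploids, which dominates raw
    means in small homokaryotype groups.
    """
    from .karyotype import Karyotype

    locus_indices = np.sort(np.asarray(locus_indices, dtype=np.intp))
    karyo = np.array([a.karyotype.value for a in assignments])
    out: dict = {"groups": {}, "skipped": []}
    masks = {
        "pooled": np.ones(gm.n_samples, dtype=bool),
        Karyotype.REF_HOM.value: karyo == Karyotype.REF_HOM.value,
        Karyotype.ALT_HOM.value: karyo == Karyotype.ALT_HOM.value,
    }
    for name, mask in masks.items():
        n = int(mask.sum())
        if name != "pooled" and n < min_group:
            log.warning("stratified_ld: group %s has %d samples (< %d); skipped",
                        name, n, min_group)
            out["skipped"].append(name)
            continue
        mean, n_pairs, n_undef = _mean_r2(gm, mask, locus_indices)
        adj = max(mean - 1.0 / (2.0 * n), 0.0) if np.isfinite(mean) else float("nan")
        out["groups"][name] = {
            "mean_r2": mean,
            "mean_r2_adjusted": adj,
            "n_samples": n,
            "n_pairs_defined": n_pairs,
            "n_pairs_undefined": n_undef,
        }
    return out


# ----------------------------------------------------------------------
# LD network


@dataclass
class LDNetwork:
    """High-LD SNP graph after the edge and degree filters.

    Edges connect locus pairs with r2 >= the edge threshold; nodes in LD
    with fewer than ``min_degree`` others are removed iteratively until
    stable (equivalently, the graph's ``min_degree``-core). Components
    are reported with their genomic spans.
    """

    graph: nx.Graph
    components: list[set]
    spans: list[dict]


def ld_network(
    results: pd.DataFrame,
    edge_min_r2: float = 0.4,
    min_degree: int = 4,
) -> LDNetwork:
    """Build and filter the LD network from a pairwise r2 table.

    ``results`` is a table as produced by :func:`pairwise_r2` /
    :func:`chromosome_ld`. Degree pruning is iterative (a removal that
    drops a neighbour below the threshold removes that neighbour too),
    i.e. the ``min_degree``-core of the thresholded graph.
    """
    g = nx.Graph()
    edges = results[(results.get("defined", True)) & (results["r2"] >= edge_min_r2)]
    for row in edges.itertuples(index=False):
        g.add_edge(
            (row.chrom_a, int(row.pos_a)),
            (row.chrom_b, int(row.pos_b)),
            r2=float(row.r2),
        )
    core = nx.k_core(g, k=min_degree) if g.number_of_nodes() else g
    comps = [set(c) for c in nx.connected_components(core)]
    comps.sort(key=lambda c: (-len(c), sorted(c)[0] if c else ""))
    spans = []
    for c in comps:
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in c:
            by_chrom.setdefault(chrom, []).append(pos)
        spans.append(
            {
                "n_loci": len(c),
                "chroms": {
                    ch: (min(ps), max(ps)) for ch, ps in sorted(by_chrom.items())
                },
            }
        )
    return LDNetwork(graph=core.copy(), components=comps, spans=spans)
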