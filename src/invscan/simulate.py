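"""Synthetic genotype datasets with a planted inversion and known truth.

The generator emulates the post-genotyping state of a reduced-
representation (RAD-seq-like) dataset: a few chromosomes of independent
biallelic SNPs in Hardy-Weinberg and linkage equilibrium, plus one
region where two diverged, non-recombining arrangements segregate. Each
sample draws its arrangement count from Binomial(2, q); within the
region every haplotype draws alleles independently from its own
arrangement's frequencies (free recombination within an arrangement,
none between). That construction produces exactly the signals the
detection pipeline relies on — three karyotype classes, pooled LD
elevated across the region without within-karyotype LD, heterokaryotype
heterozygosity excess, and higher diversity in the ancestral
arrangement — without any coalescent machinery.

At differentiated loci the alternate allele is associated with the
inverted (derived) arrangement and the within-arrangement minor-allele
frequencies partition the slack ``1 - delta`` in proportion to the two
diversity scales, so ``p_inv - p_anc = delta`` exactly while the
ancestral arrangement stays the more polymorphic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .genotypes import MISSING, GenotypeMatrix, Locus, write_vcf


@dataclass
class InversionSpec:
    chrom: str = "chr1"
    start: int = 12_540_000
    end: int = 13_700_000
    n_region_loci: int = 26


@dataclass
class SimConfig:
    """Study conditions for the planted-inversion simulation.

    Defaults mirror a rare-inversion RAD-seq cohort: 142 diploid
    samples, ~494 SNPs per 25-Mb chromosome, a 1.16-Mb region of 26 SNPs
    where the derived arrangement segregates at q = 0.17, with 90% of
    region loci differentiated by an allele-frequency gap of 0.8 and the
    ancestral arrangement carrying more within-arrangement diversity
    (scales 0.15 vs 0.05).
    """

    n_samples: int = 142
    n_chromosomes: int = 3
    loci_per_chrom: int = 494
    chrom_length_bp: int = 25_000_000
    inversion: InversionSpec = field(default_factory=InversionSpec)
    q: float = 0.17
    divergence: float = 0.9  # fraction of region loci differentiated
    delta: float = 0.8  # allele-frequency gap at differentiated loci
    theta_anc: float = 0.15  # within-arrangement MAF scale, ancestral
    theta_inv: float = 0.05  # within-arrangement MAF scale, derived
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("q", "divergence", "delta", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.theta_inv > self.theta_anc:
            raise ValueError(
                "theta_inv must be <= theta_anc (derived arrangement is "
                "younger, hence less diverse)"
            )
        inv = self.inversion
        if not (1 <= inv.start <= inv.end <= self.chrom_length_bp):
            raise ValueError("inversion region must lie inside the chromosome")
        if inv.n_region_loci > self.loci_per_chrom:
            raise ValueError("more region loci than loci per chromosome")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genotype matrix."""

    karyotypes: list[str]  # per sample: REF_HOM / HET / ALT_HOM
    region_locus_indices: np.ndarray  # global locus indices of region loci
    p_anc: np.ndarray  # arrangement-specific alt-allele freqs, region loci
    p_inv: np.ndarray
    differentiated: np.ndarray  # bool per region locus
    region_start: int
    region_end: int
    chrom: str


_KARYO = {0: "REF_HOM", 1: "HET", 2: "ALT_HOM"}
_BASES = ("A", "C", "G", "T")


def _positions(rng: np.random.Generator, n: int, length: int,
               exclude: tuple[int, int] | None = None) -> np.ndarray:
    """n distinct sorted positions in [1, length], avoiding ``exclude``."""
    out: set[int] = set()
    lo, hi = exclude if exclude else (0, -1)
    while len(out) < n:
        draw = rng.integers(1, length + 1, size=2 * (n - len(out)))
        for p in draw:
            p = int(p)
            if lo <= p <= hi:
                continue
            out.add(p)
            if len(out) == n:
                break
    return np.sort(np.fromiter(out, dtype=np.int64))


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate genotypes and truth labels; deterministic under cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    inv = cfg.inversion
    n, L = cfg.n_samples, cfg.loci_per_chrom
    samples = [f"S{i + 1:03d}" for i in range(n)]

    # per-haplotype arrangement indicators; HWE at frequency q
    hap_arr = rng.random((n, 2)) < cfg.q
    arr_count = hap_arr.sum(axis=1)
    karyotypes = [_KARYO[int(a)] for a in arr_count]

    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    region_idx: list[int] = []
    p_anc_r: np.ndarray | None = None

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    for chrom in chroms:
        if chrom == inv.chrom:
            n_bg = L - inv.n_region_loci
            bg_pos = _positions(rng, n_bg, cfg.chrom_length_bp,
                                exclude=(inv.start, inv.end))
            reg_pos = np.sort(
                rng.choice(
                    np.arange(inv.start, inv.end + 1),
                    size=inv.n_region_loci,
                    replace=False,
                )
            )
            pos = np.concatenate([bg_pos, reg_pos])
            order = np.argsort(pos)
            is_region = np.concatenate(
                [np.zeros(n_bg, bool), np.ones(inv.n_region_loci, bool)]
            )[order]
            pos = pos[order]

            # region allele frequencies per arrangement
            m = inv.n_region_loci
            n_diff = int(round(cfg.divergence * m))
            diff = np.zeros(m, bool)
            diff[rng.choice(m, size=n_diff, replace=False)] = True
            p_anc = np.empty(m)
            p_inv = np.empty(m)
            rho = (
                cfg.theta_inv / (cfg.theta_anc + cfg.theta_inv)
                if (cfg.theta_anc + cfg.theta_inv) > 0
                else 0.5
            )
            # differentiated: split the slack 1-delta between the two
            # arrangements' minor-allele frequencies, derived side smaller
            w = rng.uniform(0.0, min(2.0 * rho, 1.0), size=m)
            slack = 1.0 - cfg.delta
            p_anc[diff] = np.clip(slack * (1.0 - w[diff]), 0.0, 1.0)
            p_inv[diff] = np.clip(1.0 - slack * w[diff], 0.0, 1.0)
            # undifferentiated: minor alt allele near each arrangement's theta
            p_anc[~diff] = rng.uniform(0.0, min(2.0 * cfg.theta_anc, 0.5),
                                       size=(~diff).sum())
            p_inv[~diff] = rng.uniform(0.0, min(2.0 * cfg.theta_inv, 0.5),
                                       size=(~diff).sum())
            if cfg.delta == 0.0:
                p_inv[diff] = p_anc[diff]  # exactly shared under zero divergence

            # haplotype draws: allele ~ Bern(p of own arrangement)
            pmat = np.where(hap_arr[:, :, None], p_inv[None, None, :],
                            p_anc[None, None, :])  # (n, 2, m)
            alleles = rng.random((n, 2, m)) < pmat
            reg_geno = alleles.sum(axis=1).astype(np.int8)  # (n, m)

            bg_p = rng.uniform(0.05, 0.5, size=n_bg)
            bg_geno = rng.binomial(2, bg_p, size=(n, n_bg)).astype(np.int8)

            geno = np.empty((n, L), dtype=np.int8)
            geno[:, is_region] = reg_geno
            geno[:, ~is_region] = bg_geno
            base_index = len(loci)
            region_idx = [base_index + k for k in np.flatnonzero(is_region)]
            p_anc_r, p_inv_r, diff_r = p_anc, p_inv, diff
        else:
            pos = _positions(rng, L, cfg.chrom_length_bp)
            bg_p = rng.uniform(0.05, 0.5, size=L)
            geno = rng.binomial(2, bg_p, size=(n, L)).astype(np.int8)

        refs = rng.integers(0, 4, size=L)
        alts = (refs + rng.integers(1, 4, size=L)) % 4
        for k in range(L):
            loci.append(
                Locus(
                    chrom=chrom,
                    pos=int(pos[k]),
                    ref_allele=_BASES[refs[k]],
                    alt_allele=_BASES[alts[k]],
                )
            )
        cols.append(geno)

    calls = np.concatenate(cols, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls)
    truth = SimTruth(
        karyotypes=karyotypes,
        region_locus_indices=np.asarray(region_idx, dtype=np.intp),
        p_anc=p_anc_r,
        p_inv=p_inv_r,
        differentiated=diff_r,
        region_start=int(gm.pos[region_idx[0]]),
        region_end=int(gm.pos[region_idx[-1]]),
        chrom=inv.chrom,
    )
    return gm, truth


def simulate_sweep_region(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Hard-selective-sweep surrogate: the planted region carries a single
    high-frequency haplotype instead of two arrangements.

    Every sample shares one arrangement (no karyotype classes); region
    loci are made near-monomorphic for a swept allele with residual
    variation at the ancestral diversity scale. Used as the negative
    control for the karyotype validation gate.
    """
    swept = SimConfig(**{**asdict(cfg), "inversion": cfg.inversion,
                         "q": 0.0, "delta": 0.0, "divergence": 0.0,
                         "theta_anc": cfg.theta_inv,
                         "theta_inv": cfg.theta_inv})
    return simulate_dataset(swept)


def emit_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + truth TSV + config echo; byte-identical per (cfg, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, truth = simulate_dataset(cfg)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_vcf(gm, paths["vcf"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample\tkaryotype\n")
        for s, k in zip(gm.samples, truth.karyotypes):
            fh.write(f"{s}\t{k}\n")
    cfg_dict = asdict(cfg)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return paths
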