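"""Genotype matrix container and VCF input/output.

Every downstream stage (windowed local PCA, karyotype clustering, LD
estimation) consumes the :class:`GenotypeMatrix` built here: an ordered
sample list, an ordered list of biallelic SNP loci, and a samples x loci
array of diploid genotype codes ``{0: hom ref, 1: het, 2: hom alt,
-1: missing}``.

Only unphased biallelic SNP genotypes are used; phase separators are
ignored (``0|1`` is the same as ``0/1``) and half-missing calls such as
``./1`` are treated as missing, matching hard posterior-thresholded
genotype callers that never emit partial calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: Genotype code for a missing diploid call.
MISSING: int = -1


class EmptyMatrixError(ValueError):
    """Raised when no loci survive the read filters."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: 1-based physical position on a named chromosome."""

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "C"
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid genotype codes with locus coordinates.

    Invariants (checked at construction): dimensions consistent, loci
    grouped into contiguous chromosome blocks, positions strictly
    increasing within each chromosome.
    """

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray  # int8, shape (n_samples, n_loci), MISSING = -1

    # cached coordinate arrays
    chrom: np.ndarray = field(init=False, repr=False)
    pos: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        self.chrom = np.array([l.chrom for l in self.loci], dtype=object)
        self.pos = np.array([l.pos for l in self.loci], dtype=np.int64)
        seen: set[str] = set()
        prev = None
        for i, l in enumerate(self.loci):
            if l.chrom != prev:
                if l.chrom in seen:
                    raise ValueError(
                        f"chromosome {l.chrom!r} split into non-contiguous blocks"
                    )
                seen.add(l.chrom)
                prev = l.chrom
            elif self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {l.chrom!r} "
                    f"at index {i} ({self.pos[i - 1]} -> {self.pos[i]})"
                )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Locus indices of ``chrom`` (contiguous by construction)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(
                f"chromosome {chrom!r} not present; available: {self.chromosomes}"
            )
        return idx

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency, ignoring missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        """Per-locus minor allele frequency, ignoring missing calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def take_loci(self, indices: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to ``indices`` (kept in given order)."""
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in indices],
            calls=self.calls[:, indices].copy(),
        )


# ----------------------------------------------------------------------
# VCF input


def read_vcf(
    path: str | Path,
    min_maf: float = 0.0,
    max_missing: float = 1.0,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF file.

    Parameters
    ----------
    path
        VCF file with GT fields (plain text or bgzipped).
    min_maf
        Minimum minor allele frequency; loci below are dropped
        (``0.05`` reproduces a standard genotyping-pipeline filter).
    max_missing
        Maximum tolerated fraction of missing calls per locus
        (default 1.0 = no missingness filter).

    Multi-allelic records and indels are skipped (counts logged).
    Phase is ignored; half-missing calls become missing.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not (0.0 <= min_maf < 0.5):
        raise ValueError("min_maf must be in [0, 0.5)")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    if not path.exists():
        raise FileNotFoundError(path)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise EmptyMatrixError(f"{path}: VCF contains no samples")

    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    skipped = {"multiallelic": 0, "non_snp": 0, "low_maf": 0, "missingness": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not v.is_snp:
            skipped["non_snp"] += 1
            continue
        gt = np.asarray(v.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        a, b = gt[:, 0], gt[:, 1]
        col = np.where((a >= 0) & (b >= 0), a + b, MISSING).astype(np.int8)
        obs = col != MISSING
        n_obs = int(obs.sum())
        if n_obs == 0 or (1.0 - n_obs / len(samples)) > max_missing + 1e-12:
            skipped["missingness"] += 1
            continue
        p = col[obs].sum() / (2.0 * n_obs)
        if min(p, 1.0 - p) < min_maf - 1e-12:
            skipped["low_maf"] += 1
            continue
        loci.append(
            Locus(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                id=None if v.ID in (None, ".") else v.ID,
            )
        )
        cols.append(col)

    for kind, n in skipped.items():
        if n:
            log.info("read_vcf(%s): skipped %d records (%s)", path.name, n, kind)
    if not loci:
        raise EmptyMatrixError(
            f"{path}: no loci survived filters (min_maf={min_maf}, "
            f"max_missing={max_missing}); skipped counts: {skipped}"
        )
    calls = np.stack(cols, axis=1)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


# ----------------------------------------------------------------------
# VCF output

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write ``gm`` as a minimal GT-only VCF 4.2 file.

    Output is byte-deterministic for a given matrix, and
    ``read_vcf(write_vcf(gm))`` (with filters off) reproduces ``gm``
    exactly.
    """
    if gm.n_samples == 0 or gm.n_loci == 0:
        raise ValueError("cannot write an empty genotype matrix")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invscan\n")
        for c in gm.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, l in enumerate(gm.loci):
            gts = "\t".join(_GT[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{l.chrom}\t{l.pos}\t{l.id or '.'}\t{l.ref_allele}\t"
                f"{l.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def subset_region(
    gm: GenotypeMatrix, chrom: str, start: int, end: int
) -> GenotypeMatrix:
    """Loci with position in the closed interval ``[start, end]`` on ``chrom``.

    Sample order is preserved; an interval containing no loci yields an
    empty (0-locus) matrix, not an error.
    """
    if start > end:
        raise ValueError(f"start ({start}) > end ({end})")
    idx = gm.chrom_indices(chrom)  # raises KeyError w/ available chroms
    sel = idx[(gm.pos[idx] >= start) & (gm.pos[idx] <= end)]
    return GenotypeMatrix(
        samples=list(gm.samples),
        loci=[gm.loci[i] for i in sel],
        calls=gm.calls[:, sel].copy(),
    )
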