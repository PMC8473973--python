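"""End-to-end orchestration: scan for candidate regions, then validate them.

``run_scan`` executes read -> windows -> local-PCA summaries -> window
distances -> MDS -> Tukey outliers -> candidate regions and writes the
window/outlier/region tables. ``run_validate`` runs the structural-
variant evidence checks on one region — three-cluster region PCA with
the heterozygosity gate, heterozygosity ordering, pooled-vs-within
karyotype LD, and the LD network — and renders an overall verdict:
``SV-consistent`` when the karyotype and LD signatures all hold,
``sweep-like/ambiguous`` otherwise, ``under-resolution`` when the
region has too few SNPs to judge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import GenotypeMatrix, read_vcf, subset_region
from .karyotype import (
    Karyotype,
    KaryotypeSummary,
    assign_karyotypes,
    assignments_to_frame,
    region_pca,
    summarize_karyotypes,
)
from .ld import ld_network, pairwise_r2, stratified_ld
from .mds import MDSEmbedding, mds_embed
from .outliers import CandidateRegion, call_candidate_regions, outlier_table, regions_to_bed
from .windows import WindowSet, distance_matrix, make_windows, summarize_windows

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the standard values for this method
    (15-SNP windows, 4 MDS axes, > 4 outlier windows per region,
    network edges at r2 >= 0.4 with node degree >= 4, MAF >= 0.05)."""

    vcf: str | None = None
    window_size: int = 15
    mds_axes: int = 4
    min_outliers: int = 4
    max_gap_windows: int = 5
    edge_min_r2: float = 0.4
    min_degree: int = 4
    min_maf: float = 0.05
    max_missing: float = 1.0
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        problems = []
        if self.window_size < 2:
            problems.append(f"window_size must be >= 2 (got {self.window_size})")
        if self.mds_axes < 1:
            problems.append(f"mds_axes must be >= 1 (got {self.mds_axes})")
        if self.min_outliers < 0:
            problems.append(f"min_outliers must be >= 0 (got {self.min_outliers})")
        if self.max_gap_windows < 0:
            problems.append(f"max_gap_windows must be >= 0 (got {self.max_gap_windows})")
        if not 0.0 <= self.edge_min_r2 <= 1.0:
            problems.append(f"edge_min_r2 must be in [0,1] (got {self.edge_min_r2})")
        if not 0.0 <= self.min_maf < 0.5:
            problems.append(f"min_maf must be in [0,0.5) (got {self.min_maf})")
        if not 0.0 <= self.max_missing <= 1.0:
            problems.append(f"max_missing must be in [0,1] (got {self.max_missing})")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


@dataclass
class ScanResult:
    window_set: WindowSet
    kept_indices: list[int]
    distances: np.ndarray
    mds: MDSEmbedding
    outliers: pd.DataFrame
    regions: list[CandidateRegion]

    def window_frame(self) -> pd.DataFrame:
        rows = []
        pos = {w: k for k, w in enumerate(self.kept_indices)}
        for w in self.window_set:
            row = {
                "chrom": w.chrom,
                "window": w.index,
                "start": w.start_bp,
                "end": w.end_bp,
                "n_snps": w.n_snps,
            }
            for k in range(1, self.mds.n_axes + 1):
                row[f"MDS{k}"] = (
                    float(self.mds.axis(k)[pos[w.index]]) if w.index in pos else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def region_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "axis": r.axis,
                    "n_outlier_windows": r.n_outlier_windows,
                    "overlapping_axes": ",".join(r.overlapping_axes),
                }
                for r in self.regions
            ]
        )


def _header(cfg: PipelineConfig) -> str:
    fields = ", ".join(f"{k}={v}" for k, v in asdict(cfg).items())
    return f"# invscan {__version__} | {fields}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_scan(cfg: PipelineConfig, gm: GenotypeMatrix | None = None) -> ScanResult:
    """Local-PCA/MDS outlier scan over the whole genotype matrix.

    Windows are per-chromosome; the distance matrix and MDS embedding
    are genome-wide (all windows jointly), so outlier fences compare
    every window against the genome-wide background. Zero regions is a
    valid outcome.
    """
    cfg.validate()
    if gm is None:
        if cfg.vcf is None:
            raise ValueError("no genotype matrix and no input VCF configured")
        gm = read_vcf(cfg.vcf, min_maf=cfg.min_maf, max_missing=cfg.max_missing)
    ws = make_windows(gm, cfg.window_size)
    summaries, kept = summarize_windows(gm, ws)
    D = distance_matrix([summaries[i] for i in kept])
    n_axes = min(cfg.mds_axes, max(len(kept) - 1, 1))
    mds = mds_embed(D, n_axes=n_axes)
    table = outlier_table(mds, ws, kept)
    regions = call_candidate_regions(
        mds, ws, kept,
        min_outliers=cfg.min_outliers,
        max_gap_windows=cfg.max_gap_windows,
    )
    result = ScanResult(
        window_set=ws, kept_indices=kept, distances=D,
        mds=mds, outliers=table, regions=regions,
    )
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(result.window_frame(), outdir / "windows.tsv", cfg)
        _write_tsv(table, outdir / "outliers.tsv", cfg)
        _write_tsv(result.region_frame(), outdir / "regions.tsv", cfg)
        with open(outdir / "regions.bed", "w") as fh:
            fh.write(regions_to_bed(regions))
    log.info("run_scan: %d windows, %d candidate regions", len(ws), len(regions))
    return result


# ----------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Per-criterion evidence for one candidate region plus a verdict."""

    region: CandidateRegion
    verdict: str  # "SV-consistent" | "sweep-like/ambiguous" | "under-resolution"
    three_clusters: bool
    het_ordering: bool
    ld_contrast: bool
    network_spans_region: bool
    assignments: list = field(default_factory=list)
    summary: KaryotypeSummary | None = None
    stratified: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"region {self.region.chrom}:{self.region.start}-{self.region.end} "
            f"({self.region.axis}, {self.region.n_outlier_windows} outlier windows)",
            f"  three PC1 clusters with het excess : {self.three_clusters}",
            f"  het ordering HET > homokaryotypes  : {self.het_ordering}",
            f"  pooled LD >> within-karyotype LD   : {self.ld_contrast}",
            f"  LD network component spans region  : {self.network_spans_region}",
            f"  verdict: {self.verdict}",
        ]
        lines += [f"  note: {n}" for n in self.notes]
        return "\n".join(lines)


def run_validate(
    cfg: PipelineConfig,
    gm: GenotypeMatrix,
    region: CandidateRegion,
    ld_ratio: float = 3.0,
) -> ValidationReport:
    """Structural-variant evidence checks for one candidate region.

    The verdict is ``SV-consistent`` when the three karyotype/LD core
    signatures hold: (i) three PC1 clusters pass the heterozygosity
    gate, (ii) the HET group is the most heterozygous, and (iii) pooled
    region LD exceeds ``ld_ratio`` times each within-homokaryotype mean
    (bias-adjusted; groups below the size gate are skipped). The LD
    network check is reported as supporting evidence; at modest
    arrangement divergence a real variant can sit below the fixed
    network edge threshold, so it does not gate the verdict.
    """
    cfg.validate()
    region_gm = subset_region(gm, region.chrom, region.start, region.end)
    report = ValidationReport(
        region=region, verdict="sweep-like/ambiguous",
        three_clusters=False, het_ordering=False,
        ld_contrast=False, network_spans_region=False,
    )
    n_poly = int((region_gm.maf() > 0).sum()) if region_gm.n_loci else 0
    if n_poly < 5:
        report.verdict = "under-resolution"
        report.notes.append(
            f"region has {n_poly} polymorphic SNPs; need >= 5 to assess"
        )
        return report

    coords = region_pca(gm, region)
    assignments, diag = assign_karyotypes(coords, region_gm)
    report.assignments = assignments
    assigned = [a for a in assignments if a.karyotype != Karyotype.UNASSIGNED]
    counts = {k: sum(a.karyotype == k for a in assignments) for k in Karyotype}
    report.three_clusters = (
        len(assigned) == len(assignments)
        and all(counts[k] > 0 for k in (Karyotype.REF_HOM, Karyotype.HET, Karyotype.ALT_HOM))
    )
    if diag.get("gate"):
        report.notes.append(diag["gate"])
    if assigned:
        report.summary = summarize_karyotypes(assignments)
        mh = report.summary.mean_het
        report.het_ordering = (
            np.isfinite(mh["HET"])
            and mh["HET"] > mh["REF_HOM"]
            and mh["HET"] > mh["ALT_HOM"]
        )

        region_idx = region_gm_indices(gm, region)
        strat = stratified_ld(gm, region_idx, assignments)
        report.stratified = strat
        pooled = strat["groups"].get("pooled", {}).get("mean_r2_adjusted", np.nan)
        withins = []
        for name, g in strat["groups"].items():
            if name == "pooled":
                continue
            if np.isfinite(g["mean_r2_adjusted"]):
                withins.append(g["mean_r2_adjusted"])
            else:
                # every pair monomorphic within the group: the extreme form
                # of absent within-karyotype LD, not a veto
                report.notes.append(
                    f"within-{name} r2 undefined (region monomorphic in group)"
                )
        if np.isfinite(pooled):
            report.ld_contrast = all(pooled >= ld_ratio * w for w in withins)
        for name in strat["skipped"]:
            report.notes.append(f"LD group {name} below size gate; skipped")

        df = pairwise_r2(gm, region_idx)
        net = ld_network(df, edge_min_r2=cfg.edge_min_r2, min_degree=cfg.min_degree)
        if net.components:
            span = net.spans[0]["chroms"].get(region.chrom)
            if span:
                covered = (min(span[1], region.end) - max(span[0], region.start))
                report.network_spans_region = covered >= 0.5 * (region.end - region.start)

    if report.three_clusters and report.het_ordering and report.ld_contrast:
        report.verdict = "SV-consistent"
    return report


def region_gm_indices(gm: GenotypeMatrix, region: CandidateRegion) -> np.ndarray:
    """Global locus indices inside the region interval."""
    idx = gm.chrom_indices(region.chrom)
    return idx[(gm.pos[idx] >= region.start) & (gm.pos[idx] <= region.end)]
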