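"""Boxplot-style outlier flagging of MDS axes and candidate-region calling.

Windows whose MDS coordinate falls strictly outside the Tukey fences
(hinges -/+ 1.5 x hinge-spread, the standard R ``boxplot.stats``
convention) are flagged per axis; runs of flagged windows on one
chromosome become candidate structural-variant regions, spanning from
the start of the first outlier window to the end of the last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mds import MDSEmbedding
from .windows import WindowSet


def tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Lower and upper Tukey hinges (fivenum convention).

    Hinges are medians of the lower/upper halves of the sorted data,
    each half including the overall median position when n is odd;
    interpolation follows R's ``fivenum`` (hinge at position
    ``floor((n + 3) / 2) / 2``, averaging the straddling order
    statistics at half-integer positions).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    h = (np.floor((n + 3) / 2.0)) / 2.0  # 1-based, possibly half-integer
    lo = 0.5 * (x[int(np.floor(h)) - 1] + x[int(np.ceil(h)) - 1])
    hu = n + 1 - h
    hi = 0.5 * (x[int(np.floor(hu)) - 1] + x[int(np.ceil(hu)) - 1])
    return float(lo), float(hi)


def tukey_outliers(values: np.ndarray, coef: float = 1.5) -> pd.DataFrame:
    """Flag values strictly outside the Tukey fences.

    Returns a DataFrame with columns ``value, is_outlier, fence_low,
    fence_high``; fences are ``hinge -/+ coef * (upper hinge - lower
    hinge)``. Requires at least 5 values (fences are unstable below
    that).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("tukey_outliers needs a 1-D vector of >= 5 values")
    lo, hi = tukey_hinges(x)
    spread = hi - lo
    fence_low = lo - coef * spread
    fence_high = hi + coef * spread
    flag = (x < fence_low) | (x > fence_high)
    return pd.DataFrame(
        {
            "value": x,
            "is_outlier": flag,
            "fence_low": fence_low,
            "fence_high": fence_high,
        }
    )


def outlier_table(
    mds: MDSEmbedding, ws: WindowSet, kept_indices: list[int], coef: float = 1.5
) -> pd.DataFrame:
    """Per-(window, axis) outlier calls over all embedded windows.

    ``kept_indices`` maps MDS rows back to window indices (degenerate
    windows carry no MDS coordinates and appear in no row). Fences are
    computed per axis over all embedded windows genome-wide.
    """
    if mds.coords.shape[0] != len(kept_indices):
        raise ValueError("MDS embedding not aligned to kept window indices")
    frames = []
    for k in range(1, mds.n_axes + 1):
        calls = tukey_outliers(mds.axis(k), coef=coef)
        calls.insert(0, "axis", f"MDS{k}")
        calls.insert(0, "window", kept_indices)
        w = [ws[i] for i in kept_indices]
        calls.insert(1, "chrom", [x.chrom for x in w])
        calls.insert(2, "start", [x.start_bp for x in w])
        calls.insert(3, "end", [x.end_bp for x in w])
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CandidateRegion:
    """A run of outlier windows on one MDS axis and chromosome.

    ``start``/``end`` follow the first/last-outlier-window rule (1-based
    closed interval). ``member_windows`` are the outlier window indices;
    ``overlapping_axes`` lists other axes whose regions intersect this
    one.
    """

    chrom: str
    start: int
    end: int
    axis: str
    member_windows: list[int]
    n_outlier_windows: int
    overlapping_axes: list[str] = field(default_factory=list)

    def intersects(self, other: "CandidateRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def call_candidate_regions(
    mds: MDSEmbedding,
    ws: WindowSet,
    kept_indices: list[int],
    min_outliers: int = 4,
    max_gap_windows: int = 5,
    coef: float = 1.5,
) -> list[CandidateRegion]:
    """Group outlier windows into candidate regions, per axis and chromosome.

    Outlier windows separated by at most ``max_gap_windows`` intervening
    non-outlier windows belong to one run; a run with strictly more than
    ``min_outliers`` outlier windows becomes a region ("more than four
    outliers" at the default). Regions found on multiple axes are
    reported separately, with mutual overlaps recorded in
    ``overlapping_axes``.
    """
    table = outlier_table(mds, ws, kept_indices, coef=coef)
    # ordinal position of each window within its chromosome (degenerate
    # windows count as non-outlier gap members)
    ordinal = {}
    for chrom in {w.chrom for w in ws}:
        for o, w in enumerate(ws.on_chrom(chrom)):
            ordinal[w.index] = o

    regions: list[CandidateRegion] = []
    for axis, sub in table.groupby("axis", sort=True):
        out = sub[sub["is_outlier"]]
        for chrom, chunk in out.groupby("chrom", sort=False):
            wins = sorted(chunk["window"], key=lambda i: ordinal[i])
            runs: list[list[int]] = []
            for wi in wins:
                if runs and ordinal[wi] - ordinal[runs[-1][-1]] - 1 <= max_gap_windows:
                    runs[-1].append(wi)
                else:
                    runs.append([wi])
            for run in runs:
                if len(run) > min_outliers:
                    regions.append(
                        CandidateRegion(
                            chrom=chrom,
                            start=ws[run[0]].start_bp,
                            end=ws[run[-1]].end_bp,
                            axis=axis,
                            member_windows=run,
                            n_outlier_windows=len(run),
                        )
                    )
    for r in regions:
        r.overlapping_axes = sorted(
            {o.axis for o in regions if o is not r and r.intersects(o)}
        )
    return regions


def regions_to_bed(regions: list[CandidateRegion]) -> str:
    """BED (0-based half-open) text for a region list."""
    lines = [
        f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.axis}:{r.n_outlier_windows}_outliers"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
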