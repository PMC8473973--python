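"""Windowed local PCA: per-window relatedness summaries and distances.

The genome is cut into non-overlapping windows of a fixed SNP count
(default 15) that never span chromosomes; trailing remainder SNPs are
dropped. Each window is summarized by the rank-2 eigenstructure of its
trace-normalized sample x sample covariance matrix — the "local PCA"
picture of relatedness in that window — and windows are compared by the
Frobenius distance between their rank-2 reconstructions. This distance
is invariant to eigenvector sign flips and to rotations inside
degenerate eigenspaces, which raw PC-coordinate differences are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """Half-open global locus index range [start_idx, stop_idx) on one chromosome."""

    index: int
    chrom: str
    start_idx: int
    stop_idx: int
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.stop_idx - self.start_idx


@dataclass
class WindowSet:
    windows: list[Window]
    window_size: int

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]

    def on_chrom(self, chrom: str) -> list[Window]:
        return [w for w in self.windows if w.chrom == chrom]


@dataclass
class WindowSummary:
    """Top-2 eigenpairs of a window's trace-normalized covariance.

    ``eigvals`` are non-negative, descending, and sum to <= 1 (the full
    normalized spectrum sums to 1); ``eigvecs`` columns are orthonormal.
    ``degenerate`` marks windows whose loci carry no variance (all
    monomorphic); such windows are excluded from the distance matrix.
    """

    index: int
    eigvals: np.ndarray  # (2,)
    eigvecs: np.ndarray  # (n_samples, 2)
    total_variance: float
    degenerate: bool = False


def make_windows(gm: GenotypeMatrix, window_size: int = 15) -> WindowSet:
    """Cut each chromosome into consecutive windows of ``window_size`` SNPs.

    Per chromosome there are ``floor(n_loci / window_size)`` windows; the
    remainder is dropped (count logged). Raises if no chromosome has at
    least one full window.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    windows: list[Window] = []
    dropped = 0
    for chrom in gm.chromosomes:
        idx = gm.chrom_indices(chrom)
        n_win = len(idx) // window_size
        dropped += len(idx) - n_win * window_size
        for k in range(n_win):
            lo = int(idx[0]) + k * window_size
            hi = lo + window_size
            windows.append(
                Window(
                    index=len(windows),
                    chrom=chrom,
                    start_idx=lo,
                    stop_idx=hi,
                    start_bp=int(gm.pos[lo]),
                    end_bp=int(gm.pos[hi - 1]),
                )
            )
    if not windows:
        raise ValueError(
            f"window_size={window_size} exceeds the SNP count of every chromosome"
        )
    if dropped:
        log.info("make_windows: dropped %d trailing remainder SNPs", dropped)
    return WindowSet(windows=windows, window_size=window_size)


def _centered_block(gm: GenotypeMatrix, lo: int, hi: int) -> np.ndarray:
    """Window genotypes with per-locus mean imputation and centering."""
    X = gm.calls[:, lo:hi].astype(float)
    mask = X == MISSING
    X[mask] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)  # all-missing locus -> constant 0
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    return X - mu


def window_summary(gm: GenotypeMatrix, window: Window) -> WindowSummary:
    """Rank-2 summary of local relatedness within one window.

    Genotypes are mean-imputed per locus and centered; the sample x
    sample covariance ``C = X X^T`` is scaled by ``1/trace(C)`` so every
    window carries unit total variance, then the top-2 eigenpairs are
    kept. A window whose loci are all monomorphic has zero trace and is
    flagged degenerate.
    """
    Xc = _centered_block(gm, window.start_idx, window.stop_idx)
    C = Xc @ Xc.T
    total = float(np.trace(C))
    n = gm.n_samples
    if total <= 1e-12:
        return WindowSummary(
            index=window.index,
            eigvals=np.zeros(2),
            eigvecs=np.zeros((n, 2)),
            total_variance=0.0,
            degenerate=True,
        )
    C /= total
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:2]
    eigvals = np.clip(vals[order], 0.0, None)
    return WindowSummary(
        index=window.index,
        eigvals=eigvals,
        eigvecs=vecs[:, order],
        total_variance=total,
    )


def summarize_windows(
    gm: GenotypeMatrix, ws: WindowSet
) -> tuple[list[WindowSummary], list[int]]:
    """Summaries for every window; returns (summaries, kept_indices).

    ``kept_indices`` lists window indices that are non-degenerate and
    hence enter the distance matrix; degenerate windows are logged.
    """
    summaries = [window_summary(gm, w) for w in ws]
    kept = [s.index for s in summaries if not s.degenerate]
    n_deg = len(summaries) - len(kept)
    if n_deg:
        log.info("summarize_windows: %d degenerate windows excluded", n_deg)
    return summaries, kept


def window_distance(a: WindowSummary, b: WindowSummary) -> float:
    """Frobenius distance between the two rank-2 covariance reconstructions.

    ``||A2 - B2||_F`` with ``X2 = sum_j lambda_j v_j v_j^T``; computed
    without forming the n x n matrices via
    ``||A||^2 + ||B||^2 - 2 tr(A B)`` and
    ``tr(A B) = || Wa^T Wb ||_F^2`` where ``W = V sqrt(diag(lambda))``.
    """
    if a.eigvecs.shape[0] != b.eigvecs.shape[0]:
        raise ValueError("window summaries come from different sample sets")
    wa = a.eigvecs * np.sqrt(a.eigvals)
    wb = b.eigvecs * np.sqrt(b.eigvals)
    cross = wa.T @ wb
    d2 = (
        float(np.sum(a.eigvals**2))
        + float(np.sum(b.eigvals**2))
        - 2.0 * float(np.sum(cross**2))
    )
    return float(np.sqrt(max(d2, 0.0)))


def distance_matrix(summaries: list[WindowSummary]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise window distances.

    All summaries must be non-degenerate (filter with
    :func:`summarize_windows` first).
    """
    if any(s.degenerate for s in summaries):
        raise ValueError("degenerate window summaries must be excluded first")
    m = len(summaries)
    W = np.stack([s.eigvecs * np.sqrt(s.eigvals) for s in summaries])  # (m, n, 2)
    sq = np.array([float(np.sum(s.eigvals**2)) for s in summaries])
    # tr(A_i A_j) = || W_i^T W_j ||_F^2
    cross = np.einsum("ink,jnl->ijkl", W, W)
    tr = np.einsum("ijkl,ijkl->ij", cross, cross)
    d2 = sq[:, None] + sq[None, :] - 2.0 * tr
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))
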