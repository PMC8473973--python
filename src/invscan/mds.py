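"""Classical (Torgerson) multidimensional scaling.

Embeds a distance matrix into a small number of axes by
eigendecomposition of the double-centered squared-distance matrix
``B = -1/2 J D^2 J``. Used to place local-PCA windows on the MDS1..MDS4
surface that the outlier scan operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class MDSEmbedding:
    """Coordinates on axes MDS1..MDSk, ordered by descending eigenvalue.

    ``coords`` has shape (n_points, n_axes); columns are mean-zero.
    ``eigenvalues`` holds the full descending spectrum of B (possibly
    negative in the tail when the input is not exactly Euclidean).
    """

    coords: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def axis(self, k: int) -> np.ndarray:
        """1-based axis accessor: ``axis(1)`` is MDS1."""
        return self.coords[:, k - 1]


def mds_embed(d: np.ndarray, n_axes: int = 4) -> MDSEmbedding:
    """Classical MDS of a distance matrix into ``n_axes`` dimensions.

    Negative eigenvalues among the leading ``n_axes`` are truncated to
    zero (with a warning): those axes carry all-zero coordinates. The
    sign of each axis is fixed so its largest-magnitude loading is
    positive, making output deterministic across platforms.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if n_axes > max(n - 1, 1):
        raise ValueError(f"n_axes={n_axes} too large for {n} points")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    lead = vals[:n_axes]
    if (lead < -1e-10 * max(abs(vals[0]), 1.0)).any():
        log.warning(
            "mds_embed: %d of the leading %d eigenvalues are negative; "
            "truncated to zero",
            int((lead < 0).sum()),
            n_axes,
        )
    lam = np.clip(lead, 0.0, None)
    coords = vecs[:, :n_axes] * np.sqrt(lam)
    # deterministic sign: largest-|loading| entry of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return MDSEmbedding(coords=coords, eigenvalues=vals)
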