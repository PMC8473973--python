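"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the LD oracle
maximizes the multinomial likelihood by grid search (+ golden-section
refinement) instead of EM, and the eigen oracle reconstructs matrices
explicitly.
"""

import numpy as np

from invscan.ld import loglik_table


def grid_r2(counts: np.ndarray, step: float = 1e-4) -> float:
    """Grid-search likelihood maximizer for gametic r2 of a 3x3 table.

    Any stationary point of the random-mating likelihood keeps the
    allele frequencies at their observed values (every haplotype
    resolution of a genotype preserves allele counts), so the
    maximization reduces to a 1-D search over pAB on its feasible
    interval; the best grid point is sharpened by golden-section
    search within its bracket.
    """
    c = np.asarray(counts, dtype=float)
    n2 = 2.0 * c.sum()
    pa = (2 * c[2].sum() + c[1].sum()) / n2
    pb = (2 * c[:, 2].sum() + c[:, 1].sum()) / n2
    if not (0.0 < pa < 1.0 and 0.0 < pb < 1.0):
        return float("nan")
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)

    def ll(p11: float) -> float:
        p10, p01, p00 = pa - p11, pb - p11, 1.0 - pa - pb + p11
        if min(p11, p10, p01, p00) < -1e-12:
            return -np.inf
        return loglik_table(
            c, (max(p11, 0.0), max(p10, 0.0), max(p01, 0.0), max(p00, 0.0))
        )

    grid = np.arange(lo, hi + step, step)
    k = int(np.argmax([ll(g) for g in grid]))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    x1, x2 = b - phi * (b - a), a + phi * (b - a)
    f1, f2 = ll(x1), ll(x2)
    for _ in range(60):
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + phi * (b - a)
            f2 = ll(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - phi * (b - a)
            f1 = ll(x1)
    p11 = 0.5 * (a + b)
    D = p11 - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def random_mating_table(rng: np.random.Generator, n: int = 50) -> np.ndarray:
    """Random 3x3 genotype table drawn from random haplotype frequencies."""
    f = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
    H = [(1, 1), (1, 0), (0, 1), (0, 0)]
    haps = rng.choice(4, size=(n, 2), p=f)
    ga = np.array([H[h1][0] + H[h2][0] for h1, h2 in haps])
    gb = np.array([H[h1][1] + H[h2][1] for h1, h2 in haps])
    c = np.zeros((3, 3))
    np.add.at(c, (ga, gb), 1)
    return c
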