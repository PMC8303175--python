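"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package under test: the
Skellam tail is obtained by explicit double-Poisson enumeration over the
(n1, n2) grid, not by the package's marginalized closed-form sum.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def skellam_tail_table(lam1: float, lam2: float, d_max: int = 80) -> dict[int, float]:
    """P(N1 - N2 >= d) for all d in [-d_max, d_max] by explicit enumeration.

    The (n1, n2) grid covers each Poisson out to 20 sigma plus d_max slack, so
    the truncated mass is negligible relative to any tail in range.
    """
    n1_max = int(math.ceil(lam1 + 20 * math.sqrt(lam1))) + d_max + 40
    n2_max = int(math.ceil(lam2 + 20 * math.sqrt(lam2))) + d_max + 40
    n1 = np.arange(n1_max + 1)
    n2 = np.arange(n2_max + 1)
    joint = np.outer(stats.poisson.pmf(n1, lam1), stats.poisson.pmf(n2, lam2))
    d = n1[:, None] - n2[None, :]
    offset = n2_max
    mass = np.bincount((d + offset).ravel(), weights=joint.ravel(),
                       minlength=n1_max + n2_max + 1)
    # accumulate from the far positive tail first so tiny tails stay accurate
    sf = np.cumsum(mass[::-1])[::-1]
    return {int(dd): float(sf[dd + offset]) for dd in range(-d_max, d_max + 1)}


def brute_force_overlaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """All overlapping index pairs among 1-based inclusive intervals."""
    hits = []
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            a, b = intervals[i], intervals[j]
            if a[0] <= b[1] and b[0] <= a[1]:
                hits.append((i, j))
    return hits
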