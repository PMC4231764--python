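"""Nonparametric primitives for per-probe signal estimation.

The Hodges–Lehmann pseudo-median and the one-sided Wilcoxon signed-rank
P-value are the estimator pair behind the smoothed tiling tracks; they are
implemented here directly because the tie/zero conventions and the exact
small-sample null distribution are the contract downstream cluster calling
depends on.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["hodges_lehmann", "wilcoxon_signed_rank_p", "EXACT_MAX_N"]

#: Windows holding at most this many values use the exact signed-rank null
#: distribution; larger windows use the normal approximation with continuity
#: and tie corrections.
EXACT_MAX_N = 25


def hodges_lehmann(values) -> float:
    """Hodges–Lehmann pseudo-median: median of all Walsh averages.

    Walsh averages are (x_i + x_j)/2 over all pairs i <= j, so the sample
    itself is included. For symmetric distributions this estimates the
    centre of symmetry and pairs naturally with the signed-rank test.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("hodges_lehmann requires at least one value")
    sums = x[:, None] + x[None, :]
    iu = np.triu_indices(x.size)
    return float(np.median(sums[iu]) / 2.0)


@lru_cache(maxsize=4096)
def _signed_rank_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of 2*W+ over all sign assignments, by generating function.

    ``doubled_ranks`` are the midranks multiplied by two so that tied ranks
    stay integral. Entry k of the result counts sign vectors whose positive
    rank sum equals k/2; the total count is 2**n. Equivalent to, and tested
    against, brute-force enumeration of all 2**n sign assignments.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total - r + 1]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_p(values, exact_max_n: int = EXACT_MAX_N) -> float:
    """One-sided Wilcoxon signed-rank P-value for median > 0.

    Conventions: zeros are dropped before ranking (Wilcoxon's reduction),
    ties receive midranks. The null distribution is exact (conditional on
    the observed midranks) for up to ``exact_max_n`` non-zero values, and a
    normal approximation with continuity correction and tie-corrected
    variance beyond that. Degenerate windows (no non-zero value, or a single
    value) return 1.0 — a lone probe carries no evidence.
    """
    x = np.asarray(values, dtype=float)
    x = x[x != 0.0]
    n = x.size
    if n == 0:
        return 1.0
    if n == 1:
        warnings.warn(
            "signed-rank window holds a single non-zero value; P set to 1",
            stacklevel=2,
        )
        return 1.0
    ranks = rankdata(np.abs(x))
    w_plus = float(ranks[x > 0].sum())
    if n <= exact_max_n:
        doubled = tuple(int(round(2 * r)) for r in ranks)
        counts = _signed_rank_counts(tuple(sorted(doubled)))
        w2 = int(round(2 * w_plus))
        return float(counts[w2:].sum() / 2.0**n)
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, tie_counts = np.unique(np.abs(x), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(norm.sf(z))
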