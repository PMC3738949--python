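"""One-sided Wilcoxon rank-sum test used by the window scan.

The alternative is "ChIP stochastically greater than control".  Ties are
handled with mid-ranks.  Small samples (< 10 per side) use the exact
permutation null of the rank sum, computed by a shift-algorithm dynamic
program; larger samples use the normal approximation with tie correction
and continuity correction, matching the standard asymptotic Mann-Whitney
test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm, rankdata

EXACT_MAX_N = 9  # largest per-side n handled exactly

_TINY = np.nextafter(0.0, 1.0)


def wilcoxon_onesided(chip_values, control_values) -> float:
    """One-sided rank-sum p-value, P(rank sum >= observed) under the null.

    Parameters
    ----------
    chip_values, control_values
        Equal-length vectors (length >= 2) of bin values.

    Returns
    -------
    float in (0, 1].  When every value in both samples is identical there
    is no evidence either way and the p-value is 1.
    """
    chip = np.asarray(chip_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if chip.ndim != 1 or control.ndim != 1 or len(chip) != len(control):
        raise ValueError("chip and control must be equal-length 1-D vectors")
    if len(chip) < 2:
        raise ValueError("need at least 2 values per side")
    if len(chip) <= EXACT_MAX_N:
        return _exact_rank_sum_p(chip, control)
    return _asymptotic_rank_sum_p(chip, control)


def _exact_rank_sum_p(chip: np.ndarray, control: np.ndarray) -> float:
    """Exact P(rank sum of the ChIP side >= observed) over all C(2n, n) splits.

    Mid-ranks are doubled so they are integers, and the null distribution of
    the size-n subset sum is built by dynamic programming over the doubled
    ranks (counts fit exactly in float64 at these sizes).
    """
    n = len(chip)
    ranks = rankdata(np.concatenate([chip, control]))
    t = np.rint(2 * ranks).astype(np.int64)
    obs = int(np.rint(2 * ranks[:n].sum()))
    maxsum = int(t.sum())
    # dp[k, s]: number of k-subsets of the items processed so far with doubled-rank sum s
    dp = np.zeros((n + 1, maxsum + 1))
    dp[0, 0] = 1.0
    for v in t:
        dp[1:, v:] += dp[:-1, :maxsum + 1 - v]
    total = math.comb(2 * n, n)
    ge = dp[n, obs:].sum()
    return float(ge / total)


def _asymptotic_rank_sum_p(chip: np.ndarray, control: np.ndarray) -> float:
    """Normal approximation with tie and continuity corrections."""
    n1 = len(chip)
    n2 = len(control)
    N = n1 + n2
    combined = np.concatenate([chip, control])
    ranks = rankdata(combined)
    # tie correction term sum(t^3 - t) over tied groups
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0  # all values identical: no evidence
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    z = (u - mu - 0.5) / math.sqrt(var)
    p = float(norm.sf(z))
    return min(1.0, max(_TINY, p))
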