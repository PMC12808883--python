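"""Nonparametric group comparisons for ROI contrast and relaxometry values.

Paired comparisons (pre vs post infusion within animals) use the Wilcoxon
signed-rank test; unpaired comparisons (MI vs healthy animals) use the
Mann-Whitney U test.  For small samples (n <= 25) the p-value comes from
the exact null distribution — computed here by dynamic programming over
signed midranks, so ties and zero differences (zero-split convention) are
handled exactly; larger samples fall back to the normal approximation
with tie correction.  All p-values are two-sided.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["group_compare", "signed_rank_exact", "significance_stars"]

EXACT_N_MAX = 25


def _wplus_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """PMF of the signed-rank statistic over doubled (integer) midranks.

    Each nonzero difference contributes its rank to W+ with probability
    1/2 under the null; the distribution is the convolution of those
    two-point laws, computed exactly on the doubled-rank integer lattice.
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = 0.5 * nxt
    return pmf


def signed_rank_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are zero-split: their ranks contribute half to each
    side and do not vary under sign flips, so identical samples give
    p = 1.  Midranks handle ties; the null distribution is exact even
    with ties.  Returns ``(w_plus, p)``.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum() + 0.5 * ranks[d == 0].sum())
    nz = d != 0
    const = 0.5 * ranks[d == 0].sum()  # fixed zero-split contribution
    doubled = np.round(2 * ranks[nz]).astype(int)
    if doubled.size == 0:
        return w_plus, 1.0
    pmf = _wplus_distribution(doubled)
    # statistic on the doubled lattice, minus the constant part
    w2 = int(round(2 * (w_plus - const)))
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    return w_plus, min(1.0, 2.0 * min(cdf, sf))


def group_compare(
    values_a: np.ndarray, values_b: np.ndarray, paired: bool
) -> tuple[float, float, int]:
    """Two-sided nonparametric comparison of two samples.

    Returns ``(statistic, p_value, n)`` where the statistic is W+ (paired)
    or the U of the first sample (unpaired) and ``n`` is the number of
    pairs, or of values in the first sample.  Exact null distribution for
    n <= 25, normal approximation with tie correction beyond.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length samples")
        n = len(a)
        if n < 3:
            raise ValueError("need at least 3 pairs")
        d = a - b
        if n <= EXACT_N_MAX:
            w, p = signed_rank_exact(d)
            return w, p, n
        res = sps.wilcoxon(a, b, zero_method="zsplit", correction=False, method="approx")
        return float(res.statistic), float(res.pvalue), n
    n, m = len(a), len(b)
    if min(n, m) < 3:
        raise ValueError("need at least 3 values per group")
    ties = len(np.unique(np.concatenate([a, b]))) < n + m
    if max(n, m) <= EXACT_N_MAX and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), n


def significance_stars(p: float) -> str:
    """Figure-legend star convention: *p<0.05, **p<0.01, ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
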