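"""Independent from-definition oracles used by the statistics tests."""

import numpy as np


def brute_force_friedman(x):
    """Rank-sum definition with hand-rolled mid-ranks and tie correction."""
    n, k = x.shape
    ranks = np.zeros_like(x, dtype=float)
    tie_sum = 0.0
    for i, row in enumerate(x):
        for j, v in enumerate(row):
            less = np.sum(row < v)
            equal = np.sum(row == v)
            ranks[i, j] = less + (equal + 1) / 2
        for v in set(row):
            t = np.sum(row == v)
            tie_sum += t**3 - t
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)
    return chi2 / (1 - tie_sum / (n * (k**3 - k)))


def anova_icc_oracle(x):
    """ICC(2,k) from an explicit two-way ANOVA decomposition (independent
    of the implementation's vectorised path)."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)
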