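"""Paired nonparametric system comparison and inter-rater agreement.

Implements the analysis battery applied to question x system score tables:

* percentile bootstrap CIs for per-system means,
* the Friedman test over within-question ranks with tie correction, with
  Kendall's W = chi2 / (n (k-1)) as effect size,
* all-pairs Wilcoxon signed-rank tests with Holm step-down adjustment and
  median paired differences,
* ICC(2,2) (two-way random effects, absolute agreement, average measures)
  for two raters,
* quadratic-weighted Cohen's kappa over ordinal totals, and
* absolute rater-difference summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "ComparisonReport",
    "PairedScoreMatrix",
    "PairwiseResult",
    "UndefinedStatisticError",
    "abs_diff_summary",
    "agreement_report",
    "bootstrap_ci",
    "compare_systems",
    "friedman_w",
    "holm_adjust",
    "icc_2_2",
    "weighted_kappa",
    "wilcoxon_holm",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given data."""


@dataclass(frozen=True)
class PairedScoreMatrix:
    """An n-questions x k-systems matrix of scores with no missing cells."""

    values: np.ndarray
    systems: tuple[str, ...]
    questions: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 2:
            raise ValueError("matrix must be two-dimensional")
        n, k = arr.shape
        if k != len(self.systems):
            raise ValueError("column count must match the number of systems")
        if n < 2 or k < 2:
            raise ValueError("need at least 2 questions and 2 systems")
        if np.isnan(arr).any():
            raise ValueError("matrix has missing cells")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value: str = "total", rater: Optional[str] = None
    ) -> "PairedScoreMatrix":
        """Pivot a long-format score table to questions x systems."""
        if rater is not None:
            df = df[df["rater"] == rater]
        wide = df.pivot_table(
            index=["template_id", "rs_id"], columns="system", values=value
        )
        if wide.isna().any().any():
            raise ValueError("score table has missing (question, system) cells")
        return cls(
            values=wide.to_numpy(dtype=float),
            systems=tuple(wide.columns),
            questions=tuple(wide.index),
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def bootstrap_ci(
    values: Sequence[float],
    level: float = 0.95,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean; deterministic for a fixed seed."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(reps, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1 - level) / 2
    low, high = np.quantile(means, [alpha, 1 - alpha])
    return float(low), float(high)


def friedman_w(matrix: PairedScoreMatrix) -> tuple[float, float, float]:
    """Friedman chi-square over within-row mid-ranks (tie-corrected),
    its chi-square p-value (k-1 df), and Kendall's W = chi2 / (n (k-1)).
    """
    x = matrix.values
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)

    # tie correction: sum of (t^3 - t) over tie groups of every row
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * (k**3 - k))
    if correction <= 0:
        raise UndefinedStatisticError(
            "Friedman statistic undefined: every row is constant"
        )

    rank_sums = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)) / correction
    p = float(stats.chi2.sf(chi2, df=k - 1))
    w = float(chi2 / (n * (k - 1)))
    return float(chi2), p, w


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment over one family of p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted.tolist()


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    p_raw: float
    p_adjusted: float
    median_diff: float
    degenerate: bool = False


def wilcoxon_holm(
    matrix: PairedScoreMatrix, zero_method: str = "wilcox"
) -> list[PairwiseResult]:
    """Paired Wilcoxon signed-rank tests for all system pairs, Holm-adjusted.

    Zero differences are discarded by default (``zero_method="wilcox"``;
    ``"pratt"`` is accepted).  Exact p-values are used for <= 25 nonzero
    pairs, otherwise the normal approximation with continuity correction.
    A pair with all-zero differences is degenerate and reported as p = 1.
    """
    pairs = list(combinations(range(matrix.k), 2))
    raw: list[float] = []
    medians: list[float] = []
    degenerate: list[bool] = []
    for i, j in pairs:
        d = matrix.values[:, i] - matrix.values[:, j]
        medians.append(float(np.median(d)))
        nonzero = int(np.count_nonzero(d))
        if nonzero == 0:
            raw.append(1.0)
            degenerate.append(True)
            continue
        method = "exact" if nonzero <= 25 else "approx"
        res = stats.wilcoxon(
            matrix.values[:, i],
            matrix.values[:, j],
            zero_method=zero_method,
            correction=True,
            method=method,
        )
        raw.append(float(res.pvalue))
        degenerate.append(False)
    adjusted = holm_adjust(raw)
    return [
        PairwiseResult(
            pair=(matrix.systems[i], matrix.systems[j]),
            p_raw=raw[m],
            p_adjusted=adjusted[m],
            median_diff=medians[m],
            degenerate=degenerate[m],
        )
        for m, (i, j) in enumerate(pairs)
    ]


def icc_2_2(ratings: np.ndarray) -> float:
    """ICC(2,2): two-way random effects, absolute agreement, average
    measures, for an n x 2 matrix of two raters' scores.

    Computed from the two-way ANOVA mean squares
    (rows = questions, columns = raters):
    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n).  May be negative.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("ratings must be an n x 2 matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 questions")
    if np.isnan(x).any():
        raise ValueError("ratings has missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means.var(), 0):
        raise UndefinedStatisticError(
            "ICC undefined: zero between-question variance"
        )
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


def weighted_kappa(
    r1: Sequence[float], r2: Sequence[float], n_categories: int = 51
) -> float:
    """Quadratic-weighted Cohen's kappa over ordinal categories 0..K-1.

    Weights are w_ij = 1 - (i - j)^2 / (K - 1)^2; expected agreement uses
    the marginals of the observed pair.  Defaults to K = 51 (integer totals
    0-50); half-integer means should be doubled to 0-100 before binning.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("r1 and r2 must be equal-length 1-D sequences")
    ai = np.rint(a).astype(int)
    bi = np.rint(b).astype(int)
    if not (np.allclose(a, ai) and np.allclose(b, bi)):
        raise ValueError("ratings must be integral (double half-integer means first)")
    if ai.min() < 0 or bi.min() < 0 or ai.max() >= n_categories or bi.max() >= n_categories:
        raise ValueError(f"ratings must lie in 0..{n_categories - 1}")
    if len(set(ai) | set(bi)) < 2:
        raise UndefinedStatisticError(
            "kappa undefined: a single distinct category in both raters"
        )

    K = n_categories
    observed = np.zeros((K, K))
    np.add.at(observed, (ai, bi), 1)
    observed /= len(ai)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    i, j = np.indices((K, K))
    weights = 1.0 - (i - j) ** 2 / (K - 1) ** 2
    po = float(np.sum(weights * observed))
    pe = float(np.sum(weights * expected))
    if np.isclose(pe, 1.0):
        raise UndefinedStatisticError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def abs_diff_summary(r1: Sequence[float], r2: Sequence[float]) -> tuple[float, float, float]:
    """(median, mean, max) of |r1 - r2|; symmetric in its arguments."""
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("r1 and r2 must have equal length")
    d = np.abs(a - b)
    return float(np.median(d)), float(np.mean(d)), float(np.max(d))


# ---------------------------------------------------------------------------
# Report assembly over long-format score tables


@dataclass(frozen=True)
class ComparisonReport:
    """Per-block system comparison: means with bootstrap CIs, Friedman/W,
    Holm-adjusted pairwise Wilcoxon results."""

    block: str
    systems: tuple[str, ...]
    n_questions: int
    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    friedman_chi2: float
    friedman_p: float
    kendall_w: float
    pairwise: list[PairwiseResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "block": self.block,
            "systems": list(self.systems),
            "n_questions": self.n_questions,
            "means": self.means,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "friedman_chi2": self.friedman_chi2,
            "friedman_p": self.friedman_p,
            "kendall_w": self.kendall_w,
            "pairwise": [
                {
                    "pair": list(p.pair),
                    "p_raw": p.p_raw,
                    "p_adjusted": p.p_adjusted,
                    "median_diff": p.median_diff,
                    "degenerate": p.degenerate,
                }
                for p in self.pairwise
            ],
        }


@dataclass(frozen=True)
class AgreementReport:
    icc_2_2: float
    quadratic_weighted_kappa: float
    abs_diff_median: float
    abs_diff_mean: float
    abs_diff_max: float
    n: int

    def to_dict(self) -> dict:
        return {
            "icc_2_2": self.icc_2_2,
            "quadratic_weighted_kappa": self.quadratic_weighted_kappa,
            "abs_diff_median": self.abs_diff_median,
            "abs_diff_mean": self.abs_diff_mean,
            "abs_diff_max": self.abs_diff_max,
            "n": self.n,
        }


def _mean_rater_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Average raters per (question, system); keeps criterion columns and total."""
    value_cols = [c for c in df.columns if c not in ("template_id", "rs_id", "system", "rater", "category")]
    grouped = (
        df.groupby(["template_id", "rs_id", "system"], as_index=False)[value_cols].mean()
    )
    return grouped


def compare_systems(
    df: pd.DataFrame,
    by: str = "criterion",
    categories: Optional[dict[str, str]] = None,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> list[ComparisonReport]:
    """Build comparison reports from a long-format score table.

    ``by="criterion"`` produces one block per criterion plus the total;
    ``by="category"`` one block of totals per question category (requires a
    ``template_id -> category`` mapping or a ``category`` column).
    """
    from varqa.evaluation import CRITERIA

    if "total" not in df.columns:
        df = df.copy()
        df["total"] = df[list(CRITERIA)].sum(axis=1)
    mean_df = _mean_rater_frame(df)

    blocks: list[tuple[str, pd.DataFrame, str]] = []
    if by == "criterion":
        for value in ("total", *CRITERIA):
            blocks.append((value, mean_df, value))
    elif by == "category":
        if "category" in df.columns:
            cat_map = dict(zip(df["template_id"], df["category"]))
        elif categories is not None:
            cat_map = categories
        else:
            raise ValueError("category comparison needs a template_id -> category mapping")
        mean_df = mean_df.assign(category=mean_df["template_id"].map(cat_map))
        for cat in sorted(mean_df["category"].dropna().unique()):
            blocks.append((cat, mean_df[mean_df["category"] == cat], "total"))
    else:
        raise ValueError("by must be 'criterion' or 'category'")

    reports = []
    rng_seed = seed
    for name, frame, value in blocks:
        matrix = PairedScoreMatrix.from_frame(frame, value=value)
        chi2, p, w = friedman_w(matrix)
        means, lows, highs = {}, {}, {}
        for col, system in enumerate(matrix.systems):
            vals = matrix.values[:, col]
            means[system] = float(vals.mean())
            lows[system], highs[system] = bootstrap_ci(vals, reps=reps, seed=rng_seed)
        reports.append(
            ComparisonReport(
                block=name,
                systems=matrix.systems,
                n_questions=matrix.n,
                means=means,
                ci_low=lows,
                ci_high=highs,
                friedman_chi2=chi2,
                friedman_p=p,
                kendall_w=w,
                pairwise=wilcoxon_holm(matrix),
            )
        )
    return reports


def agreement_report(df: pd.DataFrame, raters: Optional[tuple[str, str]] = None) -> AgreementReport:
    """Inter-rater agreement on total scores pooled across systems.

    Half-integer totals are doubled to the 0-100 scale before kappa binning.
    """
    from varqa.evaluation import CRITERIA

    if "total" not in df.columns:
        df = df.copy()
        df["total"] = df[list(CRITERIA)].sum(axis=1)
    names = raters if raters is not None else tuple(sorted(df["rater"].unique()))
    if len(names) != 2:
        raise ValueError(f"need exactly 2 raters, found {names}")
    wide = df.pivot_table(
        index=["template_id", "rs_id", "system"], columns="rater", values="total"
    )[list(names)]
    if wide.isna().any().any():
        raise ValueError("score table has missing rater cells")
    x = wide.to_numpy(dtype=float)

    r1, r2 = x[:, 0], x[:, 1]
    if np.allclose(r1, np.rint(r1)) and np.allclose(r2, np.rint(r2)):
        kappa = weighted_kappa(r1, r2, n_categories=51)
    else:
        kappa = weighted_kappa(2 * r1, 2 * r2, n_categories=101)
    med, mean, mx = abs_diff_summary(r1, r2)
    return AgreementReport(
        icc_2_2=icc_2_2(x),
        quadratic_weighted_kappa=kappa,
        abs_diff_median=med,
        abs_diff_mean=mean,
        abs_diff_max=mx,
        n=x.shape[0],
    )
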