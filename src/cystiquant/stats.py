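"""Cohort-level statistics: Fisher's exact test, the chi-square test for
trend, the Mann-Whitney test and Spearman's rank correlation, plus the
fixture summaries (inflamed/normal fractions, restriction counts).

Conventions
-----------
* Fisher two-sided p uses the point-probability method: the sum of
  hypergeometric probabilities of all tables (with the observed margins)
  whose probability does not exceed that of the observed table.  The
  per-table comparison is done on exact integer weights, so ties at the
  observed probability are handled without floating-point ambiguity.
* The trend test is the Cochran-Armitage statistic with equally spaced
  column scores, no continuity correction, referred to chi-square with
  1 df (two-sided).  The statistic is invariant under affine rescaling of
  the scores.
* Mann-Whitney: exact tie-aware enumeration when both groups have at most
  8 observations; otherwise the tie-corrected normal approximation.  The
  exact two-sided p doubles the smaller inclusive tail (capped at 1),
  which is well defined because the null distribution of U is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class ContingencyTable:
    """Ordered 2xK (or RxC) count grid; column order matters for trend."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("counts must be at least 2x2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) != c.shape[0] or len(self.col_labels) != c.shape[1]:
            raise ValueError("label lengths must match the count grid")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_counts(cls, counts, row_labels=None, col_labels=None) -> "ContingencyTable":
        c = np.asarray(counts, dtype=np.int64)
        rows = tuple(row_labels) if row_labels else tuple(f"r{i}" for i in range(c.shape[0]))
        cols = tuple(col_labels) if col_labels else tuple(f"c{j}" for j in range(c.shape[1]))
        return cls(rows, cols, c)


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher's exact test (point-probability method).

    With margins fixed, table probabilities are proportional to the integer
    weights ``C(r1, a) * C(r2, c1 - a)``; the two-sided p sums weights not
    exceeding the observed one, divided by ``C(N, c1)``.
    """
    c = table.counts
    if c.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got {c.shape}")
    a, b = int(c[0, 0]), int(c[0, 1])
    cc, d = int(c[1, 0]), int(c[1, 1])
    r1, r2 = a + b, cc + d
    c1 = a + cc
    n = r1 + r2
    if n == 0:
        return TestResult("fisher_exact", math.nan, 1.0)
    lo, hi = max(0, c1 - r2), min(c1, r1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(n, c1)
    p_num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= w_obs
    )
    odds = (a * d) / (b * cc) if b * cc > 0 else math.inf
    return TestResult("fisher_exact", odds, p_num / total)


def chi2_trend(table: ContingencyTable, scores=None) -> TestResult:
    """Cochran-Armitage chi-square test for trend on a 2xK table.

    ``scores`` default to 0..K-1.  The standardized statistic is invariant
    under affine transformations of the scores; p is two-sided from the
    1-df chi-square distribution.
    """
    c = table.counts
    if c.shape[0] != 2 or c.shape[1] < 3:
        raise ValueError(f"trend test needs a 2xK table with K >= 3, got {c.shape}")
    k = c.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.shape != (k,):
        raise ValueError("scores must match the number of columns")
    n = c.sum()
    if n == 0:
        return TestResult("chi2_trend", 0.0, 1.0)
    col = c.sum(axis=0).astype(float)
    r1 = float(c[0].sum())
    t_obs = float(c[0] @ s)
    mean = r1 * (col @ s) / n
    # Hypergeometric (finite-population) variance of the score sum.
    sbar = (col @ s) / n
    var = r1 * (n - r1) / (n - 1) * (col @ (s - sbar) ** 2) / n if n > 1 else 0.0
    if var <= 0:
        return TestResult("chi2_trend", 0.0, 1.0)
    stat = (t_obs - mean) ** 2 / var
    return TestResult("chi2_trend", stat, float(sps.chi2.sf(stat, df=1)))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a over b, ties counted half."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney test.

    Exact enumeration over all group assignments of the pooled values when
    both groups have <= 8 observations (tie-aware); otherwise normal
    approximation with tie correction, no continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    na, nb = a.size, b.size
    if na <= EXACT_MW_MAX_N and nb <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        n_le = n_ge = n_tot = 0
        for comb in combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            n_tot += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / n_tot)
        return TestResult("mann_whitney_exact", u_obs, p)
    # Tie-corrected normal approximation.
    n = na + nb
    mu = na * nb / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult("mann_whitney_normal", u_obs, 1.0)
    z = (u_obs - mu) / math.sqrt(var)
    return TestResult(
        "mann_whitney_normal", u_obs, float(2.0 * sps.norm.sf(abs(z)))
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", math.nan, 1.0)
    res = sps.spearmanr(x, y)
    return TestResult("spearman", float(res.statistic), float(res.pvalue))


def summarize_inflammation(
    table3: pd.DataFrame, cutoff_bin: str = "<200"
) -> dict[str, float]:
    """Inflamed/normal percentages per group from a binned density grid.

    Expects columns group, grade, plus the ordered density-bin columns
    ("<200", "200-1000", ">1000").  A specimen is "normal" when it falls
    in the sub-cutoff bin and "inflamed" otherwise; percentages are given
    to one decimal (half-up), as conventionally printed.
    """
    bin_cols = [c for c in table3.columns if c not in ("group", "grade")]
    if cutoff_bin not in bin_cols:
        raise ValueError(f"cutoff bin {cutoff_bin!r} not among {bin_cols}")
    out: dict[str, float] = {}
    for group, sub in table3.groupby("group"):
        total = int(sub[bin_cols].to_numpy().sum())
        if total == 0:
            raise ValueError(f"group {group} has no specimens")
        normal = int(sub[cutoff_bin].sum())
        out[f"{group}_normal_percent"] = _round1(100.0 * normal / total)
        out[f"{group}_inflamed_percent"] = _round1(100.0 * (total - normal) / total)
        out[f"{group}_n"] = total
        out[f"{group}_inflamed_n"] = total - normal
    return out


def _round1(x: float) -> float:
    """Round half up to one decimal, matching printed percentages."""
    return math.floor(x * 10 + 0.5) / 10


def compare_groups(
    data: pd.DataFrame, variable: str, grouping: str, kind: str | None = None
) -> TestResult:
    """Dispatch a two-group comparison to the appropriate test.

    Categorical variables go to Fisher (2 levels) or the trend test
    (>= 3 ordered levels); continuous variables to Mann-Whitney.  ``kind``
    may force "categorical" or "continuous"; otherwise non-numeric or
    low-cardinality integer columns are treated as categorical.
    """
    groups = [g for _, g in data.groupby(grouping, sort=True)]
    if len(groups) != 2:
        raise ValueError("grouping must define exactly 2 groups")
    col = data[variable]
    if kind is None:
        if col.dtype.kind in "OUSb":
            kind = "categorical"
        elif col.dtype.kind in "iu" and col.nunique() <= 5:
            kind = "categorical"
        elif col.dtype.kind in "iuf":
            kind = "continuous"
        else:
            raise ValueError(f"cannot infer variable kind for dtype {col.dtype}")
    if kind == "continuous":
        return mann_whitney(groups[0][variable], groups[1][variable])
    if kind != "categorical":
        raise ValueError(f"unknown variable kind {kind!r}")
    levels = sorted(col.unique())
    counts = np.array(
        [[int((g[variable] == lv).sum()) for lv in levels] for g in groups]
    )
    table = ContingencyTable.from_counts(counts, col_labels=[str(v) for v in levels])
    if len(levels) == 2:
        return fisher_exact_2x2(table)
    return chi2_trend(table)
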