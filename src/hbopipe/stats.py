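"""Group-comparison statistics: unpaired t-tests (raw values or published
summary statistics), one-way ANOVA with Šídák-adjusted pairwise
comparisons, Shapiro-Wilk normality screening, and a robust FDR-controlled
outlier screen for the one-sample location case."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupSample:
    """One group's observations, either raw values or a (mean, spread, n)
    summary.  ``spread_is_sem`` tells whether ``spread`` is the standard
    error of the mean (the usual convention for published "mean ± x" values)
    or the standard deviation."""

    label: str
    values: np.ndarray | None = None
    mean: float | None = None
    spread: float | None = None
    n: int | None = None
    spread_is_sem: bool = True

    def __post_init__(self):
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            self.n = self.values.size
            self.mean = float(self.values.mean()) if self.n else None
        if self.n is None or self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2")
        if self.values is None:
            if self.mean is None or self.spread is None:
                raise ValueError(f"group {self.label!r}: summary form needs mean, spread, n")
            if not self.spread > 0:
                raise ValueError(f"group {self.label!r}: spread must be positive")

    @property
    def sd(self) -> float:
        if self.values is not None:
            return float(self.values.std(ddof=1))
        return self.spread * sqrt(self.n) if self.spread_is_sem else self.spread


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    p_adjusted: float | None = None
    method: str = ""
    comparison: tuple[str, str] | None = None


def unpaired_t(a: GroupSample, b: GroupSample, variant: str = "pooled") -> TestResult:
    """Two-tailed unpaired t-test from raw values or summary statistics.

    ``variant="pooled"`` is the classical Student test (equal variances);
    ``"welch"`` uses the Welch-Satterthwaite correction.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    m1, m2 = a.mean, b.mean
    s1, s2 = a.sd, b.sd
    n1, n2 = a.n, b.n
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if se == 0:
        t = 0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)
    else:
        t = (m1 - m2) / se
    p = float(2 * _st.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(statistic=float(t), df=float(df), p=p, method=f"unpaired_t_{variant}",
                      comparison=(a.label, b.label))


def sidak_adjust(p: float, m: int) -> float:
    """Šídák family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    # -expm1(m*log1p(-p)) keeps p_adj >= p even for p near underflow
    if p == 1.0:
        return 1.0
    return float(-np.expm1(m * np.log1p(-p)))


def anova_sidak(
    groups: list[GroupSample],
    comparisons: list[tuple[str, str]] | None = None,
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA followed by Šídák multiple comparisons.

    The omnibus F uses the usual between/within sums of squares.  Each
    pairwise comparison is a t-test on the group means with the pooled
    within-group mean square (df = N - g) as the variance estimate, and its
    p is Šídák-adjusted with m = number of requested comparisons (default:
    all pairs).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.values is None for g in groups):
        raise ValueError("anova_sidak needs raw values for every group")
    data = {g.label: np.asarray(g.values, dtype=float) for g in groups}
    ns = {k: v.size for k, v in data.items()}
    if any(n < 2 for n in ns.values()):
        raise ValueError("every group needs n >= 2")
    all_vals = np.concatenate(list(data.values()))
    grand = all_vals.mean()
    ss_between = sum(n * (v.mean() - grand) ** 2 for v, n in ((v, v.size) for v in data.values()))
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    ms_w = ss_within / df_w
    f = (ss_between / df_b) / ms_w
    omnibus = TestResult(statistic=float(f), df=float(df_w), p=float(_st.f.sf(f, df_b, df_w)),
                         method="anova_oneway")

    if comparisons is None:
        comparisons = list(combinations([g.label for g in groups], 2))
    m = len(comparisons)
    results = []
    for la, lb in comparisons:
        va, vb = data[la], data[lb]
        se = sqrt(ms_w * (1 / va.size + 1 / vb.size))
        t = (va.mean() - vb.mean()) / se
        p = float(2 * _st.t.sf(abs(t), df_w))
        results.append(
            TestResult(statistic=float(t), df=float(df_w), p=p,
                       p_adjusted=sidak_adjust(p, m), method="sidak_pairwise",
                       comparison=(la, lb))
        )
    return omnibus, results


def shapiro_wilk(values: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {values.size}")
    w, p = _st.shapiro(values)
    return TestResult(statistic=float(w), df=float(values.size), p=float(p), method="shapiro_wilk")


def outlier_screen(values: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Robust FDR-controlled outlier flags for a single sample.

    The ROUT idea (robust fit, then outlier detection with FDR control)
    reduced to the constant-location model: centre = median, scale =
    normal-consistent MAD; each point gets a two-tailed normal p-value for
    its robust z-score and the Benjamini-Hochberg procedure at rate ``q``
    flags the outliers.  Returns a boolean array (True = outlier).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        # degenerate scale (>=50% identical values): fall back to a mean-based
        # spread so a gross point among constants is still catchable
        scale = np.mean(np.abs(values - med)) * sqrt(np.pi / 2)
    if scale == 0:
        return np.zeros(values.size, dtype=bool)
    z = (values - med) / scale
    p = 2 * _st.norm.sf(np.abs(z))
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
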