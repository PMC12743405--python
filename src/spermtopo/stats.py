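"""Summary statistics and the fraction-comparison testing policy.

Group comparisons follow a normality-gated two-branch policy: Shapiro–Wilk
on each group at the working alpha; if all groups look normal, Welch's
unequal-variance t-test, otherwise the Mann–Whitney rank-sum test.  Three
or more groups go through a tie-corrected Kruskal–Wallis omnibus followed
by Dunn's pairwise z-tests with Bonferroni adjustment.  Every result
reports which test produced it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "StatsConfig",
    "TestResult",
    "summary",
    "percent_change",
    "fold_change",
    "round_half_up",
    "two_group_test",
    "kw_dunn",
    "shapiro_wilk",
]


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n−1 denominator), and SE = SD/√n."""

    n: int
    mean: float
    sd: float
    se: float


@dataclass(frozen=True)
class StatsConfig:
    """Testing policy knobs.

    alpha: significance level for all decisions.
    normality_gate: if True, two-group tests use Welch's t only when both
        groups pass Shapiro–Wilk at alpha; if False, always rank-sum.
    force_test: override the gate entirely ("welch" or "ranksum"), or None.
    adjustment: multiple-comparison family correction for Dunn ("bonferroni"
        or "none").
    """

    alpha: float = 0.05
    normality_gate: bool = True
    force_test: str | None = None
    adjustment: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.force_test not in (None, "welch", "ranksum"):
            raise ValueError(f"unknown force_test: {self.force_test!r}")
        if self.adjustment not in ("bonferroni", "none"):
            raise ValueError(f"unknown adjustment: {self.adjustment!r}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    test: str


def summary(values) -> SummaryStats:
    """Mean, sample SD and SE of a sample (n ≥ 2 required for SD)."""
    x = np.asarray(values, float)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values for SD/SE, got {n}")
    sd = float(np.std(x, ddof=1))
    return SummaryStats(n=n, mean=float(np.mean(x)), sd=sd, se=sd / math.sqrt(n))


def percent_change(ref: float, new: float) -> float:
    """Relative change 100·(new − ref)/ref, in percent."""
    if ref == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new - ref) / ref


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (reporting convention for fold changes)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(ref: float, new: float, direction: str = "increase") -> float:
    """Fold change between two positive values.

    ``increase`` → new/ref, ``decrease`` → ref/new.  Unrounded; use
    :func:`round_half_up` for 2-decimal reporting.
    """
    if ref <= 0 or new <= 0:
        raise ValueError("fold_change requires positive inputs")
    if direction == "increase":
        return new / ref
    if direction == "decrease":
        return ref / new
    raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for 3 ≤ n ≤ 5000."""
    x = np.asarray(values, float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _all_tied(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return bool(np.ptp(pooled) == 0)


def two_group_test(x, y, config: StatsConfig | None = None) -> TestResult:
    """Compare two independent groups under the normality-gated policy.

    Returns a two-sided p-value and the name of the test actually used
    ("welch-t" or "mann-whitney").
    """
    cfg = config or StatsConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if _all_tied(x, y):
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return TestResult(statistic=float("nan"), p=1.0, test="mann-whitney")

    use_welch = cfg.force_test == "welch"
    if cfg.force_test is None and cfg.normality_gate:
        def _normal(g: np.ndarray) -> bool:
            if np.ptp(g) == 0:
                return False
            return sps.shapiro(g)[1] > cfg.alpha

        use_welch = _normal(x) and _normal(y)

    if use_welch:
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        return TestResult(statistic=float(stat), p=float(p), test="welch-t")
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(statistic=float(stat), p=float(p), test="mann-whitney")


def _dunn_pairwise(groups: list[np.ndarray], adjustment: str) -> np.ndarray:
    """Dunn's z-test p-values for all group pairs, tie-corrected.

    Ranks are pooled over all groups; the z statistic for pair (i, j) is
    the difference of mean ranks over its standard error under H0, with
    the usual tie correction to the pooled-rank variance.
    """
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    mean_ranks = np.array(mean_ranks)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    p = np.ones((k, k))
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (
                1.0 / sizes[i] + 1.0 / sizes[j]
            )
            if var <= 0:
                pij = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
                pij = 2.0 * sps.norm.sf(abs(z))
            if adjustment == "bonferroni":
                pij = min(1.0, pij * n_pairs)
            p[i, j] = p[j, i] = pij
    return p


@dataclass(frozen=True)
class KwDunnResult:
    omnibus_statistic: float
    omnibus_p: float
    pairwise_p: np.ndarray  # adjusted, symmetric, 1 on the diagonal
    test: str


def kw_dunn(groups, config: StatsConfig | None = None) -> KwDunnResult:
    """Kruskal–Wallis omnibus plus Dunn pairwise comparisons.

    With exactly two groups, delegates to :func:`two_group_test` forced to
    the rank-sum branch (pairwise matrix holds the same p).
    """
    cfg = config or StatsConfig()
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")

    if len(arrays) == 2:
        res = two_group_test(
            arrays[0], arrays[1],
            StatsConfig(alpha=cfg.alpha, normality_gate=False, force_test="ranksum"),
        )
        pw = np.array([[1.0, res.p], [res.p, 1.0]])
        return KwDunnResult(res.statistic, res.p, pw, test="mann-whitney")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; omnibus p = 1", stacklevel=2)
        k = len(arrays)
        return KwDunnResult(0.0, 1.0, np.ones((k, k)), test="kruskal-dunn")

    stat, p = sps.kruskal(*arrays)
    pw = _dunn_pairwise(arrays, cfg.adjustment)
    return KwDunnResult(float(stat), float(p), pw, test="kruskal-dunn")
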