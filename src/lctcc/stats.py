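"""Two-sample comparison with a normality-gated choice of test.

Normality of each sample (and of the paired differences) is checked with
the Lilliefors test — a Kolmogorov–Smirnov test against a normal
distribution with mean and standard deviation estimated from the data,
whose null distribution is obtained by seeded Monte-Carlo simulation.
When both samples pass, Student's t (paired or unpaired) is used;
otherwise the Wilcoxon signed-rank (paired) or Mann–Whitney U (unpaired)
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .types import ValidationError

__all__ = ["TestResult", "lilliefors", "compare_groups"]

N_MC = 10_000  # Monte-Carlo replicates for the Lilliefors null
_MC_SEED = 987654321  # fixed so p-values are reproducible across calls
_null_cache: dict = {}


@dataclass
class TestResult:
    statistic: float
    p: float
    test_name: str   # t_paired | t_unpaired | wilcoxon_signed_rank | mann_whitney_u
    normality_p: float  # smallest Lilliefors p among the gated samples
    degenerate: bool = False


def _ks_normal_stat(x: np.ndarray) -> float:
    """KS distance between the ECDF of x and N(mean(x), sd(x))."""
    x = np.sort(x)
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        return 1.0
    z = sst.norm.cdf((x - x.mean()) / sd)
    up = np.arange(1, n + 1) / n - z
    lo = z - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


def _null_stats(n: int, n_mc: int = N_MC) -> np.ndarray:
    key = (n, n_mc)
    if key not in _null_cache:
        rng = np.random.default_rng(_MC_SEED + n)
        sims = rng.standard_normal((n_mc, n))
        sims.sort(axis=1)
        means = sims.mean(axis=1, keepdims=True)
        sds = sims.std(axis=1, ddof=1, keepdims=True)
        z = sst.norm.cdf((sims - means) / sds)
        ranks = np.arange(1, n + 1) / n
        up = (ranks - z).max(axis=1)
        lo = (z - (ranks - 1 / n)).max(axis=1)
        _null_cache[key] = np.maximum(up, lo)
    return _null_cache[key]


def lilliefors(x, n_mc: int = N_MC) -> tuple:
    """Lilliefors normality test; returns (statistic, Monte-Carlo p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValidationError("lilliefors needs n >= 4")
    d = _ks_normal_stat(x)
    null = _null_stats(x.size, n_mc)
    p = float((np.count_nonzero(null >= d) + 1) / (null.size + 1))
    return d, p


def compare_groups(x, y, paired: bool = False, alpha_normality: float = 0.05) -> TestResult:
    """Normality-gated two-sample comparison (two-sided).

    Paired designs gate on the Lilliefors p of the differences; unpaired
    designs on each sample separately.  A zero-variance sample forces the
    nonparametric branch (flagged ``degenerate``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("compare_groups needs n >= 3 per group")
    if paired and x.size != y.size:
        raise ValidationError("paired comparison needs equal lengths")

    degenerate = x.std() == 0 or y.std() == 0 or (paired and (x - y).std() == 0)
    if degenerate:
        norm_p = 0.0
        normal = False
    elif paired:
        _, norm_p = lilliefors(x - y)
        normal = norm_p > alpha_normality
    else:
        _, px = lilliefors(x)
        _, py = lilliefors(y)
        norm_p = min(px, py)
        normal = px > alpha_normality and py > alpha_normality

    if normal:
        if paired:
            stat, p = sst.ttest_rel(x, y)
            name = "t_paired"
        else:
            stat, p = sst.ttest_ind(x, y)
            name = "t_unpaired"
    elif paired:
        d = x - y
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sst.wilcoxon(x, y)
        name = "wilcoxon_signed_rank"
    else:
        stat, p = sst.mannwhitneyu(x, y, alternative="two-sided")
        name = "mann_whitney_u"
    return TestResult(float(stat), float(p), name, float(norm_p), degenerate)
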