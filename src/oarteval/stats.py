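"""Cohort-level statistics: median [range] summaries, paired Wilcoxon
signed-rank tests with Bonferroni correction, manual-correction accounting.

The Wilcoxon test is implemented exactly for small samples: zero differences
are discarded (classical convention), absolute differences are ranked with
average ranks for ties, and the two-sided p-value is obtained from the full
null distribution of the positive rank sum over all 2^n sign assignments,
computed by polynomial convolution (equivalent to explicit enumeration).
Above ``exact_n_max`` effective pairs a normal approximation with tie-corrected
variance and continuity correction is used.  The exact path handles ties,
which the textbook tables (and scipy's exact method) do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .core import StatsConfig, ValidationError

__all__ = [
    "PairedSample",
    "TestResult",
    "summarize",
    "wilcoxon_signed_rank",
    "bonferroni",
    "correction_frequencies",
]


@dataclass
class PairedSample:
    """Index-aligned per-session measurements for the two arms."""

    label: str
    values_clin: np.ndarray
    values_auto: np.ndarray

    def __post_init__(self) -> None:
        self.values_clin = np.asarray(self.values_clin, dtype=float)
        self.values_auto = np.asarray(self.values_auto, dtype=float)
        if self.values_clin.shape != self.values_auto.shape:
            raise ValidationError(
                f"paired sample {self.label!r}: arm lengths differ "
                f"({self.values_clin.size} vs {self.values_auto.size})"
            )

    @property
    def differences(self) -> np.ndarray:
        return self.values_auto - self.values_clin


@dataclass
class TestResult:
    statistic: float  # W = min of the signed rank sums
    p_value: float
    n_effective: int  # pairs remaining after discarding zero differences
    n_zero: int
    significant: bool
    method: str  # 'exact' or 'normal_approx'


def summarize(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max) of a non-empty sequence; median is the midpoint of
    the two central order statistics for even n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("summarize requires a non-empty sequence")
    return float(np.median(v)), float(v.min()), float(v.max())


def _exact_p(ranks2: np.ndarray, w_plus2: int) -> float:
    """Two-sided exact p for the positive rank sum.

    ``ranks2`` are the (possibly tied, averaged) ranks doubled to integers;
    ``w_plus2`` is the doubled observed positive rank sum.  The distribution
    of the doubled positive rank sum over all 2^n equiprobable sign
    assignments is built by convolving ``(1 + x^{2 r_i})`` factors; it is
    symmetric about half the total, so the two-sided p-value is
    ``min(1, P(W+ <= w) + P(W+ >= S - w))`` with ``w`` the min-side sum.
    """
    total2 = int(ranks2.sum())
    counts = np.zeros(total2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(ranks2)
    w_low = min(w_plus2, total2 - w_plus2)
    p_low = counts[: w_low + 1].sum() / n_assign
    p_high = counts[total2 - w_low :].sum() / n_assign
    return float(min(1.0, p_low + p_high))


def wilcoxon_signed_rank(
    pairs: PairedSample, config: StatsConfig | None = None
) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test between the two arms."""
    config = config or StatsConfig()
    d = pairs.differences
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        raise ValidationError(
            f"Wilcoxon test undefined for {pairs.label!r}: all differences are zero"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= config.exact_n_max:
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _exact_p(ranks2, int(round(2 * w_plus)))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            raise ValidationError("degenerate Wilcoxon variance (all ranks tied)")
        # continuity correction toward the mean; W is the min-side sum
        z = (w - mean + 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.cdf(z)))
        method = "normal_approx"

    return TestResult(
        statistic=w,
        p_value=p,
        n_effective=n,
        n_zero=n_zero,
        significant=bool(p < config.corrected_alpha),
        method=method,
    )


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison level alpha / m."""
    if m < 1:
        raise ValidationError("family size must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    return alpha / m


def correction_frequencies(
    corrections: Iterable[Mapping[str, bool]],
    roles: Sequence[str] = ("bladder", "rectum", "GTV"),
) -> dict[str, float]:
    """Percent of sessions with a manual adjustment per role, plus the
    percent of sessions with no adjustment to any monitored role ('none')."""
    flags = list(corrections)
    n = len(flags)
    if n == 0:
        return {role: 0.0 for role in roles} | {"none": 100.0}
    out = {
        role: 100.0 * sum(bool(f.get(role, False)) for f in flags) / n for role in roles
    }
    out["none"] = (
        100.0 * sum(not any(bool(f.get(r, False)) for r in roles) for f in flags) / n
    )
    return out
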