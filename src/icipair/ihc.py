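"""IHC H-scores and the study's paired / contingency statistics.

The H-score summarizes a stained section as sum(intensity x percent of
cells at that intensity) over intensities 1-3, range 0-300.  Paired
pre/post comparisons use the Wilcoxon signed-rank test with an exact
small-sample branch (full sign-flip null, average ranks for ties), and
categorical associations use Fisher's exact test (probability-ordering
two-sided convention) with a chi-square fallback for large tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: sample size above which the signed-rank test switches from the exact
#: sign-flip null to the normal approximation
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class IntensityProfile:
    """Percent of cells at staining intensity 0..3; must sum to 100."""

    pct0: float
    pct1: float
    pct2: float
    pct3: float

    def __post_init__(self) -> None:
        parts = (self.pct0, self.pct1, self.pct2, self.pct3)
        if any(p < 0 or p > 100 for p in parts):
            raise ValueError(f"intensity percentages must be in [0,100]: {parts}")
        if abs(sum(parts) - 100.0) > 1e-6:
            raise ValueError(f"intensity percentages must sum to 100: {parts}")


@dataclass
class PairedSeries:
    """Matched (pre, post) measurements; both halves required."""

    pre: list[float]
    post: list[float]
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.pre) != len(self.post):
            raise ValueError("pre and post series differ in length")
        if len(self.pre) < 1:
            raise ValueError("need at least one pair")
        if any(v is None or not math.isfinite(v) for v in [*self.pre, *self.post]):
            raise ValueError("paired series contains missing or non-finite values")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.post, dtype=float) - np.asarray(self.pre, dtype=float)


def h_score(profile: IntensityProfile) -> float:
    """H = 1*pct1 + 2*pct2 + 3*pct3, in [0, 300]."""
    return profile.pct1 + 2.0 * profile.pct2 + 3.0 * profile.pct3


def delta_h(pre: float, post: float) -> tuple[float, float | None]:
    """Absolute and percent change of an H-score pair.

    Percent change from a zero baseline is undefined and returned as None
    rather than an infinity.
    """
    for v in (pre, post):
        if not (0.0 <= v <= 300.0):
            raise ValueError(f"H-score {v} outside [0, 300]")
    absolute = post - pre
    percent = None if pre == 0 else 100.0 * absolute / pre
    return absolute, percent


def _signed_ranks(diffs: np.ndarray, zero_policy: str) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |d| and the signs, after the zero policy.

    ``drop`` discards zero differences before ranking (classic Wilcoxon);
    ``pratt`` ranks zeros with everything else and then discards their
    rank contribution.
    """
    if zero_policy not in ("drop", "pratt"):
        raise ValueError("zero_policy must be 'drop' or 'pratt'")
    if zero_policy == "drop":
        diffs = diffs[diffs != 0]
        if diffs.size == 0:
            return np.array([]), np.array([])
        ranks = sps.rankdata(np.abs(diffs))
        return ranks, np.sign(diffs)
    ranks = sps.rankdata(np.abs(diffs))
    nz = diffs != 0
    return ranks[nz], np.sign(diffs[nz])


def _exact_signed_rank_p(ranks: np.ndarray, signs: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments.

    The distribution of W+ (sum of ranks with positive sign) is built by
    convolution over the fixed rank multiset — ranks depend only on |d|,
    so they are invariant under sign flips even with ties.  Two-sided p is
    the doubled smaller tail, capped at 1.  Ranks are doubled so average
    ranks (which can be half-integers) index an integer lattice.
    """
    doubled = np.rint(ranks * 2).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(doubled)
    w_obs = int(np.rint(ranks[signs > 0].sum() * 2))
    p_low = float(dist[: w_obs + 1].sum())
    p_high = float(dist[w_obs:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def _approx_signed_rank_p(ranks: np.ndarray, signs: np.ndarray) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = len(ranks)
    w = ranks[signs > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return 1.0
    d = w - mean
    z = (d - 0.5 * np.sign(d)) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def paired_wilcoxon(series: PairedSeries, zero_policy: str = "drop") -> float:
    """Two-sided Wilcoxon signed-rank p for a paired series.

    Exact by enumeration of the sign-flip null for n <= 25 informative
    pairs; normal approximation with continuity correction above.  Tied
    |differences| receive average ranks in both branches.  All-zero
    differences give p = 1 with a warning.
    """
    ranks, signs = _signed_ranks(series.differences, zero_policy)
    if ranks.size == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 1.0
    if ranks.size <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p(ranks, signs)
    return _approx_signed_rank_p(ranks, signs)


def fisher_exact(a: int, b: int, c: int, d: int, method: str = "prob") -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    ``prob`` (default) sums hypergeometric probabilities of all tables
    with fixed margins whose probability does not exceed the observed
    table's; ``central`` doubles the smaller one-sided tail.  A zero
    margin makes the table degenerate: p = 1 with a warning.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"counts must be nonnegative integers: {cells}")
    a, b, c, d = (int(x) for x in cells)
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.warning("degenerate 2x2 table (zero margin): p = 1")
        return 1.0
    if method == "prob":
        return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if method == "central":
        p_less = float(sps.fisher_exact([[a, b], [c, d]], alternative="less")[1])
        p_greater = float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        return min(1.0, 2.0 * min(p_less, p_greater))
    raise ValueError("method must be 'prob' or 'central'")


def chi2_association(a: int, b: int, c: int, d: int, correction: bool = True) -> float:
    """Continuity-corrected chi-square p — the large-sample fallback to
    the exact test."""
    table = np.array([[a, b], [c, d]])
    if table.min() < 0:
        raise ValueError("counts must be nonnegative")
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        logger.warning("degenerate 2x2 table (zero margin): p = 1")
        return 1.0
    return float(sps.chi2_contingency(table, correction=correction)[1])


def paired_report(
    metrics: dict[str, PairedSeries], zero_policy: str = "drop"
) -> "pd.DataFrame":
    """Statistics report: metric, n, pre/post medians, test, p."""
    import pandas as pd

    rows = []
    for name, series in metrics.items():
        rows.append(
            {
                "metric": name,
                "n": len(series.pre),
                "median_pre": float(np.median(series.pre)),
                "median_post": float(np.median(series.post)),
                "test": "wilcoxon-signed-rank",
                "p": paired_wilcoxon(series, zero_policy=zero_policy),
            }
        )
    return pd.DataFrame(rows, columns=["metric", "n", "median_pre", "median_post", "test", "p"])
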