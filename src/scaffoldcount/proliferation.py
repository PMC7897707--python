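"""Proliferation time courses: fold changes and pairwise rank tests.

Cell densities measured on successive culture days come from different
scaffold fragments, so day-vs-day comparisons default to the two-sample
Wilcoxon rank-sum (Mann-Whitney) test on per-field densities; a signed-rank
variant is available for genuinely paired designs. For small samples
(combined n <= 12) the null distribution of the rank sum is enumerated
exactly, midranks included, so ties are handled without approximation;
larger samples use the tie-corrected normal approximation with continuity
correction. Two-sided p-values are twice the smaller exact tail, capped at
one. No multiple-testing correction is applied by default; Holm's step-down
adjustment is available.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Largest combined sample size for which the rank-sum null distribution is
#: enumerated exactly (C(12,6) = 924 assignments; instantaneous).
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class TimeSeriesStudy:
    """Per-field densities at successive culture days.

    ``timepoints`` maps strictly increasing day numbers (day 0 = scaffold
    formation) to lists of per-field densities (cells/mm^3);
    ``initial_density`` is the seeding concentration, if known.
    """

    timepoints: tuple[tuple[int, tuple[float, ...]], ...]
    initial_density: float | None = None

    def __post_init__(self) -> None:
        days = [d for d, _ in self.timepoints]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(d < 0 for d in days):
            raise ValueError("days must be >= 0")
        if any(len(v) == 0 for _, v in self.timepoints):
            raise ValueError("every timepoint needs at least one field density")

    @staticmethod
    def from_dict(
        data: dict[int, Sequence[float]], initial_density: float | None = None
    ) -> "TimeSeriesStudy":
        tps = tuple(
            (int(day), tuple(float(v) for v in data[day])) for day in sorted(data)
        )
        return TimeSeriesStudy(timepoints=tps, initial_density=initial_density)

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.timepoints]

    def densities_at(self, day: int) -> tuple[float, ...]:
        for d, values in self.timepoints:
            if d == day:
                return values
        raise KeyError(f"no timepoint for day {day}; have {self.days}")

    def mean_at(self, day: int) -> float:
        return float(np.mean(self.densities_at(day)))


@dataclass(frozen=True)
class PairwiseComparison:
    day_a: int
    day_b: int
    statistic: float  # rank sum of sample a
    p_value: float
    significant: bool
    alpha: float = 0.05
    method: str = "exact"


def fold_change(study: TimeSeriesStudy, day: int, *, baseline_day: int | None = None) -> float:
    """Mean density at ``day`` divided by the baseline density.

    Baseline is the seeding concentration unless ``baseline_day`` names an
    earlier measured day to use instead.
    """
    if baseline_day is not None:
        baseline = study.mean_at(baseline_day)
    elif study.initial_density is not None:
        baseline = study.initial_density
    else:
        raise ValueError("no baseline: set initial_density or pass baseline_day")
    if baseline == 0:
        raise ValueError("baseline density is zero; fold change undefined")
    return study.mean_at(day) / baseline


def _rank_sum_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration (midranks for ties).

    Returns (W, p) where W is the rank sum of sample ``a``. The two-sided
    p-value is twice the smaller tail probability P(W' <= W) / P(W' >= W)
    under random assignment of the combined ranks, capped at 1.
    """
    n1, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))  # midranks
    w_obs = float(ranks[:n1].sum())
    lo = hi = total = 0
    eps = 1e-9
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + eps:
            lo += 1
        if w >= w_obs - eps:
            hi += 1
    p = min(1.0, 2.0 * min(lo, hi) / total)
    return w_obs, p


def _rank_sum_approx_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n1 = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_obs = float(ranks[:n1].sum())
    # Mann-Whitney U and the rank sum differ by a constant; reuse scipy's
    # asymptotic machinery rather than re-deriving it.
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return w_obs, float(res.pvalue)


def pairwise_wilcoxon(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    *,
    day_a: int = 0,
    day_b: int = 0,
    method: str = "auto",
    paired: bool = False,
) -> PairwiseComparison:
    """Two-sided rank test between two samples of per-field densities.

    ``method`` is "auto" (exact enumeration when combined n <=
    ``EXACT_ENUMERATION_MAX_N``, else normal approximation), "exact" or
    "approx". With ``paired=True`` the signed-rank test is used instead and
    the samples must be equal-length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")

    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length samples")
        if np.all(a == b):
            logger.info("all paired differences zero; p = 1")
            stat, p, used = 0.0, 1.0, "signed-rank"
        else:
            res = stats.wilcoxon(a, b, alternative="two-sided")
            stat, p, used = float(res.statistic), float(res.pvalue), "signed-rank"
    elif np.all(np.concatenate([a, b]) == a[0]):
        logger.info("all values tied across both samples; p = 1")
        stat = float(stats.rankdata(np.concatenate([a, b]))[: len(a)].sum())
        p, used = 1.0, "degenerate"
    else:
        if method == "auto":
            method = "exact" if len(a) + len(b) <= EXACT_ENUMERATION_MAX_N else "approx"
        if method == "exact":
            stat, p = _rank_sum_exact_p(a, b)
        elif method == "approx":
            stat, p = _rank_sum_approx_p(a, b)
        else:
            raise ValueError(f"unknown method {method!r}")
        used = method
    return PairwiseComparison(
        day_a=day_a, day_b=day_b, statistic=stat, p_value=p,
        significant=bool(p < alpha), alpha=alpha, method=used,
    )


def all_pairwise(
    study: TimeSeriesStudy,
    alpha: float = 0.05,
    *,
    method: str = "auto",
    holm: bool = False,
) -> list[PairwiseComparison]:
    """Rank tests for every ordered pair of study days.

    With ``holm=True`` p-values are Holm step-down adjusted before the
    significance call (off by default: raw pairwise p-values are reported).
    """
    pairs = list(itertools.combinations(study.days, 2))
    comps = [
        pairwise_wilcoxon(
            study.densities_at(da), study.densities_at(db),
            alpha=alpha, day_a=da, day_b=db, method=method,
        )
        for da, db in pairs
    ]
    if holm and comps:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests([c.p_value for c in comps],
                                            alpha=alpha, method="holm")
        comps = [
            PairwiseComparison(
                day_a=c.day_a, day_b=c.day_b, statistic=c.statistic,
                p_value=float(p), significant=bool(r), alpha=alpha,
                method=c.method + "+holm",
            )
            for c, p, r in zip(comps, p_adj, reject)
        ]
    return comps
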