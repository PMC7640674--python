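"""Comparison of VAS-based and BWS-based importance measurement.

The survey asked each respondent to rate every outcome on a visual
analog scale (normalised to [0, 1]) before the best-worst task.  Two
questions are of interest: do the two instruments rank the outcomes the
same way (rank agreement of per-item medians), and which one separates
the outcomes more sharply (dispersion overlap of the per-item score
distributions)?  The overlap statistic operationalises the qualitative
box-plot comparison: for every pair of items, the length of the
intersection of their interquartile ranges over the length of the
union, averaged over all pairs — lower means better-separated items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankVector",
    "normalize_vas",
    "rank_by_median",
    "rank_agreement",
    "dispersion_overlap",
    "scores_by_item",
]


@dataclass(frozen=True)
class RankVector:
    """Item ranks (1 = most worrisome), midpoint ties allowed."""

    ranks: dict[str, float]
    method: str = ""

    def __post_init__(self) -> None:
        expected = sorted(range(1, len(self.ranks) + 1))
        if sorted(self.ranks.values()) != expected and not np.isclose(
            sum(self.ranks.values()), sum(expected)
        ):
            raise ValueError("ranks must be a (possibly midpoint-tied) permutation of 1..v")

    def aligned(self, items: Sequence[str]) -> np.ndarray:
        return np.array([self.ranks[i] for i in items])


def normalize_vas(raw, lo: float = 0.0, hi: float = 100.0):
    """Rescale an instrument reading to [0, 1] via (raw - lo)/(hi - lo).

    Out-of-range values are rejected, never silently clamped.
    """
    if hi <= lo:
        raise ValueError(f"instrument range [{lo}, {hi}] is empty")
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"raw VAS value outside instrument range [{lo}, {hi}]")
    out = (arr - lo) / (hi - lo)
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def scores_by_item(frame: pd.DataFrame, value_col: str = "score") -> dict[str, np.ndarray]:
    """Split a long (respondent_id, item_id, score) frame into per-item
    score arrays."""
    return {
        str(item): grp[value_col].to_numpy(dtype=float)
        for item, grp in frame.groupby("item_id", sort=False)
    }


def rank_by_median(
    scores: Mapping[str, Sequence[float]], method: str = ""
) -> RankVector:
    """Rank items by the median score, 1 = highest median.

    Tied medians share the midpoint (average) rank; the median of an
    even-sized sample is the midpoint of the two central values.
    """
    items = list(scores)
    if not items:
        raise ValueError("no items to rank")
    medians = []
    for item in items:
        vals = np.asarray(scores[item], dtype=float)
        if vals.size == 0:
            raise ValueError(f"item {item!r} has no scores")
        medians.append(np.median(vals))
    ranks = stats.rankdata([-m for m in medians], method="average")
    return RankVector(ranks=dict(zip(items, ranks)), method=method)


def rank_agreement(a: RankVector, b: RankVector) -> tuple[float, float]:
    """Spearman rho and Kendall tau-b between two rankings.

    Spearman is the Pearson correlation of the rank vectors (which
    handles midpoint ties); Kendall is the tau-b concordance statistic.
    """
    if set(a.ranks) != set(b.ranks):
        raise ValueError("rank vectors cover different item sets")
    items = list(a.ranks)
    ra, rb = a.aligned(items), b.aligned(items)
    rho = stats.spearmanr(ra, rb).statistic
    tau = stats.kendalltau(ra, rb, variant="b").statistic
    return float(rho), float(tau)


def _iqr(vals: np.ndarray) -> tuple[float, float]:
    return tuple(np.percentile(vals, [25, 75]))  # type: ignore[return-value]


def dispersion_overlap(scores: Mapping[str, Sequence[float]]) -> float:
    """Mean pairwise IQR-overlap fraction across items.

    For each item pair, overlap = |[Q1,Q3]_i intersect [Q1,Q3]_j| /
    |[Q1,Q3]_i union [Q1,Q3]_j| (interval lengths).  Degenerate
    zero-width IQRs count 1 if the two intervals are the identical
    point, else 0.  Lower values mean the instrument separates items
    more sharply.
    """
    items = list(scores)
    if len(items) < 2:
        raise ValueError("need at least two items")
    iqrs = {}
    for item in items:
        vals = np.asarray(scores[item], dtype=float)
        if vals.size < 4:
            raise ValueError(f"item {item!r} has fewer than 4 scores; IQR unstable")
        iqrs[item] = _iqr(vals)

    overlaps = []
    for x in range(len(items)):
        for y in range(x + 1, len(items)):
            (a1, a2), (b1, b2) = iqrs[items[x]], iqrs[items[y]]
            inter = min(a2, b2) - max(a1, b1)
            union = max(a2, b2) - min(a1, b1)
            if union <= 0.0:  # both degenerate
                overlaps.append(1.0 if a1 == b1 else 0.0)
            else:
                overlaps.append(max(inter, 0.0) / union)
    return float(np.mean(overlaps))
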