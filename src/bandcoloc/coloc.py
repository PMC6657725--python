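"""Band co-occurrence statistics and the permutation test across conditions.

Two bands from different channels co-occur when their positions agree within
a spatial tolerance (default 0.6 μm, the same scale used to separate bands
within a channel). Matching is one-to-one so no band is counted twice. A
segment's colocalization is the co-occurring bands as a percentage of all
bands recorded: 100 × 2·(matched pairs) / (n_a + n_b). Segments are averaged
per larva, larvae are the units of the condition, and conditions are
compared by permuting larva labels and recomputing the difference of means.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import BandSet

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedPair",
    "SegmentColoc",
    "ConditionData",
    "PermutationResult",
    "match_bands",
    "coloc_percent",
    "summarize_larvae",
    "permutation_test",
]


@dataclass(frozen=True)
class MatchedPair:
    index_a: int
    index_b: int
    position_a: float
    position_b: float
    distance: float


def match_bands(
    bands_a: BandSet, bands_b: BandSet, tolerance_um: float = 0.6
) -> list[MatchedPair]:
    """One-to-one matching of bands across channels, nearest pairs first.

    All candidate pairs within ``tolerance_um`` are ranked by ascending
    distance (ties by position) and accepted greedily, skipping pairs whose
    band on either side is already matched. No band appears in two pairs.
    """
    if tolerance_um <= 0:
        raise ValueError("tolerance_um must be positive")
    pairs = [
        (abs(pa - pb), pa, pb, i, j)
        for i, pa in enumerate(bands_a.positions)
        for j, pb in enumerate(bands_b.positions)
        if abs(pa - pb) <= tolerance_um
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for d, pa, pb, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append(MatchedPair(i, j, pa, pb, d))
    return matched


@dataclass(frozen=True)
class SegmentColoc:
    """Colocalization summary of one segment.

    ``percent_coloc`` is NaN (and ``defined`` False) when neither channel
    has any band — a 0/0 segment carries no information and is excluded
    from the larva mean.
    """

    segment_id: str
    larva_id: str
    condition: str
    n_bands_a: int
    n_bands_b: int
    n_matched_pairs: int
    percent_coloc: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.percent_coloc)


def coloc_percent(
    bands_a: BandSet, bands_b: BandSet, tolerance_um: float = 0.6
) -> SegmentColoc:
    """Co-occurring bands as a percentage of the total bands recorded.

    Matched bands count on both sides of the denominator, so identical band
    sets give exactly 100%.
    """
    matched = match_bands(bands_a, bands_b, tolerance_um=tolerance_um)
    n_a, n_b, n_m = len(bands_a), len(bands_b), len(matched)
    total = n_a + n_b
    percent = 100.0 * 2.0 * n_m / total if total > 0 else float("nan")
    return SegmentColoc(
        segment_id=bands_a.segment_id,
        larva_id=bands_a.larva_id,
        condition=bands_a.condition or bands_b.condition,
        n_bands_a=n_a,
        n_bands_b=n_b,
        n_matched_pairs=n_m,
        percent_coloc=percent,
    )


@dataclass
class ConditionData:
    """Per-larva mean colocalization percentages for one condition."""

    condition: str
    larva_means: pd.Series  # index = larva_id, values in [0, 100]

    @property
    def values(self) -> np.ndarray:
        return self.larva_means.to_numpy(dtype=float)

    @property
    def n_larvae(self) -> int:
        return int(self.larva_means.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def summarize_larvae(
    segments: list[SegmentColoc], condition: str | None = None
) -> ConditionData:
    """Average segment percentages within each larva (defined segments only).

    A larva whose segments are all undefined is dropped with a warning.
    """
    if condition is None:
        conditions = {s.condition for s in segments}
        if len(conditions) != 1:
            raise ValueError(f"segments span multiple conditions: {sorted(conditions)}")
        condition = conditions.pop()
    per_larva: dict[str, list[float]] = {}
    for s in segments:
        per_larva.setdefault(s.larva_id, [])
        if s.defined:
            per_larva[s.larva_id].append(s.percent_coloc)
    means = {}
    for larva, vals in per_larva.items():
        if not vals:
            warnings.warn(f"larva {larva!r} has no defined segments; excluded")
            logger.warning("larva %s has no defined segments; excluded", larva)
            continue
        means[larva] = float(np.mean(vals))
    return ConditionData(
        condition=condition, larva_means=pd.Series(means, dtype=float).sort_index()
    )


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test on the difference of condition means."""

    observed_diff: float
    n_permutations: int
    n_as_or_more_extreme: int
    p_value: float
    mode: str                      # "exhaustive" | "sampled"
    alternative: str
    seed: int | None = None
    condition_a: str = ""
    condition_b: str = ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        return (
            f"diff(mean {self.condition_a or 'A'} - mean {self.condition_b or 'B'}) "
            f"= {self.observed_diff:.3f}, p = {self.p_value:.5g} "
            f"({self.mode}, {self.n_permutations} arrangements)"
        )


def _as_values(x) -> tuple[np.ndarray, str]:
    if isinstance(x, ConditionData):
        return x.values, x.condition
    return np.asarray(x, dtype=float), ""


def _tail_count(diffs: np.ndarray, observed: float, alternative: str) -> int:
    # tolerance so permutations that tie the observed statistic up to float
    # round-off count as "as extreme"
    tol = 1e-9 * max(1.0, abs(observed))
    if alternative == "two-sided":
        return int(np.count_nonzero(np.abs(diffs) >= abs(observed) - tol))
    if alternative == "greater":
        return int(np.count_nonzero(diffs >= observed - tol))
    if alternative == "less":
        return int(np.count_nonzero(diffs <= observed + tol))
    raise ValueError(f"unknown alternative {alternative!r}")


def permutation_test(
    a,
    b,
    n_permutations: int = 100_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Permutation test on the difference of group means, mean(a) - mean(b).

    Group labels are permuted over the pooled per-larva values, preserving
    the group sizes. When the number of distinct label assignments
    C(n_a + n_b, n_a) does not exceed ``n_permutations`` the null is
    enumerated exhaustively and the p-value is the exact tail fraction;
    otherwise ``n_permutations`` random reassignments are drawn and the
    add-one-corrected estimate (count + 1) / (n + 1) is reported, so a
    sampled p is never zero.

    Parameters
    ----------
    a, b : ConditionData or array-like
        Per-larva percentages of the two conditions (>= 2 values each).
    """
    values_a, label_a = _as_values(a)
    values_b, label_b = _as_values(b)
    if values_a.size < 2 or values_b.size < 2:
        raise ValueError("each condition needs at least 2 larvae")
    n_a, n_b = values_a.size, values_b.size
    n = n_a + n_b
    pooled = np.concatenate([values_a, values_b])
    observed = float(values_a.mean() - values_b.mean())
    meta = dict(alternative=alternative, seed=seed,
                condition_a=label_a, condition_b=label_b)

    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; permutation test degenerate, p = 1")
        logger.warning("degenerate permutation test: all pooled values identical")
        return PermutationResult(
            observed_diff=observed, n_permutations=0,
            n_as_or_more_extreme=0, p_value=1.0, mode="degenerate", **meta,
        )

    total = math.comb(n, n_a)
    if total <= n_permutations:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), n_a)),
            dtype=np.intp,
        ).reshape(total, n_a)
        sums_a = pooled[idx].sum(axis=1)
        # mean_a - mean_b from the group-a sum and the fixed pooled total
        diffs = sums_a / n_a - (pooled.sum() - sums_a) / n_b
        count = _tail_count(diffs, observed, alternative)
        return PermutationResult(
            observed_diff=observed, n_permutations=total,
            n_as_or_more_extreme=count, p_value=count / total,
            mode="exhaustive", **meta,
        )

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 20_000
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perm = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        shuffled = pooled[perm]
        diffs = shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
        count += _tail_count(diffs, observed, alternative)
        done += m
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(
        observed_diff=observed, n_permutations=n_permutations,
        n_as_or_more_extreme=count, p_value=p, mode="sampled", **meta,
    )


def segments_to_frame(segments: list[SegmentColoc]) -> pd.DataFrame:
    """Per-segment colocalization records as a tidy table."""
    return pd.DataFrame([vars(s) | {"defined": s.defined} for s in segments])
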