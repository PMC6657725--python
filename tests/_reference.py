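"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (nested loops, exhaustive enumeration) and written
without reuse of the package's code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_detect(positions, y, min_distance_um=0.6, threshold_frac=0.20):
    """Reference band detector: enumerate candidates, threshold, greedy prune.

    A sample index i is a candidate iff the maximal run of equal values
    containing i is interior, strictly above both flanking values, and i is
    the (left-rounded) midpoint of that run.
    """
    positions = np.asarray(positions, float)
    y = np.asarray(y, float)
    n = y.size
    if y.max() <= 0:
        return []
    threshold = threshold_frac * y.max()
    candidates = []
    for i in range(n):
        l = i
        while l - 1 >= 0 and y[l - 1] == y[i]:
            l -= 1
        r = i
        while r + 1 < n and y[r + 1] == y[i]:
            r += 1
        if l == 0 or r == n - 1:
            continue
        if y[l - 1] < y[i] and y[r + 1] < y[i] and i == (l + r) // 2:
            if y[i] >= threshold:
                candidates.append(i)
    candidates.sort(key=lambda i: (-y[i], positions[i]))
    accepted = []
    for i in candidates:
        if all(abs(positions[i] - positions[j]) >= min_distance_um for j in accepted):
            accepted.append(i)
    return sorted(accepted, key=lambda i: positions[i])


def brute_overlap_counts(a, b, min_overlap_bp=1):
    """O(n^2) reciprocal overlap counts over (chrom, start, end) triples."""

    def hits(query, subject):
        count = 0
        for qc, qs, qe in query:
            for sc, ss, se in subject:
                if qc == sc and min(qe, se) - max(qs, ss) >= min_overlap_bp:
                    count += 1
                    break
        return count

    return hits(a, b), hits(b, a)


def brute_two_sided_p(a, b):
    """Exhaustive two-sided permutation p for the difference of means."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(np.mean(grp_a) - np.mean(grp_b)) >= observed - 1e-12:
            count += 1
    return count / total, count, total


def brute_match_count(pos_a, pos_b, tolerance):
    """Greedy nearest-pair one-to-one matching, counted exhaustively."""
    pairs = sorted(
        (abs(pa - pb), pa, pb, i, j)
        for i, pa in enumerate(pos_a)
        for j, pb in enumerate(pos_b)
        if abs(pa - pb) <= tolerance
    )
    used_a, used_b = set(), set()
    matches = []
    for _, pa, pb, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matches.append((pa, pb))
    return matches


def random_banded_trace(rng, n_samples, quantize=True):
    """A random 1-D trace with realistic structure: smooth bumps, noise and
    (optionally) quantized values so plateaus and height ties occur."""
    step = rng.uniform(0.02, 0.2)
    positions = np.arange(n_samples) * step
    y = rng.uniform(0, 5) * np.ones(n_samples)
    for _ in range(rng.integers(0, 8)):
        c = rng.uniform(positions[0], positions[-1])
        sigma = rng.uniform(step, 10 * step)
        y += rng.uniform(5, 100) * np.exp(-0.5 * ((positions - c) / sigma) ** 2)
    y += rng.normal(0, rng.uniform(0, 3), n_samples)
    y = np.maximum(y, 0)
    if quantize:
        y = np.round(y, 1)
    return positions, y
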