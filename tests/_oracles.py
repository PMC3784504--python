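"""Independent reference implementations used only to check chiptile.

These are deliberately naive (quadratic scans, explicit enumeration) and
share no code with the package: they are the brute-force oracles the tests
compare against.
"""

from __future__ import annotations

import numpy as np


def quantile_normalize_oracle(matrix: np.ndarray) -> np.ndarray:
    """Sort/average/rank-map quantile normalization, one cell at a time.

    For each cell, find the positions its value occupies in the column's
    sorted order (the whole tied span) and assign the mean of the reference
    distribution over those positions.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(m):
        col_sorted = np.sort(matrix[:, j])
        for i in range(n):
            positions = np.flatnonzero(col_sorted == matrix[i, j])
            out[i, j] = reference[positions].mean()
    return out


def overlap_count_oracle(a_intervals, b_intervals) -> int:
    """All-pairs scan: loci of A intersecting any locus of B by >= 1 bp."""
    count = 0
    for ca, sa, ea in a_intervals:
        if any(ca == cb and sa < eb and ea > sb for cb, sb, eb in b_intervals):
            count += 1
    return count


def pearson_oracle(x, y) -> float:
    """Closed-form Pearson r written out explicitly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx * dx).sum() * (dy * dy).sum()))


def chi2_oracle(table) -> tuple[float, int]:
    """Pearson chi-square from the definition: sum (obs - exp)^2 / exp."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    statistic = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return statistic, df


def run_count_oracle(scores, threshold, min_probes, max_gap) -> int:
    """Count qualifying probe runs on one chromosome by explicit walking."""
    groups: list[list[int]] = []
    current: list[int] = []
    gap = 0
    for i, s in enumerate(scores):
        if s >= threshold:
            if current and gap > max_gap:
                groups.append(current)
                current = []
            current.append(i)
            gap = 0
        elif current:
            gap += 1
    if current:
        groups.append(current)
    return sum(1 for g in groups if len(g) >= min_probes)


def single_interval_overlap_enumeration(
    chrom_len: int, len_a: int, len_b: int
) -> float:
    """Exact P(overlap) for two length-preserving uniform placements.

    Enumerates every (start_a, start_b) pair on one chromosome; the A-over-B
    locus overlap count for single-interval sets is the overlap indicator.
    """
    n_a = chrom_len - len_a + 1
    n_b = chrom_len - len_b + 1
    hits = 0
    for sa in range(n_a):
        for sb in range(n_b):
            if sa < sb + len_b and sb < sa + len_a:
                hits += 1
    return hits / (n_a * n_b)


def single_interval_overlap_given_b(
    chrom_len: int, len_a: int, b_start: int, len_b: int
) -> float:
    """Exact P(overlap) over all A placements, B fixed."""
    n_a = chrom_len - len_a + 1
    hits = sum(
        1
        for sa in range(n_a)
        if sa < b_start + len_b and b_start < sa + len_a
    )
    return hits / n_a
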