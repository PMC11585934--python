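"""Independent reference implementations used as oracles.

Everything here is written for clarity and brute force, not speed, and is
kept independent of the code paths it checks: the Poisson tail is a direct
series summation, BH is the textbook step-up procedure, the window scan
materializes every window and every test explicitly, and set matching is an
exhaustive assignment search.
"""

from __future__ import annotations

import itertools
import math


def poisson_tail_direct(x: int, lam: float, rel_stop: float = 1e-18) -> float:
    """P(X >= x) for X ~ Poisson(lam) by direct summation of the pmf series."""
    if x == 0:
        return 1.0
    if lam == 0:
        return 0.0
    # first term at k = x, in log space to survive large lam
    log_term = x * math.log(lam) - lam - math.lgamma(x + 1)
    term = math.exp(log_term)
    total = 0.0
    k = x
    while True:
        total += term
        k += 1
        term *= lam / k
        if term < rel_stop * max(total, 1e-300) and k > lam:
            break
    return min(total, 1.0)


def bh_step_up(p_values):
    """Textbook Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, compute p_(i) * m / i, then enforce monotonicity by a
    cumulative minimum from the largest rank, and cap at 1.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(p_values[i] * m / rank, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def naive_scan(counts: dict[int, int], genome_length: int, cutoff: float,
               window_size: int, step: int, alpha: float):
    """Exhaustive-window reference for the sliding-window Poisson scan.

    Returns {position: (coverage, lambda, p_raw, p_adj)} for every position
    whose best adjusted p is below alpha, using poisson_tail_direct and
    bh_step_up only.
    """
    tests = []  # (position, coverage, lambda, p_raw)
    start = 1
    while start <= genome_length:
        end = min(start + window_size - 1, genome_length)
        width = end - start + 1
        window_sum = sum(counts.get(pos, 0) for pos in range(start, end + 1))
        lam = window_sum / width
        for pos in range(start, end + 1):
            cov = counts.get(pos, 0)
            if cov >= cutoff and cov >= 1:
                tests.append((pos, cov, lam, poisson_tail_direct(cov, lam)))
        start += step
    if not tests:
        return {}
    adjusted = bh_step_up([t[3] for t in tests])
    best: dict[int, tuple] = {}
    for (pos, cov, lam, p_raw), p_adj in zip(tests, adjusted):
        if pos not in best or (p_adj, p_raw) < (best[pos][3], best[pos][2]):
            best[pos] = (cov, lam, p_raw, p_adj)
    return {pos: v for pos, v in best.items() if v[3] < alpha}


def best_matching_size(a_positions, b_positions, tolerance):
    """Size of a maximum one-to-one matching within tolerance (exhaustive).

    Only feasible for tiny instances; used to certify the greedy matcher.
    """
    best = 0
    b_indices = range(len(b_positions))
    for k in range(min(len(a_positions), len(b_positions)), 0, -1):
        for a_subset in itertools.combinations(range(len(a_positions)), k):
            for b_perm in itertools.permutations(b_indices, k):
                if all(
                    abs(a_positions[i] - b_positions[j]) <= tolerance
                    for i, j in zip(a_subset, b_perm)
                ):
                    return k
    return best


def consensus_brute_force(replicate_sets, tolerance):
    """All-pairs check of the replicate-intersection rule."""
    first = replicate_sets[0]
    kept = []
    for peak in first:
        ok = True
        for rep in replicate_sets[1:]:
            if not any(
                q.strand == peak.strand
                and q.chrom == peak.chrom
                and abs(q.peak_position - peak.peak_position) <= tolerance
                for q in rep
            ):
                ok = False
                break
        if ok:
            kept.append(peak)
    return kept
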