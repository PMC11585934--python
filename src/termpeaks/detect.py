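"""Significance scan: adaptive coverage cutoff + sliding-window Poisson test.

The detector asks, locally, whether the number of read 3' ends at a position
is surprising given its neighbourhood.  Windows of ``slidingWindowSize``
positions advance by ``slidingWindowMovementDistance``; within a window the
background rate lambda is the mean 3'-end coverage over *all* window
positions (zeros included), and each qualifying position is tested with an
upper-tail Poisson test P(X >= x | lambda).  Because windows overlap, a
position can be tested against up to ceil(size/step) local backgrounds; it
is reported when any of its tests survives Benjamini-Hochberg correction
(applied once across all tests on the strand).

Positions qualify for testing only if their coverage reaches a global
minimum-coverage cutoff derived from the data itself: the mean coverage of
the highest-coverage positions that jointly account for a ``threshAdjust``
fraction of the file's total 3'-end signal, after discarding the top
``highOutlierTrim`` fraction of those positions from the mean (they remain
eligible for testing).  This adapts the noise floor to sequencing depth
instead of imposing a fixed read-count threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import StrandCoverage

logger = logging.getLogger(__name__)


@dataclass
class Parameters:
    """User-tunable analysis parameters.

    Field names deliberately keep the camelCase spelling established for
    this analysis so that CLI flags and config keys map one-to-one.

    readScoreMinimum: minimum read quality score (BED column 5) a read must
        reach to be analyzed.
    threshAdjust: fraction of the file's total 3'-end coverage whose
        top-coverage positions define the adaptive minimum-coverage cutoff.
        Lower = stricter (recommended 0.50-0.60 for very deep data), higher
        = laxer (0.80-0.95 for shallow data).
    highOutlierTrim: fraction of those top-coverage positions dropped from
        the cutoff mean as outliers (e.g. residual rRNA); raise to
        0.025-0.05 when a few positions dominate the library.
    slidingWindowSize / slidingWindowMovementDistance: window extent and
        step, in nt.  The step must not exceed the size (windows must tile
        the genome without gaps).
    user_pValue: BH-adjusted significance level alpha.  The test family is
        large (one test per qualifying position per overlapping window), so
        the default is conservative.
    adjacentPeakDistance: max spacing (nt) between significant positions
        merged into one peak (condensing step two).
    peakCondensingDistance: max edge-to-edge gap (nt) between peaks merged
        in condensing step three.
    """

    readScoreMinimum: int = 30
    threshAdjust: float = 0.75
    highOutlierTrim: float = 0.01
    slidingWindowSize: int = 51
    slidingWindowMovementDistance: int = 25
    user_pValue: float = 0.005
    adjacentPeakDistance: int = 2
    peakCondensingDistance: int = 20

    def __post_init__(self) -> None:
        if self.readScoreMinimum < 0:
            raise ValueError("readScoreMinimum must be >= 0")
        if not 0 < self.threshAdjust <= 1:
            raise ValueError("threshAdjust must be in (0, 1]")
        if not 0 <= self.highOutlierTrim < 1:
            raise ValueError("highOutlierTrim must be in [0, 1)")
        if self.slidingWindowSize < 1 or self.slidingWindowSize % 2 == 0:
            raise ValueError("slidingWindowSize must be an odd positive integer")
        if self.slidingWindowMovementDistance < 1:
            raise ValueError("slidingWindowMovementDistance must be positive")
        if self.slidingWindowMovementDistance > self.slidingWindowSize:
            raise ValueError(
                "slidingWindowMovementDistance must be <= slidingWindowSize "
                "(windows must tile without gaps)"
            )
        if not 0 < self.user_pValue < 1:
            raise ValueError("user_pValue must be in (0, 1)")
        if self.adjacentPeakDistance < 0 or self.peakCondensingDistance < 0:
            raise ValueError("condensing distances must be >= 0")


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the adaptive minimum-coverage cutoff computation."""

    cutoff: float
    n_selected: int
    n_trimmed: int
    total_coverage: int


@dataclass(frozen=True)
class SignificantPosition:
    """One genomic position whose 3'-end coverage survived BH correction.

    ``window_lambda`` and ``p_raw`` belong to the test that achieved the
    minimum adjusted p-value for this position.
    """

    position: int
    strand: str
    coverage: int
    window_lambda: float
    p_raw: float
    p_adj: float


def compute_global_cutoff(
    coverages: Iterable[StrandCoverage], params: Parameters
) -> CutoffResult:
    """Adaptive minimum-coverage cutoff from pooled nonzero coverage values.

    Pools the nonzero 3'-end counts of all supplied coverage maps (both
    strands, all chromosomes of one input file), sorts them descending,
    selects the smallest prefix whose cumulative sum reaches
    ``threshAdjust`` x total, drops the top ``floor(highOutlierTrim x
    prefix size)`` values, and returns the mean of the remainder.
    """
    values = np.concatenate(
        [np.fromiter(c.counts.values(), dtype=np.int64) for c in coverages]
        or [np.empty(0, dtype=np.int64)]
    )
    if values.size == 0:
        raise ValueError("no signal: all positions have zero coverage")
    values = np.sort(values)[::-1]
    total = int(values.sum())
    cumulative = np.cumsum(values)
    prefix_size = int(np.searchsorted(cumulative, params.threshAdjust * total) + 1)
    n_trimmed = math.floor(params.highOutlierTrim * prefix_size)
    kept = values[n_trimmed:prefix_size]
    if kept.size == 0:
        logger.warning(
            "high-outlier trim emptied the selected prefix (%d values); "
            "falling back to the untrimmed prefix mean",
            prefix_size,
        )
        n_trimmed = 0
        kept = values[:prefix_size]
    return CutoffResult(
        cutoff=float(kept.mean()),
        n_selected=int(kept.size),
        n_trimmed=n_trimmed,
        total_coverage=total,
    )


def poisson_upper_tail(x: int, lam: float) -> float:
    """P(X >= x) for X ~ Poisson(lam), via the survival function."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if x == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(x - 1, lam))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (FDR), empty-safe."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def iter_windows(genome_length: int, params: Parameters):
    """Yield (start, end) 1-based inclusive window bounds tiling the genome.

    The last window is truncated at ``genome_length`` and still evaluated
    over its actual width.
    """
    size, step = params.slidingWindowSize, params.slidingWindowMovementDistance
    for start in range(1, genome_length + 1, step):
        yield start, min(start + size - 1, genome_length)


def scan_strand(
    coverage: StrandCoverage,
    cutoff: float,
    params: Parameters,
) -> list[SignificantPosition]:
    """Run the sliding-window Poisson scan on one strand.

    Every (position, window) pair with coverage >= ``cutoff`` is tested
    against that window's mean coverage; BH correction is applied once
    across all tests on the strand, and a position is reported when its
    best adjusted p-value is below ``user_pValue``.
    """
    positions, counts = coverage.positions_and_counts()
    if positions.size == 0:
        return []
    qualifying = counts >= cutoff
    if not qualifying.any():
        return []
    cum = np.concatenate([[0], np.cumsum(counts)])

    test_pos: list[int] = []
    test_cov: list[int] = []
    test_lam: list[float] = []
    for w_start, w_end in iter_windows(coverage.genome_length, params):
        lo = int(np.searchsorted(positions, w_start, side="left"))
        hi = int(np.searchsorted(positions, w_end, side="right"))
        if lo == hi:
            continue
        lam = (cum[hi] - cum[lo]) / (w_end - w_start + 1)
        idx = np.nonzero(qualifying[lo:hi])[0] + lo
        for i in idx:
            test_pos.append(int(positions[i]))
            test_cov.append(int(counts[i]))
            test_lam.append(lam)
    if not test_pos:
        return []

    p_raw = stats.poisson.sf(np.asarray(test_cov) - 1, np.asarray(test_lam))
    p_adj = benjamini_hochberg(p_raw)

    # keep, per position, the test with the smallest adjusted p
    # (ties: smaller raw p, then the earlier window — the iteration order)
    best: dict[int, tuple[float, float, float, int]] = {}
    for pos, cov, lam, pr, pa in zip(test_pos, test_cov, test_lam, p_raw, p_adj):
        entry = (float(pa), float(pr), float(lam), cov)
        if pos not in best or entry[:2] < best[pos][:2]:
            best[pos] = entry
    out = [
        SignificantPosition(
            position=pos,
            strand=coverage.strand,
            coverage=cov,
            window_lambda=lam,
            p_raw=pr,
            p_adj=pa,
        )
        for pos, (pa, pr, lam, cov) in sorted(best.items())
        if pa < params.user_pValue
    ]
    return out
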