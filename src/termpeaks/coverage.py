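"""Quality filtering and strand-separated 3'-end coverage.

Term-seq marks the 3' terminus of each RNA molecule, so a read contributes
a single count at the genomic position of its 3'-most base in transcript
orientation: the rightmost base for a top-strand ("+") read, the leftmost
base for a complement-strand ("-") read.  Coverage maps are sparse — the
vast majority of genomic positions carry zero 3' ends — so counts are kept
as a position->count mapping and absent positions read as zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import MappedRead

logger = logging.getLogger(__name__)


@dataclass
class StrandCoverage:
    """Per-strand counts of read 3' ends, keyed by 1-based position."""

    chrom: str
    strand: str
    counts: dict[int, int] = field(default_factory=dict)
    genome_length: int = 0

    def __post_init__(self) -> None:
        if self.counts:
            lo, hi = min(self.counts), max(self.counts)
            if lo < 1 or hi > self.genome_length:
                raise ValueError(
                    f"positions must lie in [1, {self.genome_length}], got range [{lo}, {hi}]"
                )
            if any(c < 1 for c in self.counts.values()):
                raise ValueError("stored counts must be >= 1")

    def get(self, position: int) -> int:
        return self.counts.get(position, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def positions_and_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted position array and the matching count array."""
        if not self.counts:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        order = np.argsort(pos)
        pos = pos[order]
        cnt = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))[order]
        return pos, cnt


def filter_by_quality(reads: Sequence[MappedRead], readScoreMinimum: int) -> list[MappedRead]:
    """Keep reads with quality score >= ``readScoreMinimum`` (order preserved)."""
    if readScoreMinimum < 0:
        raise ValueError("readScoreMinimum must be >= 0")
    return [r for r in reads if r.score >= readScoreMinimum]


def three_prime_position(read: MappedRead) -> int:
    """1-based genomic position of a read's 3'-most base in transcript orientation."""
    # "+": rightmost base = BED end (half-open) in 1-based terms
    # "-": leftmost base = BED start + 1
    return read.end if read.strand == "+" else read.start + 1


def extract_three_prime_coverage(
    reads: Iterable[MappedRead],
    genome_length: int | None = None,
) -> tuple[StrandCoverage, StrandCoverage]:
    """Tally read 3' ends into (top-strand, complement-strand) coverage maps.

    All reads must map to a single chromosome.  ``genome_length`` is inferred
    as the maximum read end when not given (logged).
    """
    reads = list(reads)
    chroms = {r.chrom for r in reads}
    if len(chroms) > 1:
        raise ValueError(f"reads span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else "NA"
    if genome_length is None:
        genome_length = max((r.end for r in reads), default=0)
        logger.info("genome_length not given; inferred %d from max read end", genome_length)
    tallies = {"+": Counter(), "-": Counter()}
    for r in reads:
        if r.end > genome_length:
            raise ValueError(
                f"read {r.chrom}:{r.start}-{r.end} extends past genome_length {genome_length}"
            )
        tallies[r.strand][three_prime_position(r)] += 1
    return tuple(
        StrandCoverage(chrom, strand, dict(tallies[strand]), genome_length)
        for strand in ("+", "-")
    )


def group_reads_by_chrom(reads: Iterable[MappedRead]) -> dict[str, list[MappedRead]]:
    """Split a read collection by chromosome, preserving order within each."""
    groups: dict[str, list[MappedRead]] = {}
    for r in reads:
        groups.setdefault(r.chrom, []).append(r)
    return groups
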