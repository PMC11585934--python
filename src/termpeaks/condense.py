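"""Peak condensing: significant positions -> peaks -> merged peaks.

A genuine bacterial termination site produces a pileup spread over a few
adjacent positions (imperfect termination, degradation, library noise), so
single significant positions are rarely independent events.  Step two chains
significant positions within ``adjacentPeakDistance`` nt of each other into
one peak spanning their full range; step three merges peaks whose
edge-to-edge gap is at most ``peakCondensingDistance`` nt, since RNAP
pausing geometry puts independent terminators >= 15-20 nt apart.  Both steps
preserve the full positional range of what they merge, and the reported
representative is always the member position of maximum 3'-end coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .detect import SignificantPosition


@dataclass
class Peak:
    """A condensed termination signal (1-based inclusive range)."""

    chrom: str
    strand: str
    start: int
    end: int
    peak_position: int
    peak_coverage: int
    min_adjusted_p: float
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start <= self.peak_position <= self.end:
            raise ValueError(
                f"peak_position {self.peak_position} outside range [{self.start}, {self.end}]"
            )
        if self.peak_coverage < 1:
            raise ValueError("peak_coverage must be a positive integer")


def merge_adjacent_positions(
    positions: Sequence[SignificantPosition],
    adjacentPeakDistance: int,
    chrom: str,
) -> list[Peak]:
    """Chain significant positions within ``adjacentPeakDistance`` nt into peaks.

    Chaining is transitive: consecutive positions p_i, p_{i+1} fall in the
    same peak iff p_{i+1} - p_i <= adjacentPeakDistance.  Each peak records
    the full positional range, the leftmost maximum-coverage member as its
    representative, and the minimum adjusted p over members.
    """
    if not positions:
        return []
    strands = {p.strand for p in positions}
    if len(strands) > 1:
        raise ValueError("positions span both strands; condense per strand")
    ordered = sorted(positions, key=lambda p: p.position)

    peaks: list[Peak] = []
    run: list[SignificantPosition] = [ordered[0]]
    for sp in ordered[1:]:
        if sp.position - run[-1].position <= adjacentPeakDistance:
            run.append(sp)
        else:
            peaks.append(_peak_from_run(run, chrom))
            run = [sp]
    peaks.append(_peak_from_run(run, chrom))
    return peaks


def _peak_from_run(run: list[SignificantPosition], chrom: str) -> Peak:
    best = max(run, key=lambda p: (p.coverage, -p.position))  # leftmost on tie
    return Peak(
        chrom=chrom,
        strand=run[0].strand,
        start=run[0].position,
        end=run[-1].position,
        peak_position=best.position,
        peak_coverage=best.coverage,
        min_adjusted_p=min(p.p_adj for p in run),
    )


def merge_proximal_peaks(peaks: Sequence[Peak], peakCondensingDistance: int) -> list[Peak]:
    """Merge peaks whose edge-to-edge gap is <= ``peakCondensingDistance`` nt.

    Input peaks must be non-overlapping and on one (chrom, strand).  Merging
    chains transitively; the merged representative is the member
    representative with the highest coverage (leftmost on ties) and the
    merged p is the minimum over members.  Output peaks are pairwise
    separated by more than ``peakCondensingDistance`` nt.
    """
    if not peaks:
        return []
    keys = {(p.chrom, p.strand) for p in peaks}
    if len(keys) > 1:
        raise ValueError("peaks span multiple (chrom, strand) groups; condense per group")
    ordered = sorted(peaks, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"overlapping input peaks [{a.start},{a.end}] and [{b.start},{b.end}]"
            )

    merged: list[list[Peak]] = [[ordered[0]]]
    for p in ordered[1:]:
        if p.start - merged[-1][-1].end <= peakCondensingDistance:
            merged[-1].append(p)
        else:
            merged.append([p])

    out: list[Peak] = []
    for group in merged:
        best = max(group, key=lambda p: (p.peak_coverage, -p.peak_position))
        out.append(
            Peak(
                chrom=group[0].chrom,
                strand=group[0].strand,
                start=group[0].start,
                end=group[-1].end,
                peak_position=best.peak_position,
                peak_coverage=best.peak_coverage,
                min_adjusted_p=min(p.min_adjusted_p for p in group),
            )
        )
    return out
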