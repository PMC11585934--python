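"""Genomic-context classification of peaks and cross-result comparison.

A peak's representative position is placed relative to same-strand annotated
genes into one of five categories: 5'-UTR (<= ``utr5_window`` nt upstream of
a start codon, strand-aware), 3'-UTR (<= ``utr3_window`` nt downstream of a
stop codon), coding (inside a gene body), 3'-UTR & coding (downstream of one
gene's stop while inside a different gene), or intergenic.  Where a position
satisfies both a 5'-UTR and a 3'-UTR window, the 5'-UTR label wins.

Cross-method comparison matches two peak sets one-to-one when representative
positions are within a small tolerance (5 bp by default); replicate
consensus keeps a peak only when every replicate contains a same-strand
peak within that tolerance.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Optional, Sequence

from .condense import Peak
from .io import GeneRecord

logger = logging.getLogger(__name__)

UTR3_WINDOW_DEFAULT = 150
UTR5_WINDOW_DEFAULT = 450
MATCH_TOLERANCE_DEFAULT = 5


class PeakCategory(str, Enum):
    THREE_PRIME_UTR = "3'-UTR"
    FIVE_PRIME_UTR = "5'-UTR"
    CODING = "coding"
    THREE_PRIME_UTR_AND_CODING = "3'-UTR & coding"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


def _in_utr5(pos: int, gene: GeneRecord, window: int) -> bool:
    if gene.strand == "+":
        return gene.start - window <= pos < gene.start
    return gene.end < pos <= gene.end + window


def _in_utr3(pos: int, gene: GeneRecord, window: int) -> bool:
    if gene.strand == "+":
        return gene.end < pos <= gene.end + window
    return gene.start - window <= pos < gene.start


def classify_peak(
    peak: Peak,
    genes: Sequence[GeneRecord],
    utr3_window: int = UTR3_WINDOW_DEFAULT,
    utr5_window: int = UTR5_WINDOW_DEFAULT,
) -> PeakCategory:
    """Assign one of the five genomic-context categories to a peak.

    Classification uses the representative position and considers only
    genes on the peak's chromosome and strand.
    """
    pos = peak.peak_position
    relevant = [g for g in genes if g.chrom == peak.chrom and g.strand == peak.strand]
    if any(_in_utr5(pos, g, utr5_window) for g in relevant):
        return PeakCategory.FIVE_PRIME_UTR
    utr3_genes = [g for g in relevant if _in_utr3(pos, g, utr3_window)]
    body_genes = [g for g in relevant if g.start <= pos <= g.end]
    if utr3_genes and any(b.gene_id not in {g.gene_id for g in utr3_genes} for b in body_genes):
        return PeakCategory.THREE_PRIME_UTR_AND_CODING
    if utr3_genes:
        return PeakCategory.THREE_PRIME_UTR
    if body_genes:
        return PeakCategory.CODING
    return PeakCategory.INTERGENIC


def classify_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneRecord],
    utr3_window: int = UTR3_WINDOW_DEFAULT,
    utr5_window: int = UTR5_WINDOW_DEFAULT,
) -> dict[str, int]:
    """Classify peaks in place; return counts per category label."""
    if not genes:
        logger.warning("empty gene annotation: all peaks classified as intergenic")
    counts = {c.value: 0 for c in PeakCategory}
    for p in peaks:
        cat = classify_peak(p, genes, utr3_window, utr5_window)
        p.category = cat.value
        counts[cat.value] += 1
    return counts


def _as_pos_strand(item) -> tuple[int, Optional[str]]:
    if isinstance(item, Peak):
        return item.peak_position, item.strand
    if isinstance(item, tuple):
        pos, strand = item
        return int(pos), strand
    return int(item), None


def match_peak_sets(
    set_a: Sequence,
    set_b: Sequence,
    tolerance: int = MATCH_TOLERANCE_DEFAULT,
):
    """Greedy nearest-first one-to-one matching of two peak sets.

    Items may be :class:`Peak` objects, ``(position, strand)`` tuples or bare
    positions.  Pairs are admissible when |pos_a - pos_b| <= tolerance and,
    if both carry a strand, the strands agree.  Returns
    ``(matched, a_only, b_only)`` where ``matched`` is a list of
    ``(a_item, b_item)`` pairs.
    """
    a_norm = [_as_pos_strand(x) for x in set_a]
    b_norm = [_as_pos_strand(x) for x in set_b]
    candidates = []
    for i, (pa, sa) in enumerate(a_norm):
        for j, (pb, sb) in enumerate(b_norm):
            if sa is not None and sb is not None and sa != sb:
                continue
            d = abs(pa - pb)
            if d <= tolerance:
                candidates.append((d, pa, pb, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((set_a[i], set_b[j]))
    a_only = [x for i, x in enumerate(set_a) if i not in used_a]
    b_only = [x for j, x in enumerate(set_b) if j not in used_b]
    return matched, a_only, b_only


def replicate_consensus(
    replicate_peak_sets: Sequence[Sequence[Peak]],
    tolerance: int = MATCH_TOLERANCE_DEFAULT,
) -> list[Peak]:
    """Keep replicate-1 peaks present (within tolerance, same strand) in all replicates."""
    if len(replicate_peak_sets) < 2:
        logger.warning("replicate consensus called with a single replicate; returning it unchanged")
        return list(replicate_peak_sets[0])
    first = replicate_peak_sets[0]
    consensus = []
    for p in first:
        if all(
            any(
                q.strand == p.strand
                and q.chrom == p.chrom
                and abs(q.peak_position - p.peak_position) <= tolerance
                for q in rep
            )
            for rep in replicate_peak_sets[1:]
        ):
            consensus.append(p)
    return consensus
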