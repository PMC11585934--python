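"""Reading and writing of the formats the pipeline touches.

All coordinate-convention conversion happens here.  Internally the package
works in 1-based inclusive genomic coordinates (genome-browser convention);
BED records are 0-based half-open and are converted at this boundary, in
both directions.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: columns of the peak CSV, in order
PEAK_CSV_COLUMNS = [
    "chrom",
    "strand",
    "peak_start",
    "peak_end",
    "peak_position",
    "peak_coverage",
    "min_adjusted_p",
    "category",
]


class BedParseError(ValueError):
    """A malformed line in a BED file; the message names the line number."""


@dataclass(frozen=True)
class MappedRead:
    """One aligned read from a BED6 record.

    ``start``/``end`` keep the BED convention: 0-based, half-open.
    ``score`` is BED column 5, interpreted as the aligner's read/mapping
    quality (the value the quality filter thresholds).
    """

    chrom: str
    start: int
    end: int
    score: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")
        if self.score < 0:
            raise ValueError(f"negative read score {self.score}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class GeneRecord:
    """An annotated feature interval, 1-based inclusive (GFF native)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def read_bed(path: str | Path) -> list[MappedRead]:
    """Parse a BED6 file of mapped reads, preserving line order.

    Track and comment lines (``track``, ``browser``, ``#``) are skipped.
    Raises :class:`BedParseError` naming the offending line on malformed
    input, and ``FileNotFoundError`` if the file is missing.
    """
    path = Path(path)
    reads: list[MappedRead] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, _name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                # BED scores are sometimes written as floats by aligner wrappers
                score = int(float(score_s))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score {score_s!r}") from exc
            if strand not in STRANDS:
                raise BedParseError(f"{path}:{lineno}: strand {strand!r} not in {STRANDS}")
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if score < 0:
                raise BedParseError(f"{path}:{lineno}: negative score {score}")
            reads.append(MappedRead(chrom, start, end, score, strand))
    return reads


def write_bed(reads: Iterable[MappedRead], path: str | Path) -> None:
    """Write reads back out as BED6 (inverse of :func:`read_bed`)."""
    with open(path, "w") as handle:
        for i, r in enumerate(reads):
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t{r.score}\t{r.strand}\n")


DEFAULT_FEATURE_TYPES = frozenset({"gene", "CDS", "tRNA", "rRNA"})

_GENE_ID_ATTRIBUTES = ("ID", "locus_tag", "gene_id")


def read_gene_annotation(
    path: str | Path,
    feature_types: Iterable[str] = DEFAULT_FEATURE_TYPES,
) -> list[GeneRecord]:
    """Load gene intervals from a GFF3 or GTF annotation.

    Keeps features whose type is in ``feature_types`` and takes the gene
    identifier from the ``ID``, ``locus_tag`` or ``gene_id`` attribute, in
    that priority order.  Records whose attribute column cannot be parsed
    are skipped with a warning.
    """
    import gffutils

    feature_types = set(feature_types)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            continue
        if feat.strand not in STRANDS:
            logger.warning("skipping feature at %s:%s with strand %r", feat.seqid, feat.start, feat.strand)
            continue
        gene_id = None
        for key in _GENE_ID_ATTRIBUTES:
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        if gene_id is None:
            logger.warning("skipping feature at %s:%s: no ID/locus_tag/gene_id attribute", feat.seqid, feat.start)
            continue
        records.append(GeneRecord(gene_id, feat.seqid, feat.strand, feat.start, feat.end))
    if not records:
        warnings.warn(f"no features of type {sorted(feature_types)} retained from {path}")
    return records


def write_peaks(peaks: Sequence, path: str | Path, format: str = "csv") -> None:
    """Write peaks as CSV (full schema) or BED6.

    The CSV keeps internal 1-based inclusive coordinates; BED output converts
    ``[peak_start, peak_end]`` to 0-based half-open, uses the representative
    position as the name and ``min(1000, round(peak_coverage))`` as the score.
    """
    if format == "csv":
        rows = [
            {
                "chrom": p.chrom,
                "strand": p.strand,
                "peak_start": p.start,
                "peak_end": p.end,
                "peak_position": p.peak_position,
                "peak_coverage": p.peak_coverage,
                "min_adjusted_p": p.min_adjusted_p,
                "category": "" if p.category is None else str(p.category),
            }
            for p in peaks
        ]
        pd.DataFrame(rows, columns=PEAK_CSV_COLUMNS).to_csv(path, index=False)
    elif format == "bed":
        with open(path, "w") as handle:
            for p in peaks:
                score = min(1000, round(p.peak_coverage))
                handle.write(
                    f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.peak_position}\t{score}\t{p.strand}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'bed')")


def read_peaks_csv(path: str | Path) -> list:
    """Read a peak CSV written by :func:`write_peaks` back into Peak objects."""
    from .condense import Peak

    peaks: list[Peak] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            category = row.get("category") or None
            peaks.append(
                Peak(
                    chrom=row["chrom"],
                    strand=row["strand"],
                    start=int(row["peak_start"]),
                    end=int(row["peak_end"]),
                    peak_position=int(row["peak_position"]),
                    peak_coverage=int(row["peak_coverage"]),
                    min_adjusted_p=float(row["min_adjusted_p"]),
                    category=category,
                )
            )
    return peaks


def read_positions_csv(path: str | Path) -> list[tuple[int, str | None]]:
    """Read a generic peak-position table for cross-method comparison.

    Expects a header containing at least a ``position`` (or ``peak_position``)
    column; a ``strand`` column is used when present.  Returns
    ``(position, strand-or-None)`` tuples.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    pos_col = cols.get("position") or cols.get("peak_position")
    if pos_col is None:
        raise ValueError(f"{path}: no 'position' or 'peak_position' column")
    strand_col = cols.get("strand")
    out: list[tuple[int, str | None]] = []
    for _, row in df.iterrows():
        strand = str(row[strand_col]) if strand_col is not None else None
        out.append((int(row[pos_col]), strand))
    return out
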