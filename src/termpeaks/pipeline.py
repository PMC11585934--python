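"""End-to-end orchestration of the three-step peak-calling workflow.

One input file is processed as: quality filter -> strand-separated 3'-end
coverage (per chromosome) -> one adaptive coverage cutoff pooled over the
whole file -> sliding-window Poisson scan with BH correction per
(chromosome, strand) -> condensing step two (adjacent positions) -> step
three (proximal peaks) -> optional genomic-context classification.  The
analysis path contains no randomness: identical inputs and parameters give
identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import annotate as _annotate
from . import condense as _condense
from . import coverage as _coverage
from . import detect as _detect
from . import io as _io

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Stage-by-stage diagnostics for one analyzed input file."""

    input_path: str
    parameters: dict
    n_reads_total: int = 0
    n_reads_pass: int = 0
    reads_per_strand: dict = field(default_factory=dict)
    cutoff: Optional[float] = None
    cutoff_n_selected: int = 0
    cutoff_n_trimmed: int = 0
    total_coverage: int = 0
    n_tests: int = 0
    n_significant_positions: int = 0
    n_peaks_step_two: int = 0
    n_peaks_step_three: int = 0
    category_counts: Optional[dict] = None
    stage_seconds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def call_peaks(
    reads: Sequence[_io.MappedRead],
    params: _detect.Parameters,
    genome_length: Optional[int] = None,
    report: Optional[RunReport] = None,
) -> list[_condense.Peak]:
    """Run the full analysis on an in-memory read collection.

    ``genome_length`` applies to every chromosome present (inferred per
    chromosome from the reads when omitted).
    """
    report = report if report is not None else RunReport("<memory>", asdict(params))
    report.n_reads_total = len(reads)

    t0 = time.perf_counter()
    passing = _coverage.filter_by_quality(reads, params.readScoreMinimum)
    report.n_reads_pass = len(passing)
    report.reads_per_strand = {
        s: sum(1 for r in passing if r.strand == s) for s in ("+", "-")
    }
    report.stage_seconds["filter"] = time.perf_counter() - t0
    if not passing:
        logger.warning("no reads pass the quality filter (readScoreMinimum=%d)", params.readScoreMinimum)
        return []

    t0 = time.perf_counter()
    coverages: list[_coverage.StrandCoverage] = []
    for chrom, chrom_reads in _coverage.group_reads_by_chrom(passing).items():
        coverages.extend(_coverage.extract_three_prime_coverage(chrom_reads, genome_length))
    report.stage_seconds["coverage"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cutoff_result = _detect.compute_global_cutoff(coverages, params)
    report.cutoff = cutoff_result.cutoff
    report.cutoff_n_selected = cutoff_result.n_selected
    report.cutoff_n_trimmed = cutoff_result.n_trimmed
    report.total_coverage = cutoff_result.total_coverage
    report.stage_seconds["cutoff"] = time.perf_counter() - t0
    logger.info(
        "adaptive coverage cutoff %.3f (from %d positions, %d outliers trimmed)",
        cutoff_result.cutoff, cutoff_result.n_selected, cutoff_result.n_trimmed,
    )

    t0 = time.perf_counter()
    peaks: list[_condense.Peak] = []
    n_sig = n_step2 = 0
    for cov in coverages:
        sig = _detect.scan_strand(cov, cutoff_result.cutoff, params)
        n_sig += len(sig)
        step2 = _condense.merge_adjacent_positions(sig, params.adjacentPeakDistance, cov.chrom)
        n_step2 += len(step2)
        peaks.extend(_condense.merge_proximal_peaks(step2, params.peakCondensingDistance))
    report.n_significant_positions = n_sig
    report.n_peaks_step_two = n_step2
    report.n_peaks_step_three = len(peaks)
    report.stage_seconds["scan_and_condense"] = time.perf_counter() - t0
    if not peaks:
        logger.warning("no significant peaks found")
    peaks.sort(key=lambda p: (p.chrom, p.strand, p.start))
    return peaks


def run_pipeline(
    bed_paths: Sequence[str | Path],
    params: _detect.Parameters,
    annotation: Optional[str | Path] = None,
    output_prefix: str = "termpeaks",
    genome_length: Optional[int] = None,
) -> list[RunReport]:
    """Analyze each BED file and write peak CSV/BED plus a JSON run report.

    With several inputs, each output file name carries the input's stem.
    """
    if not bed_paths:
        raise ValueError("at least one BED path is required")
    genes = _io.read_gene_annotation(annotation) if annotation else None

    reports = []
    multiple = len(bed_paths) > 1
    for bed_path in bed_paths:
        bed_path = Path(bed_path)
        prefix = f"{output_prefix}_{bed_path.stem}" if multiple else output_prefix
        report = RunReport(str(bed_path), asdict(params))

        t0 = time.perf_counter()
        reads = _io.read_bed(bed_path)
        report.stage_seconds["read_bed"] = time.perf_counter() - t0

        peaks = call_peaks(reads, params, genome_length=genome_length, report=report)

        if genes is not None:
            t0 = time.perf_counter()
            report.category_counts = _annotate.classify_peaks(peaks, genes)
            report.stage_seconds["classify"] = time.perf_counter() - t0

        _io.write_peaks(peaks, f"{prefix}_peaks.csv", "csv")
        _io.write_peaks(peaks, f"{prefix}_peaks.bed", "bed")
        with open(f"{prefix}_report.json", "w") as handle:
            json.dump(report.to_dict(), handle, indent=2)
        logger.info(
            "%s: %d reads (%d passing) -> %d significant positions -> %d peaks",
            bed_path, report.n_reads_total, report.n_reads_pass,
            report.n_significant_positions, report.n_peaks_step_three,
        )
        reports.append(report)
    return reports
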