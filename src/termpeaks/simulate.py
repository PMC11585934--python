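"""Synthetic Term-seq read generator with known terminator ground truth.

Emulates the signal structure of bacterial 3'-end sequencing: each gene ends
in a terminator that concentrates most of its reads' 3' ends at one position
(with ~1-2 nt of jitter), while the remainder of the gene's reads end
uniformly within its body, modelling expression-proportional cleavage and
degradation noise.  Read quality scores are drawn from a two-component
mixture so the quality filter is exercised end to end.

The generator does not model base-level sequencing error, rRNA
contamination, or replicate batch effects (replicates are produced by
re-seeding); see the methods note for what this implies for test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io import MappedRead


@dataclass
class SimConfig:
    """Study conditions for one synthetic Term-seq library.

    ``expression_meanlog``/``expression_sdlog`` parameterize the log-normal
    draw of each gene's read count (natural-log scale, read-count units);
    ``terminator_efficiency`` is the fraction of a gene's reads whose 3' end
    falls at the terminator (jittered), the rest end uniformly in the body.
    """

    genome_length: int = 100_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (500, 3000)
    expression_meanlog: float = 3.0
    expression_sdlog: float = 1.0
    terminator_efficiency: float = 0.7
    jitter_sd: float = 1.0
    read_length_range: tuple[int, int] = (30, 80)
    quality_mix: float = 0.9
    seed: int = 0
    chrom: str = "synth1"

    def __post_init__(self) -> None:
        if not 0 <= self.terminator_efficiency <= 1:
            raise ValueError("terminator_efficiency must be in [0, 1]")
        if not 0 <= self.quality_mix <= 1:
            raise ValueError("quality_mix must be in [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        if self.gene_length_range[1] >= self.genome_length:
            raise ValueError("genes must fit inside the genome")


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    terminator: int  # gene 3' boundary
    n_reads: int


@dataclass
class GroundTruth:
    """Planted terminators: one per simulated gene, at its 3' boundary."""

    chrom: str
    genes: list[SimGene] = field(default_factory=list)

    @property
    def terminators(self) -> list[tuple[str, str, int]]:
        return [(self.chrom, g.strand, g.terminator) for g in self.genes]


class PlacementError(RuntimeError):
    pass


_PLACEMENT_RETRIES = 1000


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Place n_genes non-overlapping-per-strand intervals, in a fixed draw order."""
    occupied: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    placed: list[tuple[str, int, int]] = []
    lo, hi = cfg.gene_length_range
    for _ in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(lo, hi + 1))
        for _attempt in range(_PLACEMENT_RETRIES):
            start = int(rng.integers(1, cfg.genome_length - length + 2))
            end = start + length - 1
            if all(end < a or start > b for a, b in occupied[strand]):
                occupied[strand].append((start, end))
                placed.append((strand, start, end))
                break
        else:
            raise PlacementError(
                f"could not place {cfg.n_genes} non-overlapping genes of length "
                f"{cfg.gene_length_range} in a {cfg.genome_length} nt genome; "
                "reduce n_genes or gene lengths"
            )
    return placed


def simulate_termseq(config: SimConfig) -> tuple[list[MappedRead], GroundTruth]:
    """Generate mapped reads and the planted-terminator ground truth.

    Deterministic for a fixed seed: one RNG stream is consumed in a fixed
    order (per gene: strand, length, placement, expression; then per read:
    terminator/noise choice, 3'-end position, read length, quality).
    """
    rng = np.random.default_rng(config.seed)
    placed = _place_genes(config, rng)

    reads: list[MappedRead] = []
    truth = GroundTruth(chrom=config.chrom)
    rl_lo, rl_hi = config.read_length_range
    for i, (strand, g_start, g_end) in enumerate(placed):
        terminator = g_end if strand == "+" else g_start
        n_reads = int(round(rng.lognormal(config.expression_meanlog, config.expression_sdlog)))
        truth.genes.append(SimGene(f"gene{i:03d}", strand, g_start, g_end, terminator, n_reads))
        for _ in range(n_reads):
            if rng.random() < config.terminator_efficiency:
                jitter = int(round(rng.normal(0.0, config.jitter_sd))) if config.jitter_sd > 0 else 0
                t = int(np.clip(terminator + jitter, 1, config.genome_length))
            else:
                t = int(rng.integers(g_start, g_end + 1))
            read_len = int(rng.integers(rl_lo, rl_hi + 1))
            if strand == "+":
                left = max(1, t - read_len + 1)
                right = t
            else:
                left = t
                right = min(config.genome_length, t + read_len - 1)
            if rng.random() < config.quality_mix:
                score = int(rng.integers(30, 61))
            else:
                score = int(rng.integers(0, 30))
            reads.append(MappedRead(config.chrom, left - 1, right, score, strand))
    return reads, truth


def truth_table(truth: GroundTruth):
    """Ground truth as a DataFrame (chrom, strand, position, gene_id, expected_reads)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": truth.chrom,
                "strand": g.strand,
                "position": g.terminator,
                "gene_id": g.gene_id,
                "gene_start": g.start,
                "gene_end": g.end,
                "expected_reads": g.n_reads,
            }
            for g in truth.genes
        ]
    )


def evaluate_against_truth(
    peaks: Sequence,
    truth: GroundTruth,
    hit_tolerance: int = 2,
    false_tolerance: int = 20,
) -> tuple[float, float]:
    """Score called peaks against the planted terminators.

    Returns ``(recovery, false_fraction)``: the fraction of planted
    terminators with a same-strand peak representative within
    ``hit_tolerance`` nt, and the fraction of peaks whose representative is
    more than ``false_tolerance`` nt from every planted terminator.
    """
    reps = [(p.strand, p.peak_position) for p in peaks]
    hits = sum(
        1
        for g in truth.genes
        if any(s == g.strand and abs(r - g.terminator) <= hit_tolerance for s, r in reps)
    )
    recovery = hits / len(truth.genes) if truth.genes else 0.0
    false_calls = sum(
        1
        for s, r in reps
        if all(
            g.strand != s or abs(r - g.terminator) > false_tolerance for g in truth.genes
        )
    )
    false_fraction = false_calls / len(reps) if reps else 0.0
    return recovery, false_fraction


def config_dict(config: SimConfig) -> dict:
    """JSON-serializable echo of the configuration (reproducibility sidecar)."""
    d = asdict(config)
    d["gene_length_range"] = list(d["gene_length_range"])
    d["read_length_range"] = list(d["read_length_range"])
    return d
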