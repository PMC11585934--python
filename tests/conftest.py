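import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/reference.py importable

from termpeaks import Parameters, SignificantPosition, StrandCoverage


@pytest.fixture
def default_params():
    return Parameters()


@pytest.fixture
def toy_gff(tmp_path):
    """Five genes on a small chromosome, GFF3 with locus_tag attributes."""
    lines = ["##gff-version 3"]
    genes = [
        ("TP_0001", 1000, 2000, "+"),
        ("TP_0002", 3000, 4200, "+"),
        ("TP_0003", 5000, 5900, "-"),
        ("TP_0004", 7000, 9000, "-"),
        ("TP_0005", 9500, 9900, "+"),
    ]
    for i, (tag, start, end, strand) in enumerate(genes):
        lines.append(
            f"chr1\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID=g{i};locus_tag={tag}"
        )
    path = tmp_path / "toy.gff3"
    path.write_text("\n".join(lines) + "\n")
    return path, genes


def make_coverage(counts: dict[int, int], genome_length: int, strand: str = "+",
                  chrom: str = "chr1") -> StrandCoverage:
    return StrandCoverage(chrom, strand, dict(counts), genome_length)


def make_positions(spec: dict[int, int], strand: str = "+", p_adj: float = 1e-4):
    """Significant positions from a {position: coverage} mapping."""
    return [
        SignificantPosition(pos, strand, cov, window_lambda=1.0, p_raw=p_adj / 2, p_adj=p_adj)
        for pos, cov in sorted(spec.items())
    ]


def random_sparse_coverage(rng: np.random.Generator, genome_length: int,
                           n_nonzero: int, max_count: int = 60) -> dict[int, int]:
    positions = rng.choice(np.arange(1, genome_length + 1), size=n_nonzero, replace=False)
    return {int(p): int(c) for p, c in zip(positions, rng.integers(1, max_count + 1, n_nonzero))}
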