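"""Simulate a Term-seq library and call termination peaks on it.

Generates 40 genes with a planted terminator each, runs the full analysis
(quality filter, 3'-end coverage, adaptive cutoff, windowed Poisson scan,
two condensing steps) and scores the calls against the planted truth.
"""

from termpeaks import Parameters, SimConfig, call_peaks, simulate_termseq
from termpeaks.simulate import evaluate_against_truth

cfg = SimConfig(seed=11)
reads, truth = simulate_termseq(cfg)
print(f"simulated {len(reads)} reads for {cfg.n_genes} genes "
      f"on a {cfg.genome_length:,} nt genome")

peaks = call_peaks(reads, Parameters(), genome_length=cfg.genome_length)
recovery, false_frac = evaluate_against_truth(peaks, truth)

print(f"called {len(peaks)} termination peaks")
print(f"recovery: {recovery:.1%} of planted terminators have a peak "
      "representative within 2 nt")
print(f"false calls: {false_frac:.1%} of peaks lie >20 nt from every planted site")
print("\nfirst three peaks (1-based inclusive ranges):")
for p in peaks[:3]:
    print(f"  {p.strand} [{p.start}-{p.end}] rep={p.peak_position} "
          f"coverage={p.peak_coverage} p_adj={p.min_adjusted_p:.2e}")
print("\nrecovery is bounded by the adaptive coverage cutoff: genes expressed "
      "below it are deliberately not tested, so misses concentrate there.")
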