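# Methods

## Model and procedure

The caller treats per-position 3′-end read counts on one strand as locally
Poisson: within a short window, the count at a position is compared with
the window's mean coverage λ via the upper tail P(X ≥ x | λ). This is a
deliberate simplification — 3′-end counts are overdispersed across the
genome — but the windowing confines each test to a neighbourhood where a
single rate is a reasonable null, which is the point of assigning
significance locally rather than against a genome-wide background.
Windows of 51 nt advancing by 25 nt mean interior positions are tested
against up to ⌈51/25⌉ = 3 overlapping local backgrounds; a position is
reported on its best Benjamini–Hochberg-adjusted p-value. λ includes
zero-coverage positions, which dominate real data (the vast majority of
genomic positions carry no 3′ ends), so excluding them would inflate the
background and suppress exactly the low-expression signal the local test
exists to protect.

The test family for BH correction is all (position, window) tests on one
strand of one file. The workflow is strand-separated throughout, so the
strand is the natural analysis unit; pooling strands would mix families
with potentially very different signal densities.

### Adaptive minimum-coverage cutoff

Only positions whose coverage reaches a file-specific floor are tested.
Nonzero counts from both strands are pooled and sorted descending; the
smallest prefix holding `threshAdjust` (default 0.75) of total coverage is
selected; `floor(highOutlierTrim × prefix size)` of its largest values
(default fraction 0.01) are dropped from the mean — guarding against
outliers such as residual rRNA — and the mean of the rest is the cutoff.
Trimmed positions remain eligible for testing; trimming only affects the
mean. Floor (not ceiling) is used for the trim count so tiny prefixes are
never over-trimmed; a consequence worth recording is that the trim can
never empty the prefix (floor(t·k) < k for t < 1), so the documented
fallback to the untrimmed mean is defensive only. Ties in the descending
sort are irrelevant to the cutoff value (only values, not identities,
enter the mean).

This cutoff is the method's strictness dial. Lowering `threshAdjust`
(0.50–0.60) suits very deep libraries or long genomes; raising it
(0.80–0.95) recovers low-coverage signal in shallow data. `highOutlierTrim`
is the more sensitive of the two and may need 0.025–0.05 when a handful of
positions dominate the library.

### Condensing

Significant positions within 2 nt chain transitively into peaks; peaks with
edge-to-edge gaps ≤ 20 nt merge. "Within k nt" is positional difference ≤ k
for positions and edge-to-edge gap ≤ k for peaks — the biological rationale
(hairpin-mediated pausing spaces independent terminators ≥ 15–20 nt apart)
constrains spacing between *sites*, and edge-to-edge is the conservative
reading. Representatives are the maximum-coverage member, leftmost on ties,
making output fully deterministic. Both steps preserve the union of member
ranges.

### Classification and comparison

Classification uses the representative position only (reported positions
are what other analyses publish), against same-strand genes. Decision
order: 5′-UTR window (≤ 450 nt upstream of a start codon) overrides
everything; then 3′-UTR (≤ 150 nt downstream of a stop) combined with a
*different* gene's body gives "3′-UTR & coding"; then 3′-UTR; then coding;
else intergenic. "Coding region" is the annotated feature interval —
bacterial gene bounds are not subdivided into CDS vs. gene. A peak on the
opposite strand of every nearby gene falls through to intergenic: the
categories are strand-respecting by construction.

Cross-set matching is greedy nearest-first one-to-one within a 5 nt
tolerance (strand-aware when both sets carry strand). Greedy is not a
maximum-cardinality matcher in adversarial configurations — a chosen pair
can block two others — but on realistic peak sets, where peaks are spaced
far beyond the tolerance, it coincides with the optimum; the tests verify
this against exhaustive assignment on small instances. Replicate consensus
keeps a replicate-1 peak iff every other replicate has a same-strand peak
within the same 5 nt tolerance, reusing the matching tolerance because no
separate intra-replicate distance is established for the protocol.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| readScoreMinimum | 30 | score | minimum BED column-5 quality |
| threshAdjust | 0.75 | fraction | coverage mass defining the cutoff prefix |
| highOutlierTrim | 0.01 | fraction | top prefix values trimmed from cutoff mean |
| slidingWindowSize | 51 | nt | window extent (odd) |
| slidingWindowMovementDistance | 25 | nt | window step (≤ size, so windows tile) |
| user_pValue | 0.005 | — | BH-adjusted α; conservative because the family is large |
| adjacentPeakDistance | 2 | nt | step-two chaining distance |
| peakCondensingDistance | 20 | nt | step-three edge-to-edge merge distance |

The `Parameters` dataclass keeps these verbatim (camelCase) names so CLI
flags, config-file keys and the field names users know from the
established R workflow coincide exactly.

## Coordinate conventions

Internal coordinates are 1-based inclusive (genome-browser convention);
BED input/output converts at the I/O boundary. A `+` read's 3′ end is its
BED `end` in 1-based terms; a `-` read's is `start + 1`. The original
workflow does not document this arithmetic publicly, so the choice is
isolated in `coverage.three_prime_position` where it can be flipped in one
place; any other choice contradicts transcript-orientation 3′-end
semantics.

## Synthetic data generator

`simulate.simulate_termseq` emulates the canonical Term-seq signal shape:
per gene, a log-normal read count (meanlog 3.0, sdlog 1.0 — median ≈ 20
reads, a realistic per-gene 3′-end yield for a desk-scale library),
a fraction `terminator_efficiency` = 0.7 of reads ending at the gene's 3′
boundary with discretized-normal jitter (sd 1 nt, matching the ±1–2 nt
spread of real terminator pileups), the rest ending uniformly in the gene
body (expression-proportional cleavage noise), and a quality mixture
(90% of scores ≥ 30) so the quality filter is exercised. One RNG stream is
consumed in a fixed documented order, making output byte-reproducible for
a seed.

What it does not model: base-level sequencing error, rRNA contamination,
replicate batch effects, operonic structure, or Rho-dependent (diffuse)
termination. Passing tests on this generator therefore demonstrate the
statistical machinery — local testing, adaptive cutoff, condensing — not
robustness to library-preparation artifacts.

A property worth stating explicitly: under these default conditions the
pipeline's terminator recovery is bounded near 65%, with essentially zero
false calls. The adaptive cutoff computed from a log-normal expression
profile lands around 3–5 reads, and the ≈35–40% of genes whose terminator
pileup stays below it are never tested. This is the method behaving as
designed — it trades sensitivity to lowly expressed transcripts for a
data-driven noise floor, and recovery rises accordingly when
`threshAdjust` is raised (see `examples/04_compare_two_analyses.py`).

## Numerical choices and degenerate inputs

- Poisson tails come from scipy's survival function (stable for large λ);
  the independent series-summation reference in the tests agrees to 1e-12
  over λ ∈ {0.1, …, 100}, x ≤ 300.
- BH adjustment delegates to statsmodels and is verified against the
  textbook step-up procedure to 1e-12.
- The terminal window is truncated at the genome end and evaluated over
  its actual width.
- Empty coverage maps scan to empty results; an all-zero file is an error
  at the cutoff stage ("no signal").
- Ties: representative selection takes the leftmost maximum; the best test
  per position prefers smaller raw p, then the earlier window.
- Problem sizes in the test suite and acceptance script (100 kb genomes,
  10-seed studies, 10 k-position noise runs) were chosen as the smallest
  sizes at which the statistical properties are stable and clearly
  resolved.

## Known limitations

- The Poisson null ignores overdispersion beyond what windowing absorbs;
  a negative-binomial variant is out of scope.
- Peaks are summarized by a single representative; sub-peak structure
  (closely spaced alternative terminators inside one merged peak) is not
  deconvolved.
- Greedy matching can under-match contrived configurations of peaks packed
  within the tolerance of each other.
- Only BED input is supported; BAM must be converted upstream.
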