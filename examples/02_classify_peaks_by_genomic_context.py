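"""Place called peaks in genomic context relative to an annotation.

Builds a two-gene annotation and classifies hand-made peaks into the five
context categories: 5'-UTR (<=450 nt upstream of a start codon, which
overrides everything), 3'-UTR (<=150 nt downstream of a stop codon),
coding, 3'-UTR & coding, and intergenic.
"""

from termpeaks import GeneRecord, Peak, classify_peak

genes = [
    GeneRecord("rpsG", "chr1", "+", 1000, 2000),
    GeneRecord("fusA", "chr1", "+", 2100, 4000),  # starts 100 nt after rpsG ends
]

def peak(pos):
    return Peak("chr1", "+", pos, pos, pos, 40, 1e-6)

cases = {
    4100: "100 nt past fusA's stop, nothing downstream",
    2120: "20 nt past rpsG's stop AND inside fusA's body",
    1500: "inside rpsG's body",
    2050: "past rpsG's stop but also <450 nt before fusA's start",
    9000: "5 kb from everything",
}
for pos, description in cases.items():
    category = classify_peak(peak(pos), genes)
    print(f"peak at {pos:>5} ({description}): {category}")

print("\nnote the override: a position in both a 3'-UTR and a 5'-UTR window "
      "is reported as 5'-UTR.")
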