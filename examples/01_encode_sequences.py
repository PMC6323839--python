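"""Encode DNA barcodes as gapped base-pair and k-mer compositions.

A sequence of length N maps, for each gap size g, to 16 numbers: the count
of each ordered base pair (s, t) with exactly g bases skipped between them,
divided by N - 1.  Stacking gaps 1..5 gives an 80-dimensional vector; adding
the contiguous dinucleotide block (g = 0) gives 96.  k-mer compositions are
the classical alternative: 4^k frequencies per order k.
"""

from barcodeforest import FeatureSpec, encode_sequence, gapped_pair_frequencies
from barcodeforest.features import DINUCLEOTIDES

sequence = "ACGTACGTTACGGA"

print(f"sequence: {sequence} (N={len(sequence)})")
print("\nnon-zero gap-1 pair frequencies (denominator N-1 = 13):")
for pair, value in zip(DINUCLEOTIDES, gapped_pair_frequencies(sequence, g=1)):
    if value:
        print(f"  {pair}: {value:.4f}")

for spec, label in [
    (FeatureSpec.gapped(), "gaps 1-5"),
    (FeatureSpec.gapped(include_gap0=True), "gaps 0-5"),
    (FeatureSpec.kmer((1, 2, 3, 4)), "k-mers 1-4"),
]:
    vec = encode_sequence(sequence, spec)
    print(f"\n{label}: {vec.size} features, block sums reflect the "
          f"N-1 normalization (total {vec.sum():.3f})")
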