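"""Encode a few mRNA windows under each feature representation.

Builds three toy sequences and prints the dimension of every encoding
plus the EIIP values of "ACGT" — the per-nucleotide pseudopotentials
that give the method its core representation.
"""

from ac4cboost import EncodingScheme, RnaSequence, encode_dataset, encode_sequence

seqs = [
    RnaSequence("w1", "ACGT" * 103 + "ACG"),  # 415 nt, like the benchmark
    RnaSequence("w2", "GGCC" * 103 + "GGC"),
    RnaSequence("w3", "ATAT" * 103 + "ATA"),
]

print("per-scheme dimensions for a 415-nt window:")
for scheme in EncodingScheme:
    vec = encode_sequence(seqs[0], scheme)
    print(f"  {scheme.value:>13}: {vec.shape[0]}")

print("\nEIIP of A,C,G,T:", encode_sequence(RnaSequence("p", "ACGT"), "eiip"))

X = encode_dataset(seqs, EncodingScheme.EIIP_PSEEIIP)
print(f"\nEIIP+PseEIIP matrix: {X.n_sequences} x {X.n_features}")
print("first PseEIIP feature names:", X.feature_names[415:418])
# Each row is one window; columns 1-415 are positional EIIP values and
# columns 416-479 are composition-weighted trinucleotide pseudopotentials.
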