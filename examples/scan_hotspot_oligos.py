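"""Motif content of the chromosomal integration-hotspot probes.

Counts GAGY tandem repeats and minimal GAGCGAGC Rep-binding consensus
occurrences in the oligonucleotides spanning the three hotspot RBS regions
(complementary strands) and in the Rep-binding-deficient GAGG-substituted
control probe.
"""

from rbsprox import compile_motif, longest_tandem_run, scan_sequence

OLIGOS = {
    "AAVS1 (chr19)": "GCCCGCCCGCCCAGCGAGCGAGCGAGCGCCGAGCCCCAACCGCCGCCA",
    "AAVS2 (chr5)": "ACAAAGCGGTGAGGGGAGAGTGAGTGAGCGAGCGTGGGGTCCAGCT",
    "AAVS3 (chr3)": "GTGAGGAGTGAGTGAGTGAGCGAGCGCACATTCATTCCCCTTGGGAAGC",
    "AAVS2 mutated": "ACAAAGCGGTGAGGGGAGAGGGAGGGAGCGAGGGTGGGGTCCAGCT",
}

consensus = compile_motif("GAGC GAGC", 0)
print(f"{'probe':<16}{'GAGY repeats':>14}{'GAGCGAGC hits':>15}")
for name, seq in OLIGOS.items():
    runs = longest_tandem_run(seq, "GAGY")
    hits = len(scan_sequence(seq, consensus, strands="+"))
    print(f"{name:<16}{runs:>14}{hits:>15}")

print(
    "\nThe longest abutting GAGY run measures the tandem-repeat strength of "
    "each Rep-binding site (5 at AAVS3, 4 at AAVS2); the GAGG-substituted "
    "control loses the GAGCGAGC consensus entirely."
)
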