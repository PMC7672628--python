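"""Extract primary-variant 3'UTRs and count the six DAZL-binding motifs.

The 3'UTR runs from the base after the stop codon to the transcript end
(reverse-complemented for minus-strand genes); motifs are counted with a
step-1 sliding window, overlaps included.
"""

from utrzga import (
    SimulationConfig,
    extract_utrs,
    scan_gene_set,
    simulate_bundle,
)

bundle = simulate_bundle(SimulationConfig(seed=1, n_genes=50))
utrs, skipped = extract_utrs(bundle.genome, bundle.transcripts)
table = scan_gene_set(utrs)

print(f"extracted {len(utrs)} UTRs ({len(skipped)} genes skipped)")
print(table.head(8).to_string())
truth = bundle.truth.motif_counts
exact = (table.loc[truth.index, truth.columns] == truth).all(axis=1).mean()
print(f"\nfraction of genes whose counts equal the planted truth: {exact:.3f}")
# 1.000 means the scanner reproduced every planted occurrence and found
# nothing on the motif-free background.
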