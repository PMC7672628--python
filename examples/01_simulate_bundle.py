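"""Generate a synthetic genome + annotation + count bundle with known truth.

The generator plants DAZL-motif occurrences in 3'UTRs on a T-free
background (so every match is intentional) and draws NB counts following
per-gene temporal archetypes across the seven developmental stages.
"""

from utrzga import SimulationConfig, simulate_bundle, write_bundle

config = SimulationConfig(seed=1, n_genes=50)
bundle = simulate_bundle(config)
paths = write_bundle(bundle, "scratch/example_bundle")

print(f"genome: 1 chromosome, {len(bundle.genome['chr1']):,} bp")
print(f"genes: {len(bundle.transcripts)} (alternating strands)")
print(f"count matrix: {bundle.counts.shape[0]} genes x {bundle.counts.shape[1]} samples")
print("archetype mix:")
print(bundle.truth.genes["archetype"].value_counts().to_string())
print(f"files written: {sorted(p.name for p in paths.values())}")
# Each gene's truth row records its archetype, exact planted motif counts
# and the true log2 fold change at every consecutive-stage contrast.
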