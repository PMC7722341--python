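"""Measure RBP binding-site enrichment over nimtRNA loci.

Binding intervals (eCLIP-style, stranded BED) are intersected with
nimtRNA loci on the same strand; the per-nucleotide coverage density
over nimtRNAs is divided by the density over the intron background
(nimtRNA bases excluded), and RBPs exceeding 2-fold are flagged.
"""

import nimtscan as ns
from nimtscan.rbp import enrichment, intron_intervals

truth = ns.simulate(ns.EvolutionParams(seed=5, sp=0.05, n_insertions=30,
                                       nuclear_length=90_000,
                                       min_trnas_per_insertion=1,
                                       intronic_fraction=1.0))
# simulate sites: RBPX truly enriched 8-fold, the rest at background
sites = ns.simulate_binding_sites(truth, ["RBPX"], fold=8.0, seed=2)
all_sites = [s for rbp in sorted(sites) for s in sites[rbp]]

nimts = [m.nuclear for m in truth.nimtrnas]
records = enrichment(nimts, intron_intervals(truth.transcripts), all_sites)

print(f"nimtRNA territory: {sum(m.length for m in nimts):,} nt "
      f"in {len(nimts)} loci")
print("rbp     density_nimt  density_bg   fold  enriched")
for r in records:
    if r.sample != "pooled":
        continue
    print(f"{r.rbp:7} {r.density_nimt:11.4f} {r.density_bg:11.4f} "
          f"{r.fold:6.2f}  {'yes' if r.enriched else 'no'}")

# Only RBPs whose binding density over nimtRNAs is strictly more than
# twice the intron background are flagged; the simulated 8-fold RBPX
# should be the only flag, background RBPs hover around fold 1.
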