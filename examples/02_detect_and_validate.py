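"""Detect tRNA-lookalikes and validate them against numtDNA synteny.

The built-in detector aligns each mitochondrial tRNA reference against
both strands of the nuclear sequence, rewarding candidates that preserve
the reference's cloverleaf base pairs.  Validation reconstructs the tRNA
copies expected inside each numtDNA from its mitochondrial source
coordinates and counts a hit as a true positive only when it matches an
expected copy in isotype, position and order.
"""

import nimtscan as ns
from nimtscan.synteny import classify_hits, expected_copies

truth = ns.simulate(ns.EvolutionParams(seed=1, n_insertions=10,
                                       nuclear_length=40_000,
                                       min_trnas_per_insertion=1))
refs = [ns.TrnaReference.from_strings(iso, seq, db)
        for iso, seq, db in truth.template.references()]

hits = ns.builtin_scan(truth.nuclear, refs)
hits = ns.assign_context(hits, truth.transcripts)

numts = [ins.numt for ins in truth.insertions]
expected = expected_copies(numts, truth.template.genes)
validated, summary = classify_hits(hits, expected, numts)

contexts = {}
for h in hits:
    contexts[h.context] = contexts.get(h.context, 0) + 1
print(f"hits: {len(hits)}  contexts: {contexts}")
print(f"expected copies from synteny: {len(expected)}")
print(f"TP={summary.tp}  FP={summary.fp}  FN={summary.fn}  "
      f"TPR={summary.tpr:.3f}")

# The TPR is the fraction of synteny-expected tRNA copies the detector
# recovered; hits outside numtDNAs or violating the expected copy order
# would count as false positives.
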