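"""Test MTLs for stabilizing selection with the divergence regression.

For each validated MTL two divergences are measured against the extant
mitochondrial genome: dt (the MTL itself vs its tRNA) and dp (the
MTL-masked numtDNA flank vs its source).  Both grow linearly with
insertion age, so under neutrality points fall on a line; MTLs evolving
slower than their flank predicts fall below it and are flagged when
their Cook's distance exceeds three times the mean.
"""

import nimtscan as ns
from nimtscan.conservation import build_points, fit_and_flag
from nimtscan.core import MtlHit
from nimtscan.synteny import classify_hits, expected_copies

params = ns.EvolutionParams(seed=4, sn=0.02, sp=0.1, st=0.1,
                            functional_factor=0.2, functional_fraction=0.1,
                            n_insertions=60, insertion_length_range=(200, 400),
                            nuclear_length=90_000, min_trnas_per_insertion=1)
truth = ns.simulate(params)
numts = [ins.numt for ins in truth.insertions]
hits = [MtlHit(m.nuclear, m.isotype, 100.0, "builtin") for m in truth.mtls]
expected = expected_copies(numts, truth.template.genes)
validated, _ = classify_hits(hits, expected, numts)

points = build_points(validated, numts, truth.extant_mito, truth.nuclear)
fit = fit_and_flag(points, k=3.0)

print(f"points: {len(points)} (flanks >50 nt)")
print(f"fit: dt = {fit.slope:.3f} * dp + {fit.intercept:.4f}")
print(f"Cook threshold (3 x mean): {fit.threshold:.5f}")
print(f"flagged conserved outliers: {int(fit.flags.sum())}")
for p, flag, d in zip(points, fit.flags, fit.cooks_d):
    if flag:
        print(f"  {p.mtl_id}: dt={p.dt:.3f} dp={p.dp:.3f} D={d:.4f}")

# Flagged loci have diverged markedly less than their surrounding
# numtDNA — the signature of stabilizing selection after insertion.
# In this simulation 10% of loci truly evolve at one fifth of the
# neutral rate; the flags above are the detectable (older) subset.
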