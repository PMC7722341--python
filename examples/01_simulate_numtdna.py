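"""Simulate a nuclear genome carrying numtDNA insertions with ground truth.

The simulator copies segments of a mitochondrial template into a random
nuclear background at random past times; flanks then diverge neutrally
while tRNA-lookalike (MTL) loci diverge at their own rate.  The returned
truth object records every insertion, its age, and the MTL loci it
carries.
"""

import nimtscan as ns

params = ns.EvolutionParams(seed=1, sn=0.02, sp=0.1, n_insertions=10,
                            nuclear_length=40_000, min_trnas_per_insertion=1)
truth = ns.simulate(params)

print(f"nuclear genome: {len(truth.nuclear.sequence):,} nt")
print(f"insertions: {len(truth.insertions)}  "
      f"MTL loci: {len(truth.mtls)}  intronic (nimtRNAs): {len(truth.nimtrnas)}")
print()
print("numt_id   nuclear interval      mt source        age t0  MTLs")
for ins in truth.insertions[:5]:
    nu, mt = ins.numt.nuclear, ins.numt.mt_source
    isotypes = ",".join(m.isotype for m in ins.mtls) or "-"
    print(f"{ins.numt.id}  {nu.start:>7}-{nu.end:<7} {nu.strand}  "
          f"chrM:{mt.start}-{mt.end} {mt.strand}  {ins.t0:5.2f}  {isotypes}")

# Each row is one insertion: its nuclear coordinates, the mitochondrial
# segment it descends from (the synteny key used for validation), its age
# in simulation time units, and the tRNA genes it carries as lookalikes.
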