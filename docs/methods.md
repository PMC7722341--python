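# Methods

This note documents the models, parameters, numerical choices and known
limitations of `nimtscan`, module by module.

## Coordinate and sequence conventions

All internal coordinates are 0-based, half-open (BED convention);
GFF3, tRNAscan-SE tables, Infernal tblout and wiggle input are converted
at the parsing boundary.  Sequences are DNA-level uppercase with U
mapped to T on input, so RNA-derived references and genomic sequence
compare directly.  Strand `-` on a numtDNA's mitochondrial source means
the nuclear copy is the reverse complement of the source region.

## The numtDNA evolution model (simulator)

The simulator is the package's source of ground-truth data.  Its model:

- A mitochondrial template genome (by default a synthetic ~3.6 kb
  sequence carrying one random cloverleaf-constrained tRNA gene per each
  of the 22 mitochondrial isotypes, the second serine isoacceptor
  D-armless) is the "primordial" state at time `t_max` before the
  present.  The mitochondrial lineage evolves to the present under
  Jukes–Cantor (JC69) substitutions at rate `sn`; per site the
  substitution probability over rate×time λt is
  p = (3/4)(1 − e^(−4λt/3)), with the replacement base uniform over the
  three alternatives.
- Each of `n_insertions` insertions copies a contiguous template segment
  (length uniform in `insertion_length_range`, orientation random) from
  the mitochondrial state at its insertion time t0 into a random nuclear
  background.  Insertion ages are t0 ~ Uniform(0, t_max] — the age
  distribution is a modeling choice, not an empirical claim; a
  `fixed_insertion_time` override supports calibration runs at one age.
  Insertion positions are uniform with a guaranteed minimum spacing so
  host genes never collide.
- After insertion, flank positions evolve at the neutral nuclear rate
  `sp` and MTL positions (tRNA genes ≥50% contained in the segment) at
  `st`; loci flagged functional evolve at `functional_factor × st`.
  Exactly `round(functional_fraction × n_loci)` loci are flagged.
- A fraction `intronic_fraction` of insertions is wrapped in a simulated
  two-exon host gene whose single intron contains the whole numtDNA; the
  gene strand is antisense with probability `antisense_prob`, so MTLs in
  hosted insertions become nimtRNAs, roughly half of them antisense.
- Parameters implying expected per-site divergence
  (sn + max(sp, st))·t_max ≥ 0.75 are refused (JC saturation).

Defaults: `sn = 0.02`, `sp = st = 0.1`, `t_max = 2`,
`functional_factor = 0.2`, `functional_fraction = 0.1`,
`intronic_fraction = 0.4` (close to the observed intronic share of
annotated MTL sets), `antisense_prob = 0.5`.  With these values mean
flank divergence is ~0.12, comfortably below saturation.

What the simulator does **not** emulate: indels (divergences are pure
substitution processes, so the alignment-based divergence reduces to a
Hamming proportion), rate heterogeneity along the sequence, numtDNA
truncation after insertion, nested or overlapping insertions,
multi-species orthology, and realistic nuclear background composition
(the background is i.i.d. uniform).  Tests passing on simulated data
therefore certify the statistical machinery, not performance on real
genomes with repeats and assembly artifacts.

Binding-site simulation: every RBP receives sites over nimtRNA loci on
the nimtRNA's own strand at coverage density `base_density`
(default 0.05) — multiplied by `fold` for RBPs declared enriched — plus
background sites over the intron territory (nimtRNA bases excluded) on
the intron strand.  Site placement is Poisson; realized coverage
densities are recorded in the truth object.  Because coverage is a
union of possibly overlapping sites, the realized density ratio is
compressed below the nominal `fold` at non-dilute densities; recovery is
therefore judged against the realized ratio.

## Detection

The built-in detector exists so the pipeline runs at desk scale without
external tools.  For each reference and strand, windows of
`len(ref) + max(20, len(ref)/2)` with step `len(ref)/2` are pre-filtered
by shared 8-mers (≥1 shared k-mer keeps the window; at 30% divergence
the chance of losing a true locus is ~3%) and aligned semi-globally
(reference-global, target-local) with match +1, mismatch −1, gap open
−3, gap extend −1.  The composite score adds λ = 5 times the fraction
of reference base pairs whose aligned candidate columns still form a
Watson–Crick or G–U pair.  The default cutoff `min_score = 32` was
calibrated on simulated data: true loci score ≥ ~36 up to ~25%
divergence while cross-isotype and reverse-complement shadows of other
tRNA genes stay ≤ ~30.

Best-hit merging clusters same-strand hits by single-linkage ≥1 bp
overlap and keeps the highest score per cluster (ties: longer, then
leftmost, then lexicographically first isotype).  Scores are never
compared across tools; per-tool survivor sets are combined later by
taking the union of validated true positives.

Context assignment: exon overlap (any transcript) beats intron
containment — a hit crossing an exon boundary is not "in an intron";
a hit fully inside an intron is intronic (a nimtRNA) and records its
host gene and antisense status; anything unassignable is intergenic.
Hit strand is ignored for overlap testing.

## Synteny validation

A mitochondrial tRNA gene contributes an expected copy to a numtDNA iff
≥50% of its length lies within the source interval (the threshold is a
parameter; the choice of how to count edge-truncated genes is otherwise
arbitrary).  Truncated copies are clipped to the source before
projection.  Projection is affine, reversed for minus-strand sources;
order indices follow nuclear coordinate order.  Sources spanning the
circular mitochondrial origin must be supplied pre-split — the tool
validates rather than guesses.

Hits are matched greedily in nuclear coordinate order to unmatched
expected copies of the containing numtDNA, requiring isotype equality
and ≥1 bp overlap with the projection, and requiring order indices to
increase (a hit that only matches an already-passed copy is demoted to
FP with reason `out_of_order`).  Strand is deliberately not required to
match: antisense lookalikes are bona fide findings.  Unmatched expected
copies are FNs; hits outside every numtDNA, or inside tRNA-free
numtDNAs, are FPs.

## Conservation test

Divergence is unit-cost edit distance divided by the longer sequence's
length.  This denominator (rather than the length of one particular
optimal alignment) keeps the measure symmetric — co-optimal global
alignments can differ in length, so "alignment length" is not
well-defined — stays within [0, 1], and equals the Hamming proportion in
the indel-free regime the simulator produces.  Edit distances are
computed with edlib.

d_p is computed once per numtDNA on the flank with all matched MTL
intervals masked out of both the nuclear copy and the extant source, so
the tested signal cannot leak into its own baseline (`mask_mtls=False`
gives the unmasked sensitivity mode).  Points with flank ≤ 50 nt are
dropped to avoid over-weighting short, noisy flanks.  d_t compares the
MTL to the extant tRNA clipped to the region the numtDNA actually
carries.

The regression is OLS of d_t on d_p with intercept (orientation recorded
in the fit metadata so plots can use either axis convention).  Cook's
distance D_i = e_i²·h_ii / (p·s²·(1−h_ii)²) with p = 2 comes from
statsmodels' influence diagnostics; a point is flagged iff
D_i > k·mean(D) (default k = 3) **and** its residual is negative — the
direction in which the MTL is more conserved than predicted.  The
one-sided rule reflects that only slower-than-expected evolution is
evidence of stabilizing selection.

Statistical power of this flag rule is intrinsically limited: with a
contaminated sample the outliers' own Cook's distances inflate the mean,
so with ages uniform from zero only loci older than roughly a third of
the age range can exceed 3× the mean even in the noise-free limit, and
the per-locus sampling noise of ~70-nt divergences (sd ≈ 0.05) lowers
recall further.  At the default rates, recall of truly functional loci
is ~0.2 while the false-flag rate stays ~0.02; the flagged set is a
high-confidence, not exhaustive, list.  This matches how the statistic
behaves on real data, where flagged loci are "the more extreme
outliers".

Per-base conservation scores (PhyloP-style wiggle tracks) are averaged
per feature and per flank; unscored bases are excluded rather than
zero-imputed, because zero is a meaningful score value in such tracks.

## Structure analysis

Cloverleaf models are parsed from dot-bracket strings: the helix chain
closing the molecule is the acceptor stem; the helices branching off the
central multiloop are, 5'→3', the D-arm, anticodon arm and T-arm.  A
structure with only two inner helices is parsed as D-armless (the
configuration known from mitochondrial tRNAs); with more than three
inner helices parsing fails.  Pair tables must be balanced and
pseudoknot-free.

Classification of a candidate against its reference uses a unit-cost
global alignment whose traceback prefers substitutions over indels
(written in-house because library tracebacks do not expose this
tie-break; equal-length sequences therefore always align
column-to-column).  Per differing column: unpaired → `loop`; paired
with candidate bases forming WC → `compensatory`; forming G-U →
`wobble_shift` (kept distinct from compensatory whether the reference
pair was WC or already wobble, so the ambiguity of single-partner
changes is externalized rather than collapsed); unpairable →
`disruptive`; gap columns → `deletion`/`insertion`.  The
structure-conservation score is the fraction of reference pairs still
formed (WC or wobble) by the aligned candidate bases; pairs with a
gapped partner count as lost.

An arm is reported deleted when ≥60% (configurable) of its reference
positions align to gaps.  Reverse-complement analysis mirrors the pair
table, (i, j) → (L−1−j, L−1−i): WC pairs survive (complementation swaps
the partners), G-U maps to A-C and is counted lost.

Consensus across nimtRNAs of one isotype is expressed as per-column
class frequencies from pairwise classifications; no simultaneous
fold-and-align is attempted.

## RBP enrichment

Coverage is a strict same-strand union (duplicate and overlapping sites
never double-count).  The background territory is the merged intron
union with nimtRNA bases excluded by default (an inclusive mode exists),
so the tested signal is not part of its own baseline.  Fold = nimtRNA
coverage density / background density; the enriched flag requires
fold > 2 strictly.  RBPs with zero background coverage are reported with
fold NaN and never flagged.  Multiple samples per RBP are reported both
pooled and per sample.  No multiple-testing correction is applied — the
statistic is a fold threshold, not a p-value.

## Pipeline and determinism

`run_all` executes simulate → detect (numtDNA-based and genome-based
strategies) → validate → conservation → structure → enrichment and
writes one TSV per stage plus a summary; every table carries a header
with the package version, a config digest and the master seed.
Per-stage random streams are children of the master seed
(numpy `SeedSequence.spawn`), so outputs are byte-identical across
reruns and stages can be re-run in isolation.  Floats in tables are
rounded to fixed precision for stable text output.

Default problem sizes (tens of insertions, tens of kilobases) keep a
full pipeline run in seconds; the statistical checks in the test suite
use hundreds of replicates or ~100-point regressions, sizes at which
the asserted properties concentrate.

## Known limitations

- The built-in detector is a homology scanner, not a covariance-model
  search; on real genomes dedicated tools (tRNAscan-SE, Infernal) should
  provide the hits, which the parsers ingest.
- Circular-origin-spanning numtDNA sources must be pre-split.
- The conservation test assumes one shared insertion age per numtDNA
  and substitution-only divergence; heavy indel activity would bias d_t
  and d_p differently.
- Wiggle ingestion is text-only (no bigWig), and liftover between
  assemblies is out of scope.
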