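"""MTL candidate detection, best-hit merging, and context assignment.

The built-in detector is a structure-aware homology scanner for
desk-scale runs: each of the 22 mitochondrial tRNA references is aligned
semi-globally (reference-global, target-local) against sliding windows of
the target sequence on both strands, and the alignment score is augmented
with a term rewarding candidate columns that still form the reference's
cloverleaf base pairs.  External tool output (tRNAscan-SE, Infernal) is
consumed through the io_formats parsers and unified here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import Align
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, MtlHit, RawHit, SequenceRecord, revcomp
from .structure import CloverleafModel, _can_pair, parse_cloverleaf

# Built-in detector scoring (recorded defaults): match +1, mismatch -1,
# gap open -3, gap extend -1; structure bonus weight lambda = 5 applied to
# the fraction of reference pairs preserved in the candidate columns.
MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -3.0
GAP_EXTEND = -1.0
STRUCTURE_LAMBDA = 5.0
# Calibrated on simulated data: true lookalike loci score >= ~36 up to
# ~25% divergence, while cross-isotype / reverse-complement shadows of
# other tRNA genes stay <= ~30.
DEFAULT_MIN_SCORE = 32.0


@dataclass(frozen=True)
class TrnaReference:
    """A reference mitochondrial tRNA with its cloverleaf structure."""

    isotype: str
    model: CloverleafModel

    @classmethod
    def from_strings(cls, isotype: str, sequence: str, structure: str) -> "TrnaReference":
        return cls(isotype, parse_cloverleaf(sequence, structure))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps in the query track (target overhangs align to gaps):
    # reference-global, target-local
    aligner.end_deletion_score = 0.0
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _structure_fraction(ref: CloverleafModel, cand: str,
                        ref_to_cand: dict[int, int]) -> float:
    pairs = ref.pairs
    if not pairs:
        return 1.0
    ok = 0
    for i, j in pairs:
        ci, cj = ref_to_cand.get(i), ref_to_cand.get(j)
        if ci is not None and cj is not None and _can_pair(cand[ci], cand[cj]):
            ok += 1
    return ok / len(pairs)


def _scan_strand(seq: str, ref: TrnaReference, aligner, min_score: float,
                 prefilter_k: int, prefilter_min: int) -> list[tuple[int, int, float, str]]:
    """Hits on the forward orientation of ``seq``: (start, end, score, subseq)."""
    rseq = ref.model.sequence
    L = len(rseq)
    win = L + max(20, L // 2)
    step = max(10, L // 2)
    ref_kmers = _kmer_set(rseq, prefilter_k)
    hits = []
    n = len(seq)
    pos = 0
    while pos < n:
        window = seq[pos:pos + win]
        if len(window) < max(10, L // 2):
            break
        shared = sum(1 for i in range(len(window) - prefilter_k + 1)
                     if window[i:i + prefilter_k] in ref_kmers)
        if shared >= prefilter_min:
            alns = aligner.align(window, rseq)
            aln = alns[0]
            blocks_t, blocks_q = aln.aligned
            ref_to_cand: dict[int, int] = {}
            t0 = t1 = None
            for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
                for k in range(te - ts):
                    ref_to_cand[qs + k] = ts + k
                t0 = ts if t0 is None else min(t0, ts)
                t1 = te if t1 is None else max(t1, te)
            if t0 is None:
                pos += step
                continue
            frac = _structure_fraction(ref.model, window, ref_to_cand)
            composite = aln.score + STRUCTURE_LAMBDA * frac
            if composite >= min_score:
                hits.append((pos + t0, pos + t1, composite, window[t0:t1]))
        pos += step
    return hits


def builtin_scan(
    nuclear: SequenceRecord,
    references: Sequence[TrnaReference],
    min_score: float = DEFAULT_MIN_SCORE,
    regions: Optional[Sequence[GenomicInterval]] = None,
    prefilter_k: int = 8,
    prefilter_min: int = 1,
) -> list[MtlHit]:
    """Scan a nuclear sequence for tRNA-lookalikes on both strands.

    ``regions`` restricts the scan to sub-intervals of the sequence (the
    numtDNA-based strategy); by default the whole sequence is scanned
    (the genome-based strategy).  Overlapping window duplicates are
    reduced to the best-scoring hit per locus and strand.
    """
    for ref in references:
        if not (20 <= len(ref.model.sequence) <= 120):
            raise ValueError(f"reference {ref.isotype}: implausible length")
    aligner = _make_aligner()
    if regions is None:
        regions = [GenomicInterval(nuclear.id, 0, len(nuclear.sequence), ".")]
    raw: list[MtlHit] = []
    for region in regions:
        sub = nuclear.sequence[region.start:region.end]
        for ref in references:
            for strand in ("+", "-"):
                target = sub if strand == "+" else revcomp(sub)
                for s, e, score, subseq in _scan_strand(
                        target, ref, aligner, min_score, prefilter_k, prefilter_min):
                    if strand == "+":
                        gs, ge = region.start + s, region.start + e
                    else:
                        gs, ge = region.start + len(sub) - e, region.start + len(sub) - s
                    raw.append(MtlHit(
                        GenomicInterval(nuclear.id, gs, ge, strand),
                        ref.isotype, score, "builtin", aligned_sequence=subseq))
    return merge_best_hit(raw)


# ---------------------------------------------------------------------------
# Best-hit merging

def merge_best_hit(hits: Sequence[MtlHit]) -> list[MtlHit]:
    """One hit per locus: cluster same-strand overlapping hits, keep the best.

    Clusters are single-linkage components under >=1 bp same-strand
    overlap.  Within a cluster the highest score wins; ties break toward
    the longer, then leftmost, then lexicographically first isotype.
    Idempotent; the survivors are pairwise non-overlapping per strand.
    """
    by_key: dict[tuple[str, str], list[MtlHit]] = {}
    for h in hits:
        by_key.setdefault((h.interval.chrom, h.interval.strand), []).append(h)
    out: list[MtlHit] = []
    for key, group in by_key.items():
        group.sort(key=lambda h: (h.interval.start, h.interval.end))
        cluster: list[MtlHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.interval.start >= cluster_end:
                out.append(_best_of(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.interval.end)
        if cluster:
            out.append(_best_of(cluster))
    out.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return out


def _best_of(cluster: list[MtlHit]) -> MtlHit:
    return max(cluster, key=lambda h: (h.score, h.interval.length,
                                       -h.interval.start,
                                       tuple(-ord(c) for c in h.isotype)))


def raw_to_mtl(hits: Iterable[RawHit]) -> list[MtlHit]:
    """Lift tool RawHits to MtlHits (no alignment, context unassigned)."""
    return [MtlHit(h.interval, h.isotype, h.score, h.tool) for h in hits]


# ---------------------------------------------------------------------------
# Transcriptional context

def assign_context(hits: Sequence[MtlHit],
                   transcripts: Sequence[GeneModel]) -> list[MtlHit]:
    """Classify each hit as exonic, intronic (nimtRNA) or intergenic.

    Exon overlap (any transcript) takes precedence; otherwise a hit fully
    inside an intron is intronic, carrying the host gene and whether it
    is antisense to it; otherwise intergenic.  Overlap testing ignores
    the hit's strand.
    """
    exon_trees: dict[str, IntervalTree] = {}
    intron_trees: dict[str, IntervalTree] = {}
    for gm in transcripts:
        et = exon_trees.setdefault(gm.chrom, IntervalTree())
        for s, e in gm.exons:
            et.addi(s, e, gm)
        it = intron_trees.setdefault(gm.chrom, IntervalTree())
        for s, e in gm.introns():
            it.addi(s, e, gm)
    out = []
    for h in hits:
        iv = h.interval
        if exon_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            out.append(h.with_context("exonic"))
            continue
        containing = [t.data for t in
                      intron_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
                      if t.begin <= iv.start and iv.end <= t.end]
        if containing:
            gm = sorted(containing, key=lambda g: g.gene_id)[0]
            out.append(h.with_context("intronic", gm.gene_id,
                                      antisense=(iv.strand != gm.strand)))
        else:
            out.append(h.with_context("intergenic"))
    return out
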