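"""Synteny-based validation of MTL hits against numtDNA records.

Every numtDNA record carries the mitochondrial interval it was copied
from, so the mitochondrial tRNA genes expected inside it — their number,
types and order — can be reconstructed and projected into nuclear
coordinates.  A hit is a true positive when it falls inside a numtDNA
and matches an expected copy in isotype, position and order; hits inside
tRNA-free numtDNAs and hits outside any numtDNA are false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval, MtlHit, NumtRecord
from .numtsim import TrnaGene


@dataclass(frozen=True)
class ExpectedCopy:
    """A mitochondrial tRNA copy expected within one numtDNA."""

    numt_id: str
    isotype: str
    order_index: int
    projected: GenomicInterval  # nuclear coordinates
    mt_gene: GenomicInterval


@dataclass(frozen=True)
class ValidatedMtl:
    hit: MtlHit
    status: str          # TP | FP
    reason: str          # matched | outside_numt | no_expected_match | out_of_order
    numt_id: Optional[str] = None
    expected: Optional[ExpectedCopy] = None


@dataclass(frozen=True)
class ValidationSummary:
    tp: int
    fp: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def expected_copies(
    numts: Sequence[NumtRecord],
    mito_trnas: Sequence[TrnaGene],
    min_containment: float = 0.5,
    mito_length: Optional[int] = None,
) -> list[ExpectedCopy]:
    """Project mito tRNA genes into each numtDNA's nuclear coordinates.

    A gene contributes a copy iff at least ``min_containment`` of its
    length lies within the numt's mitochondrial source.  Projection is by
    affine offset, reversed for minus-strand sources; truncated genes are
    clipped to the source.  ``order_index`` follows nuclear coordinate
    order within each numtDNA.  Sources spanning the circular origin must
    be supplied pre-split; a source beyond ``mito_length`` is an error.
    """
    out: list[ExpectedCopy] = []
    for numt in numts:
        src = numt.mt_source
        if mito_length is not None and src.end > mito_length:
            raise ValueError(f"{numt.id}: mt_source exceeds mitochondrial genome "
                             f"length {mito_length} (circular-origin sources must "
                             "be pre-split)")
        copies = []
        for gene in mito_trnas:
            ovl = max(0, min(src.end, gene.end) - max(src.start, gene.start))
            if ovl < min_containment * gene.length or ovl == 0:
                continue
            gs, ge = max(src.start, gene.start), min(src.end, gene.end)
            if src.strand == "+":
                ns = numt.nuclear.start + (gs - src.start)
                ne = numt.nuclear.start + (ge - src.start)
                strand = "+"
            else:
                ns = numt.nuclear.start + (src.end - ge)
                ne = numt.nuclear.start + (src.end - gs)
                strand = "-"
            copies.append((GenomicInterval(numt.nuclear.chrom, ns, ne, strand), gene))
        copies.sort(key=lambda c: c[0].start)
        for k, (proj, gene) in enumerate(copies):
            out.append(ExpectedCopy(numt.id, gene.isotype, k, proj, gene.interval))
    return out


def classify_hits(
    hits: Sequence[MtlHit],
    expected: Sequence[ExpectedCopy],
    numts: Sequence[NumtRecord],
) -> tuple[list[ValidatedMtl], ValidationSummary]:
    """Match hits to expected copies; label TP/FP and summarize.

    Hits are processed in nuclear coordinate order and matched greedily
    to unmatched expected copies of the containing numtDNA, requiring
    isotype equality and >=1 bp overlap with the projected interval.
    Strand is not required to match (antisense lookalikes are bona fide).
    A hit overlapping a lower order_index than one already matched in its
    numtDNA violates the synteny order and is demoted to FP.  Unmatched
    expected copies are FNs.
    """
    tree: dict[str, IntervalTree] = {}
    for numt in numts:
        tree.setdefault(numt.nuclear.chrom, IntervalTree()).addi(
            numt.nuclear.start, numt.nuclear.end, numt)
    by_numt: dict[str, list[ExpectedCopy]] = {}
    for ec in expected:
        by_numt.setdefault(ec.numt_id, []).append(ec)
    matched: set[tuple[str, int]] = set()
    last_order: dict[str, int] = {}
    validated: list[ValidatedMtl] = []
    for h in sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start,
                                         h.interval.end, h.interval.strand)):
        iv = h.interval
        overlapping = [t.data for t in
                       tree.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)]
        if not overlapping:
            validated.append(ValidatedMtl(h, "FP", "outside_numt"))
            continue
        numt = max(overlapping, key=lambda nu: iv.overlap_length(nu.nuclear))
        cands = [ec for ec in by_numt.get(numt.id, ())
                 if (ec.numt_id, ec.order_index) not in matched
                 and ec.isotype == h.isotype
                 and iv.overlap_length(ec.projected) >= 1]
        in_order = [ec for ec in cands
                    if ec.order_index > last_order.get(numt.id, -1)]
        if in_order:
            ec = min(in_order, key=lambda e: e.order_index)
            matched.add((ec.numt_id, ec.order_index))
            last_order[numt.id] = ec.order_index
            validated.append(ValidatedMtl(h, "TP", "matched", numt.id, ec))
        elif cands:
            validated.append(ValidatedMtl(h, "FP", "out_of_order", numt.id))
        else:
            validated.append(ValidatedMtl(h, "FP", "no_expected_match", numt.id))
    tp = sum(1 for v in validated if v.status == "TP")
    fp = sum(1 for v in validated if v.status == "FP")
    fn = len(expected) - tp
    return validated, ValidationSummary(tp, fp, fn)


def union_tp_set(validated_sets: Sequence[Sequence[ValidatedMtl]]) -> list[ValidatedMtl]:
    """The final MTL set: all TPs from any tool/strategy, deduplicated.

    TPs from different runs claiming the same expected copy are reduced
    to the highest-scoring hit.
    """
    best: dict[tuple[str, int], ValidatedMtl] = {}
    for vs in validated_sets:
        for v in vs:
            if v.status != "TP" or v.expected is None:
                continue
            key = (v.expected.numt_id, v.expected.order_index)
            if key not in best or v.hit.score > best[key].hit.score:
                best[key] = v
    return [best[k] for k in sorted(best)]
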