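"""RBP binding-site enrichment over nimtRNA loci.

Binding intervals (eCLIP-style BED6) are intersected with nimtRNA loci on
the same strand; per-RBP coverage density over nimtRNA territory is
compared with the density over the intron background, and RBPs whose
density ratio exceeds 2 (strictly) are flagged enriched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .core import GeneModel, GenomicInterval


@dataclass(frozen=True)
class BindingSite:
    """One stranded binding interval of an RBP in one sample."""

    rbp: str
    interval: GenomicInterval
    sample: str = "pooled"

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError("binding sites must be stranded")


@dataclass(frozen=True)
class EnrichmentRecord:
    rbp: str
    sample: str
    covered_nimt_nt: int
    total_nimt_nt: int
    covered_intron_nt: int
    total_intron_nt: int

    @property
    def density_nimt(self) -> float:
        return self.covered_nimt_nt / self.total_nimt_nt

    @property
    def density_bg(self) -> float:
        return self.covered_intron_nt / self.total_intron_nt

    @property
    def fold(self) -> float:
        if self.covered_intron_nt == 0:
            return float("nan")
        return self.density_nimt / self.density_bg

    @property
    def enriched(self) -> bool:
        """Strictly more than 2-fold over the intron background."""
        f = self.fold
        return (not math.isnan(f)) and f > 2.0


def _merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _by_key(ivs: Iterable[GenomicInterval]) -> dict[tuple[str, str], list[tuple[int, int]]]:
    d: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for iv in ivs:
        d.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    return {k: _merge(v) for k, v in d.items()}


def merged_length(ivs: Iterable[GenomicInterval]) -> int:
    """Total length of the stranded union of intervals (no double counting)."""
    return sum(e - s for spans in _by_key(ivs).values() for s, e in spans)


def stranded_coverage(features: Iterable[GenomicInterval],
                      sites: Iterable[GenomicInterval]) -> int:
    """Bases of the feature union covered by >=1 same-strand site.

    Coverage is a union: duplicated or overlapping sites do not double
    count, and feature territory is merged per (chrom, strand) first.
    """
    feat = _by_key(features)
    site = _by_key(sites)
    covered = 0
    for key, fspans in feat.items():
        sspans = site.get(key)
        if not sspans:
            continue
        si = 0
        for fs, fe in fspans:
            while si < len(sspans) and sspans[si][1] <= fs:
                si += 1
            j = si
            while j < len(sspans) and sspans[j][0] < fe:
                covered += min(fe, sspans[j][1]) - max(fs, sspans[j][0])
                j += 1
    return covered


def intron_intervals(transcripts: Iterable[GeneModel]) -> list[GenomicInterval]:
    """Stranded intron intervals derived from transcript exon chains."""
    out = []
    for gm in transcripts:
        for s, e in gm.introns():
            out.append(GenomicInterval(gm.chrom, s, e, gm.strand))
    return out


def background_territory(introns: list[GenomicInterval],
                         nimts: list[GenomicInterval],
                         exclude_nimts: bool = True) -> list[GenomicInterval]:
    """Intron background, by default with nimtRNA bases subtracted.

    Subtraction is positional (both strands of an intron position are
    removed when any nimtRNA covers it), since the nimtRNA signal should
    not contaminate its own background regardless of orientation.
    """
    if not exclude_nimts:
        return list(introns)
    cut = _merge([(m.start, m.end) for m in nimts])
    out = []
    for iv in introns:
        pos = iv.start
        for s, e in cut:
            if e <= iv.start or s >= iv.end:
                continue
            if s > pos:
                out.append(GenomicInterval(iv.chrom, pos, s, iv.strand))
            pos = max(pos, e)
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end, iv.strand))
    return out


def enrichment(
    nimts: list[GenomicInterval],
    introns: list[GenomicInterval],
    sites: Iterable[BindingSite],
    exclude_nimts_from_background: bool = True,
    per_sample: bool = True,
) -> list[EnrichmentRecord]:
    """Per-RBP fold enrichment of binding density in nimtRNAs over introns.

    Always reports a pooled record per RBP (all samples unioned); when
    several samples are present and ``per_sample`` is set, per-sample
    records are reported as well.  RBPs with zero background coverage get
    fold NaN and are never flagged.
    """
    if not nimts:
        raise ValueError("no nimtRNA intervals supplied")
    bg = background_territory(introns, nimts, exclude_nimts_from_background)
    total_nimt = merged_length(nimts)
    total_bg = merged_length(bg)
    if total_nimt == 0 or total_bg == 0:
        raise ValueError("empty nimtRNA or intron territory")
    all_sites = list(sites)
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    samples_per_rbp: dict[str, set[str]] = {}
    for s in all_sites:
        groups.setdefault((s.rbp, "pooled"), []).append(s.interval)
        groups.setdefault((s.rbp, s.sample), []).append(s.interval)
        samples_per_rbp.setdefault(s.rbp, set()).add(s.sample)
    records = []
    for (rbp, sample), ivs in sorted(groups.items()):
        if sample != "pooled":
            if not per_sample or len(samples_per_rbp[rbp]) < 2:
                continue
        records.append(EnrichmentRecord(
            rbp, sample,
            stranded_coverage(nimts, ivs), total_nimt,
            stranded_coverage(bg, ivs), total_bg))
    return records


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "rbp": r.rbp, "sample": r.sample,
            "covered_nimt_nt": r.covered_nimt_nt, "total_nimt_nt": r.total_nimt_nt,
            "covered_intron_nt": r.covered_intron_nt, "total_intron_nt": r.total_intron_nt,
            "density_nimt": round(r.density_nimt, 6),
            "density_bg": round(r.density_bg, 6),
            "fold": round(r.fold, 6) if not math.isnan(r.fold) else float("nan"),
            "enriched": int(r.enriched),
        })
    return pd.DataFrame(rows)
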