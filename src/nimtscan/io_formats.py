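"""Readers and writers for the external formats the pipeline touches.

Everything 1-based (GFF3, tRNAscan-SE tables, Infernal tblout, wiggle) is
converted to the package-wide 0-based half-open convention here, at the
boundary.  Sequences are normalized to uppercase DNA (U mapped to T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import (
    GeneModel,
    GenomicInterval,
    MtlHit,
    NumtRecord,
    RawHit,
    SequenceRecord,
    normalize_isotype,
)


class ParseError(ValueError):
    """A malformed line in an external file; the message names the line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED6

@dataclass(frozen=True)
class Bed6Record:
    interval: GenomicInterval
    name: str
    score: float


def read_bed6(path) -> list[Bed6Record]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(parts)}")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[5])
                score = float(parts[4]) if parts[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(Bed6Record(iv, parts[3], score))
    return out


def write_bed6(records: Iterable[Bed6Record], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                     f"{r.name}\t{r.score:g}\t{r.interval.strand}\n")


# ---------------------------------------------------------------------------
# tRNAscan-SE v2 tabular output

def read_trnascan_table(path) -> list[RawHit]:
    """Parse tRNAscan-SE v2 tabular output into RawHits.

    Coordinates are 1-based inclusive; rows with begin > end are minus
    strand hits and are normalized to a forward 0-based half-open
    interval.  Rows with an unrecognizable tRNA type are reported via a
    warning and excluded.  No score filtering is applied here.
    """
    hits: list[RawHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split()
            # Header block: column-name lines and the dashed rule.
            if parts[0] in ("Sequence", "Name", "--------") or parts[0].startswith("---"):
                continue
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected >=9 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                begin, end = int(parts[2]), int(parts[3])
                score = float(parts[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                isotype = normalize_isotype(parts[4])
            except ValueError:
                warnings.warn(f"{path}:{lineno}: unknown isotype {parts[4]!r}, row rejected")
                continue
            if begin <= end:
                iv = GenomicInterval(chrom, begin - 1, end, "+")
            else:
                iv = GenomicInterval(chrom, end - 1, begin, "-")
            hits.append(RawHit(iv, isotype, score, "trnascan"))
    return hits


# ---------------------------------------------------------------------------
# Infernal tblout

def read_infernal_tblout(path) -> list[RawHit]:
    """Parse Infernal cmsearch/cmscan --tblout output into RawHits.

    The isotype is taken from the query (CM) name; 1-based inclusive
    seq-from/seq-to coordinates are normalized respecting the strand
    column.
    """
    hits: list[RawHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 15:
                raise ParseError(f"{path}:{lineno}: expected >=15 columns, got {len(parts)}")
            chrom, cm_name = parts[0], parts[2]
            try:
                seq_from, seq_to = int(parts[7]), int(parts[8])
                strand = parts[9]
                score = float(parts[14])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                isotype = normalize_isotype(cm_name)
            except ValueError:
                warnings.warn(f"{path}:{lineno}: unknown CM name {cm_name!r}, row rejected")
                continue
            lo, hi = min(seq_from, seq_to), max(seq_from, seq_to)
            iv = GenomicInterval(chrom, lo - 1, hi, strand)
            hits.append(RawHit(iv, isotype, score, "infernal"))
    return hits


# ---------------------------------------------------------------------------
# Wiggle (fixedStep / variableStep)

def read_wiggle(path) -> dict[str, dict[int, float]]:
    """Parse a wiggle track into a sparse per-base score map.

    Returns ``{chrom: {0-based position: score}}``.  Positions without a
    value are simply absent (no zero-filling): in conservation tracks a
    score of zero is meaningful and distinct from missing data.
    """
    scores: dict[str, dict[int, float]] = {}
    mode = None  # ("fixed", chrom, next_pos0, step, span) | ("variable", chrom, span)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                if "chrom" not in kv:
                    raise ParseError(f"{path}:{lineno}: declaration missing chrom")
                span = int(kv.get("span", 1))
                if span < 1:
                    raise ParseError(f"{path}:{lineno}: span must be >=1")
                if line.startswith("fixedStep"):
                    if "start" not in kv:
                        raise ParseError(f"{path}:{lineno}: fixedStep missing start")
                    step = int(kv.get("step", 1))
                    if span > step:
                        raise ParseError(f"{path}:{lineno}: span {span} exceeds step {step}")
                    mode = ["fixed", kv["chrom"], int(kv["start"]) - 1, step, span]
                else:
                    mode = ["variable", kv["chrom"], span]
                scores.setdefault(kv["chrom"], {})
                continue
            if mode is None:
                raise ParseError(f"{path}:{lineno}: data before any step declaration")
            if mode[0] == "fixed":
                _, chrom, pos, step, span = mode
                try:
                    val = float(line)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                for k in range(span):
                    scores[chrom][pos + k] = val
                mode[2] = pos + step
            else:
                _, chrom, span = mode
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: variableStep rows need 2 fields")
                try:
                    pos = int(parts[0]) - 1
                    val = float(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                for k in range(span):
                    scores[chrom][pos + k] = val
    return scores


# ---------------------------------------------------------------------------
# GFF3 transcripts

def write_gff3_transcripts(models: Iterable[GeneModel], path) -> None:
    """Write gene/mRNA/exon features, 1-based inclusive per GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            s, e = gm.span
            fh.write(f"{gm.chrom}\tnimtscan\tgene\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                     f"ID=gene:{gm.gene_id}\n")
            tid = f"transcript:{gm.gene_id}.t1"
            fh.write(f"{gm.chrom}\tnimtscan\tmRNA\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                     f"ID={tid};Parent=gene:{gm.gene_id}\n")
            for i, (xs, xe) in enumerate(gm.exons, 1):
                fh.write(f"{gm.chrom}\tnimtscan\texon\t{xs + 1}\t{xe}\t.\t{gm.strand}\t.\t"
                         f"ID={tid}.exon{i};Parent={tid}\n")


def read_gff3_transcripts(path) -> list[GeneModel]:
    """Read transcripts (one GeneModel per mRNA/transcript) from GFF3.

    Exons are grouped by their Parent transcript; the transcript's gene is
    recovered from its own Parent when present, else the transcript ID is
    used as the gene identifier.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    models = []
    tx_types = [t for t in db.featuretypes() if t in ("mRNA", "transcript")]
    for tt in tx_types:
        for tx in db.features_of_type(tt):
            parents = list(db.parents(tx, level=1))
            gene_id = parents[0].id if parents else tx.id
            gene_id = gene_id.split(":", 1)[-1]
            exons = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="exon"))
            if not exons:
                continue
            models.append(GeneModel(gene_id, tx.seqid, tx.strand, tuple(exons)))
    models.sort(key=lambda g: (g.chrom, g.span))
    return models


# ---------------------------------------------------------------------------
# numtDNA records (BED-like TSV with mitochondrial source coordinates)

NUMT_COLUMNS = ["chrom", "start", "end", "strand",
                "mt_start", "mt_end", "mt_strand", "numt_id"]


def write_numt_table(numts: Iterable[NumtRecord], path) -> None:
    rows = [{"chrom": n.nuclear.chrom, "start": n.nuclear.start, "end": n.nuclear.end,
             "strand": n.nuclear.strand, "mt_start": n.mt_source.start,
             "mt_end": n.mt_source.end, "mt_strand": n.mt_source.strand,
             "numt_id": n.id} for n in numts]
    pd.DataFrame(rows, columns=NUMT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_numt_table(path, mito_chrom: str = "chrM") -> list[NumtRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(NUMT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(NumtRecord(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand)),
            GenomicInterval(mito_chrom, int(row.mt_start), int(row.mt_end), str(row.mt_strand)),
            str(row.numt_id)))
    return out


# ---------------------------------------------------------------------------
# MTL hit tables

HIT_COLUMNS = ["chrom", "start", "end", "strand", "isotype", "score", "tool",
               "context", "host_gene", "antisense"]


def write_hit_table(hits: Iterable[MtlHit], path) -> None:
    rows = [{"chrom": h.interval.chrom, "start": h.interval.start,
             "end": h.interval.end, "strand": h.interval.strand,
             "isotype": h.isotype, "score": round(h.score, 6), "tool": h.tool,
             "context": h.context, "host_gene": h.host_gene or ".",
             "antisense": int(h.antisense_to_host)} for h in hits]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> list[MtlHit]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        host = None if str(row.host_gene) == "." else str(row.host_gene)
        out.append(MtlHit(
            GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand)),
            str(row.isotype), float(row.score), str(row.tool),
            context=str(row.context), host_gene=host,
            antisense_to_host=bool(row.antisense)))
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Uniform TSV report writer (UTF-8, header row, tab-separated)."""
    df.to_csv(path, sep="\t", index=False)
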