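"""Core domain types shared across the pipeline.

All genomic coordinates in this package are 0-based, half-open (BED
convention).  Formats that use 1-based inclusive coordinates (GFF3,
tRNAscan-SE tables, Infernal tblout, wiggle) are converted at the parsing
boundary and never leak their conventions inward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

# The 22 mitochondrially encoded tRNA families.  Serine and leucine each
# have two isoacceptor genes, conventionally indexed 1/2.
MT_TRNA_ISOTYPES: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu1", "Leu2", "Lys", "Met", "Phe", "Pro", "Ser1", "Ser2", "Thr",
    "Trp", "Tyr", "Val",
)

_ONE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
    "F": "Phe", "P": "Pro", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

VALID_STRANDS = ("+", "-", ".")

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_isotype(name: str) -> str:
    """Map a tool-reported tRNA identity to one of the 22 mt families.

    Accepts three-letter codes (``Tyr``), serine/leucine with index
    (``Ser2``, ``SerUGA`` is not supported), one-letter amino-acid codes,
    and prefixed covariance-model names such as ``mt-tRNA-Gln`` or
    ``trnL1``.  Raises ``ValueError`` for anything unrecognizable.
    """
    raw = name.strip()
    s = raw
    for prefix in ("mt-tRNA-", "mt-trna-", "mtRNA-", "tRNA-", "trna-", "trn", "mt-"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    s = s.strip("-_")
    cand = s[:1].upper() + s[1:].lower() if len(s) > 1 else s.upper()
    if cand in MT_TRNA_ISOTYPES:
        return cand
    # Ser/Leu without index are ambiguous between the two genes; reject.
    if len(s) == 1 and s.upper() in _ONE_LETTER:
        return _ONE_LETTER[s.upper()]
    if len(s) == 2 and s[0].upper() in "SL" and s[1] in "12":
        base = {"S": "Ser", "L": "Leu"}[s[0].upper()]
        return base + s[1]
    raise ValueError(f"unknown mitochondrial tRNA isotype: {name!r}")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T; reject characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located feature: 0-based half-open [start, end) on a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start},{self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, normalized to uppercase ACGTN."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        s = self.sequence[start:end]
        return revcomp(s) if strand == "-" else s


@dataclass(frozen=True)
class RawHit:
    """A candidate tRNA-lookalike locus as reported by a search tool."""

    interval: GenomicInterval
    isotype: str
    score: float
    tool: str  # trnascan | infernal | builtin

    def __post_init__(self):
        if self.isotype not in MT_TRNA_ISOTYPES:
            raise ValueError(f"not a mitochondrial tRNA isotype: {self.isotype!r}")
        if self.tool not in ("trnascan", "infernal", "builtin"):
            raise ValueError(f"unknown tool: {self.tool!r}")


@dataclass(frozen=True)
class MtlHit:
    """A detected MTL locus with alignment and transcriptional context.

    ``context`` is one of intronic / exonic / intergenic / unassigned;
    intronic MTLs are the nimtRNAs and always carry a ``host_gene``.
    """

    interval: GenomicInterval
    isotype: str
    score: float
    tool: str
    aligned_sequence: str = ""
    context: str = "unassigned"
    host_gene: Optional[str] = None
    antisense_to_host: bool = False

    def __post_init__(self):
        if self.context not in ("intronic", "exonic", "intergenic", "unassigned"):
            raise ValueError(f"invalid context: {self.context!r}")
        if self.context == "intronic" and self.host_gene is None:
            raise ValueError("intronic hit requires host_gene")

    def with_context(self, context: str, host_gene: Optional[str] = None,
                     antisense: bool = False) -> "MtlHit":
        return replace(self, context=context, host_gene=host_gene,
                       antisense_to_host=antisense)


@dataclass(frozen=True)
class NumtRecord:
    """A nuclear insertion of mitochondrial DNA with its traceable source.

    ``mt_source`` is the interval on the mitochondrial genome the nuclear
    segment was copied from; its strand records the orientation of the
    copy (``-`` means the nuclear segment is the reverse complement of the
    mitochondrial source).  This source interval is the synteny key used
    for validation.
    """

    nuclear: GenomicInterval
    mt_source: GenomicInterval
    id: str


@dataclass(frozen=True)
class GeneModel:
    """A transcript: ordered, non-overlapping exons on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: transcript without exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: unsorted/overlapping exons")
            prev_end = e
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Within-transcript gaps between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out
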