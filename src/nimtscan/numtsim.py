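"""Synthetic numtDNA evolution simulator.

The generator emulates the history of nuclear insertions of mitochondrial
DNA (numtDNA): an ancestral mitochondrial genome evolves toward the
present under Jukes-Cantor substitutions at rate ``sn``; at random times
``t0`` contiguous mitochondrial segments are copied into a random nuclear
background, after which flank positions evolve neutrally at rate ``sp``
while embedded tRNA-lookalike (MTL) positions evolve at rate ``st`` —
reduced by ``functional_factor`` for loci flagged as functional, modeling
stabilizing selection.  The expected divergences then follow the linear
forms dt = (sn + st)·t0 (MTL vs extant mitochondrial tRNA) and
dp = (sn + sp)·t0 (flanking numtDNA vs extant mitochondrial source) in
the small-rate regime.

A configurable fraction of insertions land inside introns of simulated
two-exon host genes (their MTLs become nimtRNAs), with random gene strand
so that roughly half of the nimtRNAs are antisense to their host.  All
ground truth (insertion times, loci, functional flags, realized
substitution counts) is recorded for downstream validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import GeneModel, GenomicInterval, NumtRecord, SequenceRecord, revcomp
from .structure import parse_cloverleaf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {ord(b): i for i, b in enumerate("ACGT")}

NUCLEAR_CHROM = "chr1"
MITO_CHROM = "chrM"


# ---------------------------------------------------------------------------
# Mitochondrial template

@dataclass(frozen=True)
class TrnaGene:
    """An annotated tRNA gene on the mitochondrial template (always '+')."""

    isotype: str
    start: int
    end: int
    structure: str  # dot-bracket over the gene sequence

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(MITO_CHROM, self.start, self.end, "+")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MitoTemplate:
    """A mitochondrial genome sequence with its tRNA gene annotation."""

    genome: SequenceRecord
    genes: tuple[TrnaGene, ...]

    def gene_sequence(self, gene: TrnaGene) -> str:
        return self.genome.sequence[gene.start:gene.end]

    def references(self) -> list[tuple[str, str, str]]:
        """(isotype, sequence, structure) triples for the detector."""
        return [(g.isotype, self.gene_sequence(g), g.structure) for g in self.genes]


# Cloverleaf layout used for synthetic tRNA genes: 7 bp acceptor stem,
# 4 bp D stem + 8 nt loop, 5 bp anticodon stem + 7 nt loop, 4 nt variable
# region, 5 bp T stem + 7 nt loop, 72 nt total.
_CLOVERLEAF_DB = ("(((((((" + ".." + "((((" + "........" + "))))" + "."
                  + "(((((" + "......." + ")))))" + "...."
                  + "(((((" + "......." + ")))))" + ")))))))" + ".")
# D-armless layout (mirrors the D-armless mitochondrial serine tRNA).
_DARMLESS_DB = ("(((((((" + "......"
                + "(((((" + "......." + ")))))" + "...."
                + "(((((" + "......." + ")))))" + ")))))))" + ".")


def _random_structured_trna(structure: str, rng: np.random.Generator,
                            wobble_prob: float = 0.1) -> str:
    """Random sequence folding into ``structure``: WC stems (occasional G-U)."""
    model_pairs = parse_cloverleaf("A" * len(structure), structure).pairs
    seq = [""] * len(structure)
    paired = {i for p in model_pairs for i in p}
    wc = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
    gu = [("G", "T"), ("T", "G")]
    for i, j in model_pairs:
        pool = gu if rng.random() < wobble_prob else wc
        a, b = pool[rng.integers(len(pool))]
        seq[i], seq[j] = a, b
    for i in range(len(structure)):
        if i not in paired:
            seq[i] = "ACGT"[rng.integers(4)]
    return "".join(seq)


def default_mito_template(seed: int = 20_240_101) -> MitoTemplate:
    """Synthetic 22-gene mitochondrial template (~3.6 kb).

    A deterministic stand-in for a real mitochondrial genome: one
    synthetic tRNA gene per mitochondrial isotype (Ser2 D-armless),
    separated by random spacers.  Synthetic — the sequences are random
    subject to the cloverleaf constraint, not biological sequences.
    """
    from .core import MT_TRNA_ISOTYPES

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[TrnaGene] = []
    pos = 0
    for isotype in MT_TRNA_ISOTYPES:
        spacer_len = int(rng.integers(60, 120))
        spacer = "".join("ACGT"[k] for k in rng.integers(0, 4, spacer_len))
        parts.append(spacer)
        pos += spacer_len
        db = _DARMLESS_DB if isotype == "Ser2" else _CLOVERLEAF_DB
        seq = _random_structured_trna(db, rng)
        genes.append(TrnaGene(isotype, pos, pos + len(seq), db))
        parts.append(seq)
        pos += len(seq)
    tail = "".join("ACGT"[k] for k in rng.integers(0, 4, 80))
    parts.append(tail)
    return MitoTemplate(SequenceRecord(MITO_CHROM, "".join(parts)), tuple(genes))


# ---------------------------------------------------------------------------
# Parameters and truth containers

@dataclass
class EvolutionParams:
    """Rates and sizes governing the numtDNA evolution model.

    Rates are substitutions per site per unit time; ``t_max`` sets the
    span of insertion ages t0 ~ Uniform(0, t_max] (or all equal to
    ``fixed_insertion_time`` when given).  ``functional_factor`` scales
    ``st`` down for loci flagged functional; ``functional_fraction`` of
    MTL loci are so flagged.  ``intronic_fraction`` of insertions are
    wrapped in a simulated host gene (their MTLs become nimtRNAs), with
    gene strand chosen antisense with probability ``antisense_prob``.
    """

    sn: float = 0.02
    sp: float = 0.1
    st: Optional[float] = None  # defaults to sp (neutral MTL evolution)
    functional_factor: float = 0.2
    functional_fraction: float = 0.1
    t_max: float = 2.0
    n_insertions: int = 20
    insertion_length_range: tuple[int, int] = (300, 800)
    min_trnas_per_insertion: int = 0
    nuclear_length: int = 50_000
    intronic_fraction: float = 0.4
    antisense_prob: float = 0.5
    fixed_insertion_time: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.st is None:
            self.st = self.sp
        if min(self.sn, self.sp, self.st) < 0:
            raise ValueError("substitution rates must be non-negative")
        if not (0 < self.functional_factor <= 1):
            raise ValueError("functional_factor must be in (0, 1]")
        if not (0 <= self.functional_fraction <= 1):
            raise ValueError("functional_fraction must be in [0, 1]")
        if self.n_insertions < 1:
            raise ValueError("n_insertions must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        lo, hi = self.insertion_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid insertion_length_range")
        horizon = self.fixed_insertion_time if self.fixed_insertion_time is not None \
            else self.t_max
        if (self.sn + max(self.sp, self.st)) * horizon >= 0.75:
            raise ValueError(
                "expected per-site divergence >= 0.75: Jukes-Cantor saturated; "
                "reduce rates or t_max")


@dataclass
class TruthMtl:
    """Ground truth for one MTL locus created by an insertion."""

    mtl_id: str
    isotype: str
    nuclear: GenomicInterval  # strand = orientation relative to the mt gene
    mt_gene: GenomicInterval
    functional: bool
    subs: int  # realized substitutions within the locus since insertion
    host_gene: Optional[str] = None
    antisense_to_host: Optional[bool] = None

    @property
    def context(self) -> str:
        return "intronic" if self.host_gene else "intergenic"


@dataclass
class InsertionTruth:
    numt: NumtRecord
    t0: float
    mtls: list[TruthMtl]
    subs_flank: int
    flank_len: int


@dataclass
class SimulationTruth:
    """Everything the simulator knows: the oracle for downstream stages."""

    params: EvolutionParams
    template: MitoTemplate
    extant_mito: SequenceRecord
    nuclear: SequenceRecord
    insertions: list[InsertionTruth]
    transcripts: list[GeneModel]
    binding_truth: dict = field(default_factory=dict)

    @property
    def mtls(self) -> list[TruthMtl]:
        return [m for ins in self.insertions for m in ins.mtls]

    @property
    def nimtrnas(self) -> list[TruthMtl]:
        return [m for m in self.mtls if m.host_gene]

    def extant_mtrna(self, isotype: str) -> str:
        gene = next(g for g in self.template.genes if g.isotype == isotype)
        return self.extant_mito.sequence[gene.start:gene.end]


# ---------------------------------------------------------------------------
# Jukes-Cantor machinery

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def jc_evolve(arr: np.ndarray, rate: float, time: float,
              rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence under Jukes-Cantor for ``rate * time``.

    Each site substitutes with probability (3/4)(1 - exp(-4*rate*time/3)),
    the changed site drawing uniformly among the three other bases.
    """
    if rate * time == 0:
        return arr.copy()
    p_change = 0.75 * (1.0 - math.exp(-4.0 * rate * time / 3.0))
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < p_change)[0]
    if hit.size:
        idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, hit.size)
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def jc_expected_divergence(rate: float, time: float) -> float:
    """Closed-form expected proportion of differing sites under JC69."""
    return 0.75 * (1.0 - math.exp(-4.0 * rate * time / 3.0))


def evolve_with_indels(seq: str, sub_rate: float, indel_rate: float,
                       time: float, rng: np.random.Generator,
                       mean_indel_len: float = 2.0) -> str:
    """JC substitutions plus small indels (geometric lengths).

    A stress-test mode for the alignment-based divergence: indel events
    arrive at ``indel_rate`` per site, each deleting or inserting (1:1) a
    geometric-length tract (mean ``mean_indel_len``).  Truth divergences
    in the insertion model remain substitution-based; this utility is not
    wired into the coordinate bookkeeping of :func:`simulate`.
    """
    arr = jc_evolve(_encode(SequenceRecord("x", seq).sequence),
                    sub_rate, time, rng)
    n_events = rng.poisson(indel_rate * time * arr.size)
    p_geom = 1.0 / max(1.0, mean_indel_len)
    out = arr
    for _ in range(n_events):
        length = int(rng.geometric(p_geom))
        pos = int(rng.integers(0, max(1, out.size)))
        if rng.random() < 0.5 and out.size > length:
            out = np.concatenate([out[:pos], out[pos + length:]])
        else:
            out = np.concatenate([out[:pos],
                                  _random_seq_arr(length, rng), out[pos:]])
    return _decode(out)


# ---------------------------------------------------------------------------
# The simulator

def _random_seq_arr(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def simulate(params: EvolutionParams,
             template: MitoTemplate | None = None) -> SimulationTruth:
    """Run the full insertion-and-divergence model; return ground truth.

    The mitochondrial lineage starts from the template ("primordial")
    sequence ``t_max`` time units before the present and accumulates
    substitutions at ``sn``; each insertion copies the mitochondrial state
    at its insertion time t0 into the nuclear background, after which the
    copy's flank evolves at ``sp`` and MTL loci at ``st`` (scaled by
    ``functional_factor`` when flagged functional).
    """
    if template is None:
        template = default_mito_template()
    if not template.genes:
        raise ValueError("mito template carries no tRNA genes")
    rng = np.random.default_rng(params.seed)
    n = params.n_insertions

    if params.fixed_insertion_time is not None:
        t0s = np.full(n, float(params.fixed_insertion_time))
    else:
        # Uniform(0, t_max]
        t0s = params.t_max * (1.0 - rng.random(n))

    # --- sample source segments on the mitochondrial template -----------
    mito_len = len(template.genome)
    lo, hi = params.insertion_length_range
    segments: list[tuple[int, int, str]] = []
    for _ in range(n):
        seg_len = int(rng.integers(lo, hi + 1))
        seg_len = min(seg_len, mito_len)
        if params.min_trnas_per_insertion > 0:
            # anchor the segment on a random gene it must fully contain
            gene = template.genes[rng.integers(len(template.genes))]
            if seg_len < gene.length:
                seg_len = gene.length
            a_min = max(0, gene.end - seg_len)
            a_max = min(gene.start, mito_len - seg_len)
            a = int(rng.integers(a_min, a_max + 1)) if a_max >= a_min else a_min
        else:
            a = int(rng.integers(0, mito_len - seg_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        segments.append((a, a + seg_len, strand))

    # genes contained (>=50% of length) in each segment
    def contained_genes(a: int, b: int) -> list[TrnaGene]:
        out = []
        for g in template.genes:
            ovl = max(0, min(b, g.end) - max(a, g.start))
            if ovl * 2 >= g.length:
                out.append(g)
        return out

    seg_genes = [contained_genes(a, b) for a, b, _ in segments]

    # --- functional flags: exactly round(fraction * n_mtls) loci ---------
    all_loci = [(i, g) for i, genes in enumerate(seg_genes) for g in genes]
    n_functional = int(round(params.functional_fraction * len(all_loci)))
    functional_idx = set(
        map(int, rng.choice(len(all_loci), size=n_functional, replace=False))
    ) if n_functional else set()
    # (insertion index, gene start) pairs flagged functional
    functional_pairs = {(all_loci[k][0], all_loci[k][1].start)
                        for k in functional_idx}

    # --- mitochondrial lineage with snapshots at insertion times ---------
    order = np.argsort(-t0s, kind="stable")  # oldest first
    cur = _encode(template.genome.sequence)
    t_prev = float(params.t_max if params.fixed_insertion_time is None
                   else max(params.fixed_insertion_time, params.t_max))
    t_prev = max(t_prev, float(t0s.max()))
    snapshots: dict[int, np.ndarray] = {}
    for i in order:
        t0 = float(t0s[i])
        cur = jc_evolve(cur, params.sn, t_prev - t0, rng)
        snapshots[int(i)] = cur.copy()
        t_prev = t0
    cur = jc_evolve(cur, params.sn, t_prev, rng)
    extant_mito = SequenceRecord(MITO_CHROM, _decode(cur))

    # --- evolve each inserted copy ---------------------------------------
    loci_counter = 0
    evolved_copies: list[np.ndarray] = []
    insertion_meta = []  # per insertion: list of (gene, functional, subs), flank subs
    for i in range(n):
        a, b, strand = segments[i]
        t0 = float(t0s[i])
        copy = snapshots[i][a:b].copy()
        genes = seg_genes[i]
        is_mtl = np.zeros(b - a, dtype=bool)
        for g in genes:
            is_mtl[max(0, g.start - a):min(b - a, g.end - a)] = True
        mtl_info = []
        evolved = copy.copy()
        for g in genes:
            functional = (i, g.start) in functional_pairs
            rate = params.st * (params.functional_factor if functional else 1.0)
            s0, s1 = max(0, g.start - a), min(b - a, g.end - a)
            evolved[s0:s1] = jc_evolve(copy[s0:s1], rate, t0, rng)
            subs = int(np.count_nonzero(evolved[s0:s1] != copy[s0:s1]))
            mtl_info.append((g, functional, subs))
        flank_mask = ~is_mtl
        evolved[flank_mask] = jc_evolve(copy[flank_mask], params.sp, t0, rng)
        subs_flank = int(np.count_nonzero(evolved[flank_mask] != copy[flank_mask]))
        if strand == "-":
            evolved = _encode(revcomp(_decode(evolved)))
        evolved_copies.append(evolved)
        insertion_meta.append((mtl_info, subs_flank, int(flank_mask.sum())))

    # --- place insertions in the nuclear background ----------------------
    total_inserted = sum(len(c) for c in evolved_copies)
    bg_len = params.nuclear_length - total_inserted
    min_gap = 600  # room for host-gene exons/flanks between insertions
    if bg_len < (n + 1) * min_gap:
        raise ValueError("nuclear_length too small for the requested insertions")
    bg = _random_seq_arr(bg_len, rng)
    # uniform placement with a guaranteed minimum gap: distribute the
    # slack beyond (n+1)*min_gap via sorted uniform cut points
    slack = bg_len - (n + 1) * min_gap
    cuts = np.sort(rng.integers(0, slack + 1, n))
    pts = min_gap * np.arange(1, n + 1) + cuts

    pieces = []
    numt_coords = []
    prev = 0
    offset = 0
    for i in range(n):
        pieces.append(bg[prev:pts[i]])
        start = int(pts[i]) + offset
        pieces.append(evolved_copies[i])
        numt_coords.append((start, start + len(evolved_copies[i])))
        offset += len(evolved_copies[i])
        prev = int(pts[i])
    pieces.append(bg[prev:])
    nuclear = SequenceRecord(NUCLEAR_CHROM, _decode(np.concatenate(pieces)))

    # --- assemble truth ---------------------------------------------------
    insertions: list[InsertionTruth] = []
    for i in range(n):
        a, b, strand = segments[i]
        nstart, nend = numt_coords[i]
        numt = NumtRecord(
            GenomicInterval(NUCLEAR_CHROM, nstart, nend, strand),
            GenomicInterval(MITO_CHROM, a, b, strand),
            f"numt{i:03d}")
        mtl_info, subs_flank, flank_len = insertion_meta[i]
        mtls = []
        for g, _func, subs in mtl_info:
            functional = (i, g.start) in functional_pairs
            gs, ge = max(a, g.start), min(b, g.end)
            if strand == "+":
                ns, ne = nstart + (gs - a), nstart + (ge - a)
            else:
                ns, ne = nstart + (b - ge), nstart + (b - gs)
            mtls.append(TruthMtl(
                f"numt{i:03d}.{g.isotype}.{loci_counter}", g.isotype,
                GenomicInterval(NUCLEAR_CHROM, ns, ne, strand),
                g.interval, functional, subs))
            loci_counter += 1
        mtls.sort(key=lambda m: m.nuclear.start)
        insertions.append(InsertionTruth(numt, float(t0s[i]), mtls,
                                         subs_flank, flank_len))

    # --- host genes for the intronic fraction of insertions --------------
    n_intronic = int(round(params.intronic_fraction * n))
    intronic_ids = set(map(int, rng.choice(n, size=n_intronic, replace=False))) \
        if n_intronic else set()
    transcripts: list[GeneModel] = []
    for i in sorted(intronic_ids):
        ins = insertions[i]
        nstart, nend = ins.numt.nuclear.start, ins.numt.nuclear.end
        up = int(rng.integers(120, 220))
        down = int(rng.integers(120, 220))
        exon_len = 60
        g_start = max(0, nstart - up - exon_len)
        g_end = min(len(nuclear.sequence), nend + down + exon_len)
        gene_strand = "-" if rng.random() < params.antisense_prob else "+"
        gene_id = f"HOST{i:03d}"
        gm = GeneModel(gene_id, NUCLEAR_CHROM, gene_strand,
                       ((g_start, g_start + exon_len), (g_end - exon_len, g_end)))
        transcripts.append(gm)
        for m in ins.mtls:
            m.host_gene = gene_id
            m.antisense_to_host = (m.nuclear.strand != gene_strand)
    transcripts.sort(key=lambda g: g.span)

    return SimulationTruth(params, template, extant_mito, nuclear,
                           insertions, transcripts)


# ---------------------------------------------------------------------------
# Binding-site simulation (fixture for the enrichment stage)

def simulate_binding_sites(
    truth: SimulationTruth,
    enriched_rbps: list[str],
    fold: float,
    seed: int,
    rbps: Optional[list[str]] = None,
    base_density: float = 0.05,
    site_length: int = 40,
    sample: str = "simA",
):
    """Scatter stranded binding sites over introns and nimtRNA loci.

    Background sites cover intron territory (nimtRNA bases excluded) at
    coverage density ``base_density`` on the intron strand; every RBP also
    receives sites over nimtRNA loci on the nimtRNA's own strand at
    density ``base_density`` — multiplied by ``fold`` for RBPs listed in
    ``enriched_rbps``.  Returns ``{rbp: [BindingSite, ...]}``; realized
    coverage densities are recorded in ``truth.binding_truth``.
    """
    from .rbp import BindingSite, merged_length, stranded_coverage

    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    if rbps is None:
        rbps = sorted(set(enriched_rbps) | {f"RBP{i:02d}" for i in range(8)})
    nimts = [m.nuclear for m in truth.nimtrnas]
    intron_ivs = []
    for gm in truth.transcripts:
        for s, e in gm.introns():
            intron_ivs.append(GenomicInterval(gm.chrom, s, e, gm.strand))
    # background territory excludes nimtRNA bases
    nimt_spans = [(m.start, m.end) for m in nimts]

    def bg_segments(iv: GenomicInterval):
        cuts = [(s, e) for s, e in nimt_spans if s < iv.end and e > iv.start]
        segs, pos = [], iv.start
        for s, e in sorted(cuts):
            if s > pos:
                segs.append((pos, s))
            pos = max(pos, e)
        if pos < iv.end:
            segs.append((pos, iv.end))
        return segs

    sites: dict[str, list[BindingSite]] = {r: [] for r in rbps}
    for rbp in rbps:
        r_fold = fold if rbp in enriched_rbps else 1.0
        for iv in intron_ivs:
            for s, e in bg_segments(iv):
                lam = base_density * (e - s) / site_length
                for _ in range(rng.poisson(lam)):
                    st = int(rng.integers(s, max(s + 1, e - site_length + 1)))
                    en = min(e, st + site_length)
                    sites[rbp].append(BindingSite(
                        rbp, GenomicInterval(iv.chrom, st, en, iv.strand), sample))
        for m in nimts:
            lam = r_fold * base_density * m.length / site_length
            for _ in range(rng.poisson(lam)):
                st = int(rng.integers(m.start, max(m.start + 1, m.end - site_length + 1)))
                en = min(m.end, st + site_length)
                sites[rbp].append(BindingSite(
                    rbp, GenomicInterval(m.chrom, st, en, m.strand), sample))

    # realized densities against the territories the enrichment stage uses
    total_nimt = merged_length(nimts)
    bg_ivs = [GenomicInterval(iv.chrom, s, e, iv.strand)
              for iv in intron_ivs for s, e in bg_segments(iv)]
    total_bg = merged_length(bg_ivs)
    realized = {}
    for rbp in rbps:
        cov_n = stranded_coverage(nimts, [s.interval for s in sites[rbp]])
        cov_b = stranded_coverage(bg_ivs, [s.interval for s in sites[rbp]])
        realized[rbp] = {
            "density_nimt": cov_n / total_nimt if total_nimt else float("nan"),
            "density_bg": cov_b / total_bg if total_bg else float("nan"),
        }
    truth.binding_truth = {"realized": realized, "fold": fold,
                           "enriched_rbps": sorted(enriched_rbps),
                           "base_density": base_density}
    return sites
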