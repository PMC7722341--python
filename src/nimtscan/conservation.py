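"""The stabilizing-selection test on divergence pairs (dt, dp).

For each validated MTL, dt is the divergence between the nuclear MTL
sequence and its extant mitochondrial tRNA, and dp the divergence between
the MTL-masked numtDNA flank and the corresponding extant mitochondrial
source.  Under neutral evolution both are linear in insertion age,
dt = (sn + st)·t0 and dp = (sn + sp)·t0, so MTLs under stabilizing
selection (st reduced) fall below the regression of dt on dp.  Such
points are flagged by Cook's distance exceeding three times the mean,
restricted to negative residuals (the conserved direction).

Per-base conservation-score tracks (PhyloP-style wiggle input) are
aggregated per feature against flank baselines in ``aggregate_scores``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .align import edit_distance
from .core import GenomicInterval, SequenceRecord, revcomp
from .synteny import ValidatedMtl
from .core import NumtRecord


def divergence(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Proportion divergence: unit-cost edit distance over sequence length.

    The denominator is the longer sequence's length, which makes the
    measure symmetric, keeps it in [0, 1], and reduces to the Hamming
    proportion for equal-length sequences (the no-indel case the
    evolution model produces).
    """
    sa = a.sequence if isinstance(a, SequenceRecord) else a
    sb = b.sequence if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("divergence requires non-empty sequences")
    d, _ = edit_distance(sa, sb)
    return d / max(len(sa), len(sb))


@dataclass(frozen=True)
class DivergencePoint:
    mtl_id: str
    dt: float
    dp: float
    mtl_len: int
    flank_len: int


MIN_FLANK = 50  # flanks of at most this many nt are excluded


def build_points(
    validated: Sequence[ValidatedMtl],
    numts: Sequence[NumtRecord],
    extant_mito: SequenceRecord,
    nuclear: SequenceRecord,
    min_flank: int = MIN_FLANK,
    mask_mtls: bool = True,
) -> list[DivergencePoint]:
    """Divergence pairs for every TP MTL with a usable flank.

    dp is computed once per numtDNA on the flank with all matched MTL
    intervals masked out of both the nuclear copy and the extant
    mitochondrial source (masking keeps the tested signal out of its own
    baseline; pass ``mask_mtls=False`` for the unmasked sensitivity
    mode).  Points whose flank is not longer than ``min_flank`` nt are
    dropped.  Sequences from minus-strand numtDNAs are oriented back to
    mitochondrial forward before comparison.
    """
    numt_by_id = {n.id: n for n in numts}
    tps = [v for v in validated if v.status == "TP" and v.expected is not None]
    by_numt: dict[str, list[ValidatedMtl]] = {}
    for v in tps:
        if v.numt_id not in numt_by_id:
            warnings.warn(f"{v.hit.isotype} hit: numt {v.numt_id} unknown, skipped")
            continue
        by_numt.setdefault(v.numt_id, []).append(v)

    points: list[DivergencePoint] = []
    for numt_id, vs in sorted(by_numt.items()):
        numt = numt_by_id[numt_id]
        nuc = numt.nuclear
        src = numt.mt_source
        # nuclear copy oriented to mitochondrial forward coordinates
        copy = nuclear.sequence[nuc.start:nuc.end]
        if src.strand == "-":
            copy = revcomp(copy)
        source = extant_mito.sequence[src.start:src.end]
        if len(copy) != len(source):
            warnings.warn(f"{numt_id}: nuclear/source length mismatch, "
                          "using unmasked flank")
        # mask MTL intervals (in source coordinates) out of the flank
        mask = np.zeros(len(source), dtype=bool)
        if mask_mtls and len(copy) == len(source):
            for v in vs:
                ec = v.expected
                s = max(0, ec.mt_gene.start - src.start)
                e = min(len(source), ec.mt_gene.end - src.start)
                if e > s:
                    mask[s:e] = True
        keep = ~mask
        flank_nuc = "".join(c for c, k in zip(copy, keep) if k) \
            if len(copy) == len(source) else copy
        flank_src = "".join(c for c, k in zip(source, keep) if k)
        flank_len = len(flank_src)
        if flank_len <= min_flank or not flank_nuc:
            continue
        dp = divergence(flank_nuc, flank_src)
        for v in vs:
            ec = v.expected
            mtl_nuc = nuclear.sequence[ec.projected.start:ec.projected.end]
            if ec.projected.strand == "-":
                mtl_nuc = revcomp(mtl_nuc)
            # clip the extant tRNA to the part the numtDNA actually carries
            gs = max(src.start, ec.mt_gene.start)
            ge = min(src.end, ec.mt_gene.end)
            mtrna = extant_mito.sequence[gs:ge]
            dt = divergence(mtl_nuc, mtrna)
            points.append(DivergencePoint(
                f"{numt_id}:{ec.order_index}:{ec.isotype}", dt, dp,
                ec.projected.length, flank_len))
    return points


@dataclass
class RegressionFit:
    """OLS fit of dt on dp with influence diagnostics and outlier flags."""

    slope: float
    intercept: float
    residuals: np.ndarray
    leverages: np.ndarray
    mse: float
    cooks_d: np.ndarray
    flags: np.ndarray  # boolean; True = conserved outlier
    threshold: float
    k: float
    orientation: str = "dt~dp"  # recorded so plots can match either axis choice


def fit_and_flag(points: Sequence[DivergencePoint], k: float = 3.0) -> RegressionFit:
    """Regress dt on dp; flag conserved outliers by Cook's distance.

    A point is flagged iff its Cook's distance exceeds ``k`` times the
    mean Cook's distance (default 3) AND its residual is negative, i.e.
    dt is smaller than the regression predicts — the direction of
    stabilizing selection on the MTL.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for the regression")
    dp = np.array([p.dp for p in points])
    dt = np.array([p.dt for p in points])
    if np.ptp(dp) == 0:
        raise ValueError("all dp identical: regression is degenerate")
    X = sm.add_constant(dp)
    res = sm.OLS(dt, X).fit()
    infl = OLSInfluence(res)
    cooks = infl.cooks_distance[0]
    resid = res.resid
    mean_d = float(np.mean(cooks))
    threshold = k * mean_d
    flags = (cooks > threshold) & (resid < 0)
    return RegressionFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        residuals=resid, leverages=infl.hat_matrix_diag,
        mse=float(res.mse_resid), cooks_d=cooks, flags=flags,
        threshold=threshold, k=k)


# ---------------------------------------------------------------------------
# Conservation-score aggregation

@dataclass(frozen=True)
class ScoreAggregate:
    feature_id: str
    mean: Optional[float]       # None when no base of the feature is scored
    n_bases: int
    flank_mean: Optional[float]
    flank_n: int

    @property
    def delta(self) -> Optional[float]:
        if self.mean is None or self.flank_mean is None:
            return None
        return self.mean - self.flank_mean


def _interval_stats(ivs: Sequence[GenomicInterval],
                    scores: dict[str, dict[int, float]]) -> tuple[Optional[float], int]:
    total, n = 0.0, 0
    for iv in ivs:
        chrom_scores = scores.get(iv.chrom, {})
        for pos in range(iv.start, iv.end):
            v = chrom_scores.get(pos)
            if v is not None:
                total += v
                n += 1
    return (total / n if n else None), n


def aggregate_scores(
    features: Sequence[tuple[str, GenomicInterval]],
    flanks: dict[str, Sequence[GenomicInterval]],
    scores: dict[str, dict[int, float]],
) -> tuple[list[ScoreAggregate], dict[str, int]]:
    """Mean per-base score per feature vs its flank, plus sign counts.

    ``scores`` is the sparse map produced by the wiggle reader; unscored
    bases are excluded from means (zero is a meaningful score, missing is
    not).  Returns the per-feature aggregates and a cohort-level paired
    comparison: counts of positive / negative / zero deltas.
    """
    if not scores:
        warnings.warn("empty score map: all aggregates will be missing")
    aggs = []
    signs = {"positive": 0, "negative": 0, "zero": 0, "missing": 0}
    for fid, iv in features:
        mean, n = _interval_stats([iv], scores)
        fmean, fn = _interval_stats(flanks.get(fid, ()), scores)
        agg = ScoreAggregate(fid, mean, n, fmean, fn)
        aggs.append(agg)
        d = agg.delta
        if d is None:
            signs["missing"] += 1
        elif d > 0:
            signs["positive"] += 1
        elif d < 0:
            signs["negative"] += 1
        else:
            signs["zero"] += 1
    return aggs, signs


def numt_flanks(numt: NumtRecord,
                features: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """The numtDNA interval minus the given feature intervals."""
    cuts = sorted((max(numt.nuclear.start, f.start), min(numt.nuclear.end, f.end))
                  for f in features if f.overlaps(numt.nuclear))
    out, pos = [], numt.nuclear.start
    for s, e in cuts:
        if s > pos:
            out.append(GenomicInterval(numt.nuclear.chrom, pos, s, numt.nuclear.strand))
        pos = max(pos, e)
    if pos < numt.nuclear.end:
        out.append(GenomicInterval(numt.nuclear.chrom, pos, numt.nuclear.end,
                                   numt.nuclear.strand))
    return out
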