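"""End-to-end orchestration of the simulated analysis pipeline.

``run_all`` executes the stages in dependency order — simulate, detect
(both the numtDNA-based and the genome-based strategy), validate against
synteny, conservation regression, structure classification, binding-site
enrichment — and writes one TSV per stage plus a summary.  Outputs are
pure functions of (config, seed): re-running with the same configuration
yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation import build_points, fit_and_flag
from .detection import DEFAULT_MIN_SCORE, TrnaReference, assign_context, builtin_scan
from .io_formats import (Bed6Record, write_bed6, write_fasta,
                         write_gff3_transcripts, write_hit_table,
                         write_numt_table, write_table)
from .numtsim import (EvolutionParams, SimulationTruth, simulate,
                      simulate_binding_sites)
from .rbp import enrichment, enrichment_table, intron_intervals
from .structure import classify_changes, detect_arm_deletion
from .synteny import classify_hits, expected_copies, union_tp_set
from .align import global_align_columns

log = logging.getLogger("nimtscan")

_SIM_KEYS = {f.name for f in dataclasses.fields(EvolutionParams)} - {"seed"}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; unknown keys are rejected on load."""

    seed: int = 0
    sim: dict = field(default_factory=dict)          # EvolutionParams overrides
    min_score: float = DEFAULT_MIN_SCORE             # built-in detector cutoff
    min_containment: float = 0.5                     # expected-copy rule
    cook_k: float = 3.0                              # Cook's distance multiplier
    min_flank: int = 50                              # flank length filter (nt)
    arm_deletion_fraction: float = 0.6
    enriched_rbps: list = field(default_factory=lambda: ["RBPX"])
    enrichment_fold: float = 10.0
    base_site_density: float = 0.05

    def __post_init__(self):
        unknown = set(self.sim) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        if self.cook_k <= 0 or self.min_score is None:
            raise ValueError("invalid thresholds")
        if not (0 < self.min_containment <= 1):
            raise ValueError("min_containment must be in (0, 1]")
        if not (0 < self.arm_deletion_fraction <= 1):
            raise ValueError("arm_deletion_fraction must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage on simulated data; write the report bundle.

    Returns a dict of the in-memory stage results (truth, hits, validated
    sets, points, fit, enrichment records) for programmatic use.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, sites_seed = _child_seeds(config.seed, 2)
    header = (f"# nimtscan {__version__} | config {config.digest()} "
              f"| seed {config.seed}\n")

    # --- simulate ---------------------------------------------------------
    params = EvolutionParams(seed=sim_seed, **config.sim)
    truth = simulate(params)
    log.info("simulated %d insertions, %d MTL loci (%d intronic)",
             len(truth.insertions), len(truth.mtls), len(truth.nimtrnas))
    write_fasta([truth.nuclear], out / "nuclear.fa")
    write_fasta([truth.extant_mito], out / "mito.fa")
    numts = [ins.numt for ins in truth.insertions]
    write_numt_table(numts, out / "numts.tsv")
    write_gff3_transcripts(truth.transcripts, out / "transcripts.gff3")
    write_table(truth_table(truth), out / "truth.tsv")

    # --- detect (both strategies) ----------------------------------------
    refs = [TrnaReference.from_strings(g.isotype,
                                       truth.extant_mtrna(g.isotype), g.structure)
            for g in truth.template.genes]
    strategies = {
        "numt": [n.nuclear for n in numts],
        "genome": None,
    }
    expected = expected_copies(numts, truth.template.genes,
                               min_containment=config.min_containment,
                               mito_length=len(truth.template.genome))
    validated_sets = []
    summary_rows = []
    hits_by_strategy = {}
    for name, regions in strategies.items():
        hits = builtin_scan(truth.nuclear, refs, min_score=config.min_score,
                            regions=regions)
        hits = assign_context(hits, truth.transcripts)
        hits_by_strategy[name] = hits
        write_hit_table(hits, out / f"hits_{name}.tsv")
        validated, summ = classify_hits(hits, expected, numts)
        validated_sets.append(validated)
        summary_rows.append({"tool": "builtin", "strategy": name,
                             "tp": summ.tp, "fp": summ.fp, "fn": summ.fn,
                             "tpr": round(summ.tpr, 4)})
        log.info("strategy %s: TPR %.3f (%d TP / %d FP / %d FN)",
                 name, summ.tpr, summ.tp, summ.fp, summ.fn)
    tpr_df = pd.DataFrame(summary_rows)
    _write_with_header(tpr_df, out / "validation_summary.tsv", header)

    final = union_tp_set(validated_sets)
    final_hits = assign_context([v.hit for v in final], truth.transcripts)
    final = [dataclasses.replace(v, hit=h) for v, h in zip(final, final_hits)]
    write_hit_table(final_hits, out / "final_mtls.tsv")

    # --- conservation -----------------------------------------------------
    points = build_points(final, numts, truth.extant_mito, truth.nuclear,
                          min_flank=config.min_flank)
    pts_df = pd.DataFrame([{"mtl_id": p.mtl_id, "dt": round(p.dt, 6),
                            "dp": round(p.dp, 6), "mtl_len": p.mtl_len,
                            "flank_len": p.flank_len} for p in points])
    _write_with_header(pts_df, out / "points.tsv", header)
    fit = None
    if len(points) >= 3 and len({p.dp for p in points}) > 1:
        fit = fit_and_flag(points, k=config.cook_k)
        fit_df = pd.DataFrame([{
            "slope": round(fit.slope, 6), "intercept": round(fit.intercept, 6),
            "mse": round(fit.mse, 8), "k": fit.k,
            "threshold": round(fit.threshold, 8), "n_points": len(points),
            "n_outliers": int(fit.flags.sum()), "orientation": fit.orientation,
        }])
        _write_with_header(fit_df, out / "fit.tsv", header)
        outl_df = pd.DataFrame([
            {"mtl_id": p.mtl_id, "dt": round(p.dt, 6), "dp": round(p.dp, 6),
             "residual": round(float(fit.residuals[i]), 6),
             "cooks_d": round(float(fit.cooks_d[i]), 8),
             "outlier": int(fit.flags[i])}
            for i, p in enumerate(points)])
        _write_with_header(outl_df, out / "outliers.tsv", header)

    # --- structure --------------------------------------------------------
    ref_by_iso = {r.isotype: r for r in refs}
    struct_rows = []
    from .core import revcomp
    for v in final:
        ec = v.expected
        ref = ref_by_iso[ec.isotype]
        seq = truth.nuclear.sequence[ec.projected.start:ec.projected.end]
        if ec.projected.strand == "-":
            seq = revcomp(seq)
        aln = global_align_columns(ref.model.sequence, seq)
        _, summ = classify_changes(ref.model, seq, aln)
        deleted = detect_arm_deletion(ref.model, aln,
                                      min_fraction=config.arm_deletion_fraction)
        struct_rows.append({
            "mtl_id": f"{ec.numt_id}:{ec.order_index}:{ec.isotype}",
            "isotype": ec.isotype,
            "n_loop": summ.counts["loop"],
            "n_compensatory": summ.counts["compensatory"],
            "n_wobble": summ.counts["wobble_shift"],
            "n_disruptive": summ.counts["disruptive"],
            "deleted_arms": ",".join(sorted(deleted)) or ".",
            "structure_score": round(summ.structure_score, 4),
        })
    _write_with_header(pd.DataFrame(struct_rows), out / "structure.tsv", header)

    # --- enrichment -------------------------------------------------------
    sites = simulate_binding_sites(truth, list(config.enriched_rbps),
                                   config.enrichment_fold, sites_seed,
                                   base_density=config.base_site_density)
    sites_dir = out / "sites"
    sites_dir.mkdir(exist_ok=True)
    for rbp in sorted(sites):
        write_bed6([Bed6Record(s.interval, s.rbp, 0.0) for s in sites[rbp]],
                   sites_dir / f"{rbp}.bed")
    nimt_ivs = [h.interval for h in final_hits if h.context == "intronic"]
    enr_records = []
    if nimt_ivs:
        introns = intron_intervals(truth.transcripts)
        all_sites = [s for rbp in sorted(sites) for s in sites[rbp]]
        enr_records = enrichment(nimt_ivs, introns, all_sites)
        _write_with_header(enrichment_table(enr_records),
                           out / "enrichment.tsv", header)

    # --- summary ----------------------------------------------------------
    ctx_counts = pd.Series([h.context for h in final_hits]).value_counts()
    summary = pd.DataFrame([{
        "n_insertions": len(truth.insertions),
        "n_truth_mtls": len(truth.mtls),
        "n_final_mtls": len(final),
        "n_intronic": int(ctx_counts.get("intronic", 0)),
        "n_exonic": int(ctx_counts.get("exonic", 0)),
        "n_intergenic": int(ctx_counts.get("intergenic", 0)),
        "n_points": len(points),
        "n_outliers": int(fit.flags.sum()) if fit is not None else 0,
        "n_enriched_rbps": sum(1 for r in enr_records
                               if r.sample == "pooled" and r.enriched),
    }])
    _write_with_header(summary, out / "summary.tsv", header)
    return {"truth": truth, "hits": hits_by_strategy, "validated": validated_sets,
            "final": final, "points": points, "fit": fit,
            "enrichment": enr_records, "tpr_table": tpr_df}


def _write_with_header(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def truth_table(truth: SimulationTruth) -> pd.DataFrame:
    rows = []
    for ins in truth.insertions:
        for m in ins.mtls:
            rows.append({
                "mtl_id": m.mtl_id, "isotype": m.isotype,
                "chrom": m.nuclear.chrom, "start": m.nuclear.start,
                "end": m.nuclear.end, "strand": m.nuclear.strand,
                "numt_id": ins.numt.id, "t0": round(ins.t0, 6),
                "functional": int(m.functional), "subs": m.subs,
                "host_gene": m.host_gene or ".",
                "antisense": int(bool(m.antisense_to_host)),
            })
    return pd.DataFrame(rows)


def scatter_plot(points, fit, path) -> None:
    """Diagnostic dt-vs-dp scatter with the fitted line and flagged outliers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dp = np.array([p.dp for p in points])
    dt = np.array([p.dt for p in points])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(dp[~fit.flags], dt[~fit.flags], s=12, label="MTL")
    if fit.flags.any():
        ax.scatter(dp[fit.flags], dt[fit.flags], s=20, color="tab:orange",
                   label="conserved outlier")
    xs = np.linspace(dp.min(), dp.max(), 10)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="red", lw=1)
    ax.set_xlabel("dp (numtDNA flank divergence)")
    ax.set_ylabel("dt (MTL divergence)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
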