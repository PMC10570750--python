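"""End-to-end orchestration: one config, a run report, per-stage TSVs.

Stage order follows the analysis narrative: expression filter and
donor-paired DE; promoter chromatin states of all genes; enhancer calling,
signal-matrix k-means states and closest-gene assignment; the effector
subset (enhancers assigned to regulated genes with marked promoters);
triage and naming of regulated unannotated transcripts; optional gene-set
overlap tests; optional single-cell marker merge and condition proportions.
Every count in the report is re-derivable from the emitted TSVs, and a
self-consistency audit re-reads them to check exactly that.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    compare_to_reference,
    gene_tss_map,
    promoter_of,
    read_gtf,
    read_narrowpeak,
)
from .diffexpr import ExpressionTable, differential_genes, results_frame
from .epigenome import (
    EnhancerRecord,
    assign_enhancers_to_genes,
    build_signal_matrix,
    call_enhancers,
    classify_promoter_state,
    cluster_enhancer_states,
    differential_motif_enrichment,
    effector_subset,
    read_bedgraph,
    read_jaspar,
    window_sequences,
)
from .lncrna import (
    TriageThresholds,
    assign_names,
    classify_novel_transcript,
    transcript_sequence,
)
from .scmarkers import (
    CellDataset,
    cluster_condition_proportions,
    merge_clusters_by_marker,
    qc_filter,
)
from .setstats import rescue_set_test

log = logging.getLogger("isletomics")


class ConfigError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    reference_gtf: str
    assembled_gtf: str
    genome_fasta: str
    tpm: str
    design: str
    peaks: dict[str, str] = field(default_factory=dict)      # mark -> path
    coverage: dict[str, str] = field(default_factory=dict)   # mark -> path
    cells_dir: str | None = None        # matrix.mtx/barcodes/features/cells.tsv
    pwms: str | None = None             # JASPAR file for motif enrichment
    suppressed_set: str | None = None   # one gene id per line
    rescued_set: str | None = None
    universe_N: int | None = None
    outdir: str = "isletomics_run"
    seed: int = 0
    # thresholds
    tpm_min: float = 0.5
    alpha: float = 0.05
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    orf_min: int = 100
    signal_window: int = 6000
    signal_bins: int = 60
    motif_window: int = 500
    marker_gene: str = "Ri-lnc1"
    hi: float = 0.3
    lo: float = 0.18
    suppress_frac: float = 0.30
    rescue_tol: float = 0.15
    max_enhancer_distance: int | None = None

    def __post_init__(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha in (0,1)"),
            (self.tpm_min >= 0, "tpm_min >= 0"),
            (self.hi > self.lo > 0, "hi > lo > 0"),
            (0 < self.suppress_frac < 1, "suppress_frac in (0,1)"),
            (self.rescue_tol > 0, "rescue_tol > 0"),
            (self.orf_min > 0, "orf_min > 0"),
        ]
        for ok, what in checks:
            if not ok:
                raise ConfigError(f"threshold out of range: {what}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    t0 = time.time()
    for name in ("reference_gtf", "assembled_gtf", "genome_fasta", "tpm", "design"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise InputError(f"mandatory input {name} missing: {p}")
    for mark in ("H3K4me3", "H3K4me1", "H3K27ac", "ATAC"):
        if mark not in config.peaks:
            raise InputError(f"peak calls for {mark} are required")
        if not Path(config.peaks[mark]).exists():
            raise InputError(f"peak file missing: {config.peaks[mark]}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    reference = read_gtf(config.reference_gtf)
    assembled = read_gtf(config.assembled_gtf)
    genome = _read_fasta(config.genome_fasta)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    peaks = {m: read_narrowpeak(p, m) for m, p in config.peaks.items()}
    log.info("loaded %d reference / %d assembled transcripts", len(reference),
             len(assembled))

    # --- differential expression --------------------------------------------
    table = ExpressionTable.read(config.tpm, config.design)
    de = differential_genes(table, alpha=config.alpha, tpm_min=config.tpm_min)
    de_frame = results_frame(de)
    de_frame.to_csv(outdir / "de_results.tsv", sep="\t")
    regulated = {r.gene_id for r in de if r.regulated}
    report["stages"]["diffexpr"] = {
        "genes_tested": len(de),
        "regulated": len(regulated),
        "up": sum(1 for r in de if r.regulated and r.direction == "up"),
        "down": sum(1 for r in de if r.regulated and r.direction == "down"),
    }

    # --- promoter states -----------------------------------------------------
    rep_transcripts = gene_tss_map(reference)
    promoters = {
        g: promoter_of(t, config.promoter_upstream, config.promoter_downstream,
                       chrom_lengths.get(t.chrom))
        for g, t in rep_transcripts.items()
    }
    prom_rows = []
    for g, prom in promoters.items():
        state = classify_promoter_state(prom, peaks["H3K4me3"], peaks["H3K27ac"])
        prom_rows.append({"gene_id": g, "chrom": prom.chrom, "start": prom.start,
                          "end": prom.end, "state": state})
    prom_frame = pd.DataFrame(prom_rows).set_index("gene_id")
    prom_frame.to_csv(outdir / "promoter_states.tsv", sep="\t")
    state_counts = prom_frame["state"].value_counts().to_dict()
    regulated_known = regulated & set(prom_frame.index)
    reg_marked = {
        g for g in regulated_known if prom_frame.loc[g, "state"] != "unmarked"
    }
    reg_active = {g for g in regulated_known if prom_frame.loc[g, "state"] == "active"}
    report["stages"]["promoters"] = {
        "states": state_counts,
        "regulated_with_k4me3": len(reg_marked),
        "regulated_active": len(reg_active),
    }

    # --- enhancers -----------------------------------------------------------
    enhancers = call_enhancers(
        peaks["ATAC"], peaks["H3K4me1"], list(promoters.values())
    )
    enhancers = assign_enhancers_to_genes(
        enhancers, reference, config.max_enhancer_distance
    )
    tracks = {m: read_bedgraph(p, m) for m, p in config.coverage.items()}
    states: list[str | None] = [None] * len(enhancers)
    if len(enhancers) >= 3 and {"H3K4me3", "H3K4me1", "H3K27ac"} <= set(tracks):
        sm = build_signal_matrix(
            enhancers,
            {m: tracks[m] for m in ("H3K4me3", "H3K4me1", "H3K27ac")},
            config.signal_window,
            config.signal_bins,
        )
        states = cluster_enhancer_states(sm, k=3, seed=config.seed)
        for e, s in zip(enhancers, states):
            e.state = s
    else:
        log.warning("enhancer-state clustering skipped (needs >=3 enhancers "
                    "and all three coverage tracks)")
    effectors = effector_subset(enhancers, reg_marked)
    enh_frame = pd.DataFrame(
        {
            "chrom": [e.interval.chrom for e in enhancers],
            "start": [e.interval.start for e in enhancers],
            "end": [e.interval.end for e in enhancers],
            "summit": [e.summit for e in enhancers],
            "state": [e.state for e in enhancers],
            "assigned_gene": [e.assigned_gene for e in enhancers],
            "distance": [e.distance for e in enhancers],
            "effector": [e.assigned_gene in reg_marked for e in enhancers],
        }
    )
    enh_frame.to_csv(outdir / "enhancers.tsv", sep="\t", index=False)
    report["stages"]["enhancers"] = {
        "called": len(enhancers),
        "by_state": enh_frame["state"].value_counts(dropna=True).to_dict(),
        "effectors": len(effectors),
    }

    # --- motif enrichment (optional) ----------------------------------------
    if config.pwms and len(effectors) > 0 and len(effectors) < len(enhancers):
        pwms = read_jaspar(config.pwms)
        fg = window_sequences(
            genome, [(e.interval.chrom, e.summit) for e in effectors],
            config.motif_window,
        )
        bg = window_sequences(
            genome,
            [(e.interval.chrom, e.summit) for e in enhancers
             if e.assigned_gene not in reg_marked],
            config.motif_window,
        )
        motif_frame = differential_motif_enrichment(fg, bg, pwms)
        motif_frame.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        report["stages"]["motifs"] = {
            "pwms_tested": len(motif_frame),
            "enriched_q05": int((motif_frame["q_bh"] < 0.05).sum()),
        }
    elif config.pwms:
        log.warning("motif stage skipped: effector/background split is degenerate")

    # --- novel-transcript triage --------------------------------------------
    novelty = compare_to_reference(assembled, reference)
    unannotated = [
        t for t in assembled if novelty[t.transcript_id] == "unannotated"
    ]
    unannotated_reg = [t for t in unannotated if t.gene_id in regulated
                       or t.transcript_id in regulated]
    reference_seqs = {
        t.transcript_id: transcript_sequence(t, genome) for t in reference
    }
    thresholds = TriageThresholds(orf_min=config.orf_min, tpm_detect=config.tpm_min)
    mean_tpm_all = table.tpm.mean(axis=1)
    calls = []
    funnel_k4me3 = funnel_active_expressed = 0
    for t in unannotated_reg:
        prom = promoter_of(t, config.promoter_upstream, config.promoter_downstream,
                           chrom_lengths.get(t.chrom))
        state = classify_promoter_state(prom, peaks["H3K4me3"], peaks["H3K27ac"])
        tpm = float(mean_tpm_all.get(t.gene_id, mean_tpm_all.get(t.transcript_id, 0.0)))
        if state != "unmarked":
            funnel_k4me3 += 1
            if state == "active" and tpm > config.tpm_min:
                funnel_active_expressed += 1
        calls.append(
            classify_novel_transcript(
                t, state, prom, peaks["H3K4me1"], peaks["H3K27ac"], tpm,
                reference, reference_seqs, genome, thresholds,
            )
        )
    transcripts_by_id = {t.transcript_id: t for t in unannotated_reg}
    mean_tpm_map = {tid: float(mean_tpm_all.get(tid, 0.0)) for tid in transcripts_by_id}
    calls = assign_names(calls, transcripts_by_id, mean_tpm_map)
    call_frame = pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "category": [c.category for c in calls],
            "assigned_name": [c.assigned_name for c in calls],
            "evidence": [json.dumps(c.evidence, sort_keys=True) for c in calls],
        }
    )
    call_frame.to_csv(outdir / "novelty_calls.tsv", sep="\t", index=False)
    cat_counts = call_frame["category"].value_counts().to_dict()
    n_lnc = cat_counts.get("lncRNA_antisense", 0) + cat_counts.get("lncRNA_intergenic", 0)
    report["stages"]["lncrna"] = {
        "unannotated_total": len(unannotated),
        "unannotated_regulated": len(unannotated_reg),
        "with_k4me3_promoter": funnel_k4me3,
        "active_and_expressed": funnel_active_expressed,
        "lncRNAs": n_lnc,
        "categories": cat_counts,
        "lncRNA_names": sorted(
            c.assigned_name for c in calls
            if c.category in ("lncRNA_antisense", "lncRNA_intergenic")
        ),
    }

    # --- gene-set overlap (optional) ----------------------------------------
    if config.suppressed_set or config.rescued_set:
        if config.universe_N is None:
            raise ConfigError(
                "universe_N is required for overlap tests and has no default"
            )
        sup = _read_gene_set(config.suppressed_set) if config.suppressed_set else set()
        res = _read_gene_set(config.rescued_set) if config.rescued_set else set()
        t_sup, t_res = rescue_set_test(reg_marked, sup, res, config.universe_N)
        report["stages"]["setstats"] = {
            "suppressed": {"k": t_sup.k, "n": t_sup.n, "K": t_sup.K,
                           "N": t_sup.N, "p_upper": t_sup.p_upper},
            "rescued": {"k": t_res.k, "n": t_res.n, "K": t_res.K,
                        "N": t_res.N, "p_upper": t_res.p_upper},
        }

    # --- single cells (optional) --------------------------------------------
    if config.cells_dir:
        d = Path(config.cells_dir)
        ds = CellDataset.read_mtx(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", d / "cells.tsv"
        )
        n_before = ds.n_cells
        ds = qc_filter(ds)
        if config.marker_gene in ds.adata.var_names:
            merge = merge_clusters_by_marker(ds, config.marker_gene,
                                             config.hi, config.lo)
            props, tests = cluster_condition_proportions(merge, ds)
            props.to_csv(outdir / "cluster_proportions.tsv", sep="\t")
            tests.to_csv(outdir / "proportion_tests.tsv", sep="\t", index=False)
            merged_counts = merge.cell_labels.value_counts().to_dict()
            report["stages"]["scmarkers"] = {
                "cells_before_qc": int(n_before),
                "cells_after_qc": int(ds.n_cells),
                "cluster_means": {k: float(v) for k, v in
                                  merge.cluster_means.items()},
                "merged_cells": {k: int(v) for k, v in merged_counts.items()},
            }
        else:
            log.warning("marker %s absent from cells; merge skipped",
                        config.marker_gene)

    report["funnel"] = [
        report["stages"]["lncrna"]["unannotated_regulated"],
        report["stages"]["lncrna"]["with_k4me3_promoter"],
        report["stages"]["lncrna"]["active_and_expressed"],
        report["stages"]["lncrna"]["lncRNAs"],
    ]
    report["runtime_s"] = round(time.time() - t0, 2)

    _audit(report, outdir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_summary(report, outdir / "summary.txt")
    return report


def _audit(report: dict, outdir: Path) -> None:
    """Re-derive headline counts from the emitted TSVs; raise on mismatch."""
    de = pd.read_csv(outdir / "de_results.tsv", sep="\t")
    if int(de["regulated"].sum()) != report["stages"]["diffexpr"]["regulated"]:
        raise RuntimeError("audit: regulated count disagrees with de_results.tsv")
    enh = pd.read_csv(outdir / "enhancers.tsv", sep="\t")
    if len(enh) != report["stages"]["enhancers"]["called"]:
        raise RuntimeError("audit: enhancer count disagrees with enhancers.tsv")
    if int(enh["effector"].sum()) != report["stages"]["enhancers"]["effectors"]:
        raise RuntimeError("audit: effector count disagrees with enhancers.tsv")
    calls = pd.read_csv(outdir / "novelty_calls.tsv", sep="\t")
    n_lnc = int(calls["category"].isin(["lncRNA_antisense", "lncRNA_intergenic"]).sum())
    if n_lnc != report["stages"]["lncrna"]["lncRNAs"]:
        raise RuntimeError("audit: lncRNA count disagrees with novelty_calls.tsv")
    report["audit"] = "passed"


def _write_summary(report: dict, path: Path) -> None:
    s = report["stages"]
    lines = [
        f"isletomics {report['version']} run summary",
        "",
        f"genes tested: {s['diffexpr']['genes_tested']}; regulated: "
        f"{s['diffexpr']['regulated']} ({s['diffexpr']['up']} up / "
        f"{s['diffexpr']['down']} down)",
        f"promoter states: {s['promoters']['states']}",
        f"regulated with H3K4me3 promoters: {s['promoters']['regulated_with_k4me3']}",
        f"enhancers called: {s['enhancers']['called']} "
        f"(by state {s['enhancers']['by_state']}); effectors: "
        f"{s['enhancers']['effectors']}",
        f"unannotated regulated funnel: {' -> '.join(str(x) for x in report['funnel'])}",
        f"lncRNA names: {', '.join(s['lncrna']['lncRNA_names']) or '(none)'}",
    ]
    if "scmarkers" in s:
        lines.append(
            f"cells: {s['scmarkers']['cells_before_qc']} -> "
            f"{s['scmarkers']['cells_after_qc']} after QC; merged "
            f"{s['scmarkers']['merged_cells']}"
        )
    lines.append(f"runtime: {report['runtime_s']} s")
    path.write_text("\n".join(lines) + "\n")
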