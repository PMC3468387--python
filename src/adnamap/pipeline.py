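"""End-to-end pipeline: QC -> filter -> profile -> divergence.

The toolkit never runs the aligner itself: ``bwa_params`` prints the
recommended command line and the pipeline consumes whatever SAM alignments
are supplied (real BWA output, or simulator truth SAM in testing).  Every
stage fails fast, naming itself, when an input is missing; all intermediate
outputs are written in standard formats and a JSON summary carries the
counts at every stage.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import io as adio
from .columns import reconstruct_columns
from .damage import accumulate_profile, cumulative_terminal_damage
from .divergence import estimate_divergence
from .hq_filter import (
    ContaminantMode,
    HitStatus,
    classify_against_contaminant,
    spurious_rate,
)
from .model import Platform
from .qc import QcConfig, QcSummary, qc_pass

logger = logging.getLogger("adnamap")


@dataclass
class PipelineConfig:
    platform: Platform = Platform.ILLUMINA
    reads: Optional[str] = None  # FASTQ/FASTA; optional (SAMs carry SEQ)
    target_sam: str = ""
    contaminant_sam: Optional[str] = None
    outgroup_sam: Optional[str] = None
    mapq_min: int = 25
    exclude_duplicates: bool = True
    best_hit: bool = False
    contaminant_mode: ContaminantMode = ContaminantMode.ANY_HIT
    run_qc: bool = False
    qc: QcConfig = field(default_factory=QcConfig)
    profile_window: int = 15
    bq_grid: tuple[int, ...] = (0, 10, 20, 25, 30, 35)
    end_masks: tuple[int, ...] = (0, 5)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "platform" in data:
            data["platform"] = Platform(data["platform"])
        if "contaminant_mode" in data:
            data["contaminant_mode"] = ContaminantMode(data["contaminant_mode"])
        if "qc" in data:
            data["qc"] = QcConfig(**data["qc"])
        for key in ("bq_grid", "end_masks"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(cfg: PipelineConfig, outdir: str) -> dict:
    """Run the full pipeline; returns (and writes) the JSON summary."""
    os.makedirs(outdir, exist_ok=True)
    summary: dict = {"platform": cfg.platform.value, "stages": {}}

    reads = None
    if cfg.reads is not None:
        adio.ensure_exists(cfg.reads, "reads")
        reads = list(adio.read_reads(cfg.reads, cfg.platform))
        summary["stages"]["reads_input"] = len(reads)
        if cfg.run_qc:
            qc_summary = QcSummary()
            reads = list(qc_pass(reads, cfg.qc, qc_summary))
            with open(os.path.join(outdir, "qc_summary.tsv"), "w") as handle:
                handle.write(qc_summary.to_tsv())
            summary["stages"]["reads_after_qc"] = qc_summary.n_passed
            logger.info("qc: %d/%d reads passed", qc_summary.n_passed, qc_summary.n_input)

    adio.ensure_exists(cfg.target_sam, "filter")
    target_hits = list(adio.read_sam(cfg.target_sam))
    summary["stages"]["target_alignments"] = len(target_hits)
    if cfg.contaminant_sam is not None:
        adio.ensure_exists(cfg.contaminant_sam, "filter")
        contaminant_hits = list(adio.read_sam(cfg.contaminant_sam))
    else:
        contaminant_hits = []
    classifications = classify_against_contaminant(
        target_hits,
        contaminant_hits,
        cfg.contaminant_mode,
        best_hit=cfg.best_hit,
        mapq_min=cfg.mapq_min,
        exclude_duplicates=cfg.exclude_duplicates,
    )
    by_status: dict[str, int] = {}
    for cls in classifications:
        by_status[cls.status.value] = by_status.get(cls.status.value, 0) + 1
    summary["stages"]["classification"] = by_status
    retained = {
        c.read_id for c in classifications if c.status is HitStatus.HQ_ENDOGENOUS
    }
    summary["stages"]["retained"] = len(retained)
    with open(os.path.join(outdir, "classifications.tsv"), "w") as handle:
        handle.write("read_id\tstatus\treason\ttarget_nm\tcontaminant_nm\n")
        for c in classifications:
            handle.write(
                f"{c.read_id}\t{c.status.value}\t{c.reason}\t"
                f"{'' if c.target_nm is None else c.target_nm}\t"
                f"{'' if c.contaminant_nm is None else c.contaminant_nm}\n"
            )
    with open(os.path.join(outdir, "retained_ids.txt"), "w") as handle:
        for rid in sorted(retained):
            handle.write(rid + "\n")
    logger.info("filter: retained %d of %d target alignments", len(retained), len(target_hits))

    if cfg.outgroup_sam is not None and reads is not None:
        adio.ensure_exists(cfg.outgroup_sam, "spurious-monitor")
        count, rate, hist = spurious_rate(reads, adio.read_sam(cfg.outgroup_sam), cfg.mapq_min)
        summary["stages"]["outgroup_hq_hits"] = {
            "count": count,
            "rate": rate,
            "length_histogram": {str(k): v for k, v in sorted(hist.items())},
        }

    read_index = {r.read_id: r for r in reads} if reads is not None else {}
    series = []
    for hit in target_hits:
        if hit.read_id not in retained or hit.md is None:
            continue
        series.append(reconstruct_columns(hit, read_index.get(hit.read_id)))
    table = accumulate_profile(series, window=cfg.profile_window)
    table.to_frame().to_csv(os.path.join(outdir, "misincorporation.tsv"), sep="\t", index=False)
    terminal = cumulative_terminal_damage(table, n_terminal=5)
    summary["stages"]["profile"] = {
        "reads_profiled": table.n_reads,
        "total_mismatches": table.total_mismatches(),
        "cumulative_terminal_gc_at": terminal,
        "damage_rate_5p_pos1": table.damage_rate(cfg.platform, pos=1, end="5p"),
    }

    if cfg.platform is Platform.ILLUMINA and series:
        rows = []
        with_quals = {
            (hit.read_id): quals
            for hit, quals in adio.read_sam_with_quals(cfg.target_sam)
            if quals is not None
        }
        qual_series = [
            reconstruct_columns(hit, qualities=with_quals[hit.read_id])
            for hit in target_hits
            if hit.read_id in retained and hit.md is not None and hit.read_id in with_quals
        ]
        for mask in cfg.end_masks:
            for bq in cfg.bq_grid:
                est = estimate_divergence(qual_series, bq, mask)
                if est is None:
                    continue
                rows.append(
                    f"{bq}\t{mask}\t{est.n_sites}\t{est.divergence:.6f}\t{est.gc_to_at_rate:.6f}"
                )
        with open(os.path.join(outdir, "divergence.tsv"), "w") as handle:
            handle.write("bq_threshold\tend_mask\tn_sites\tdivergence\tgc_to_at_rate\n")
            for row in rows:
                handle.write(row + "\n")
        summary["stages"]["divergence_rows"] = len(rows)

    with open(os.path.join(outdir, "summary.json"), "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary
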