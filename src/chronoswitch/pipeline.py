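"""End-to-end orchestration: ingest -> noise -> detect -> filter -> STP ->
consequences -> gene aggregation -> enrichment, with deterministic seeding
and a hashed output manifest.

The pipeline is a pure function of its configuration: rerunning with the
same config (including seed) produces bit-identical outputs. A single
global seed fans out to per-stage seeds through a fixed derivation so
stages can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from . import io_formats, switch_detection, stp_analysis, consequence, enrichment
from .io_formats import TimeCourseMatrix
from .switch_detection import SwitchThresholds

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline",
           "gene_expression_change", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed (stable across runs)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    quant_dir: str
    tx2gene: str
    out_dir: str
    gtf: str | None = None
    fasta: str | None = None
    domains: str | None = None
    gmt: str | None = None
    thresholds: SwitchThresholds = field(default_factory=SwitchThresholds)
    noise_amount: float = 2.0
    seed: int = 0
    use_smoothing: bool = True
    spline_degree: int = 4
    bin_width: float = 3.0
    stp_alpha: float = 1.0
    time_origin_offset: float = 0.0   # add to switch times in reports (e.g. ZT)
    cp_cutoff: float = consequence.CODING_POTENTIAL_CUTOFF
    length_similar_fraction: float = consequence.ORF_LENGTH_SIMILAR_FRACTION
    ora_p_max: float = 0.05
    ora_q_max: float = 0.2
    ora_top: int = 10
    zero_fill: bool = False
    strip_versions: bool = False


@dataclass
class PipelineReport:
    seed: int
    n_samples: int
    n_transcripts: int
    n_genes: int
    n_events_detected: int
    n_events_filtered: int
    n_stps: int
    stp_counts: list[int]
    n_switching_genes: int
    n_consequence_records: int
    n_enriched_sets: int
    manifest: dict[str, str]


def _write_tsv(path: Path, frame) -> str:
    frame.to_csv(path, sep="\t", index=False)
    return _sha256(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ingest(config: PipelineConfig) -> TimeCourseMatrix:
    quant_dir = Path(config.quant_dir)
    quants = sorted(quant_dir.glob("quant_t*.sf"))
    if not quants:
        raise FileNotFoundError(
            f"no quant_t*.sf files found in {quant_dir}"
        )
    tx2gene = io_formats.read_tx2gene(
        config.tx2gene, strip_versions=config.strip_versions
    )
    samples = []
    for q in quants:
        time = float(q.stem.split("quant_t")[1])
        samples.append((time, io_formats.read_quant_table(q)))
    return io_formats.assemble_time_course(
        samples, tx2gene, zero_fill=config.zero_fill
    )


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full switch-analysis flow, writing every intermediate table
    under ``config.out_dir`` plus a MANIFEST of content hashes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stage = "ingest"
    try:
        matrix = _ingest(config)
        hash_ = _write_tsv(out / "time_course.tsv", matrix.to_frame().reset_index())
        manifest["time_course.tsv"] = hash_
        logger.info("ingest: %d transcripts x %d times",
                    matrix.n_transcripts, matrix.times.size)

        stage = "noise"
        if config.noise_amount > 0:
            matrix = switch_detection.add_noise(
                matrix, config.noise_amount, stage_seed(config.seed, "noise")
            )

        stage = "detect"
        events = switch_detection.score_all_genes(
            matrix, use_smoothing=config.use_smoothing,
            degree=config.spline_degree,
        )
        logger.info("detect: %d candidate events", len(events))

        stage = "filter"
        filtered = switch_detection.filter_switches(events, config.thresholds)
        frame = switch_detection.events_to_frame(filtered)
        frame["switch_time_h"] += config.time_origin_offset
        manifest["switch_events.tsv"] = _write_tsv(out / "switch_events.tsv", frame)
        logger.info("filter: %d events pass", len(filtered))

        stage = "stp"
        hist = stp_analysis.bin_switch_times(
            filtered, bin_width=config.bin_width,
            origin=float(matrix.times[0]),
            t_max=float(matrix.times[-1]) + config.bin_width,
        )
        stps = stp_analysis.detect_stps(hist, alpha=config.stp_alpha)
        import pandas as pd

        hist_frame = pd.DataFrame({
            "bin_start_h": hist.bin_edges[:-1] + config.time_origin_offset,
            "bin_end_h": hist.bin_edges[1:] + config.time_origin_offset,
            "count": hist.counts,
        })
        manifest["switch_histogram.tsv"] = _write_tsv(
            out / "switch_histogram.tsv", hist_frame)
        stp_frame = pd.DataFrame({
            "rank": [s.rank for s in stps],
            "bin_start_h": [s.bin_start + config.time_origin_offset for s in stps],
            "bin_end_h": [s.bin_end + config.time_origin_offset for s in stps],
            "count": [s.count for s in stps],
        })
        manifest["stps.tsv"] = _write_tsv(out / "stps.tsv", stp_frame)
        logger.info("stp: %d peaks", len(stps))

        stage = "consequences"
        records: list[consequence.ConsequenceRecord] = []
        if config.gtf and config.fasta:
            models = {
                m.transcript_id: m
                for m in io_formats.load_gene_models(
                    config.gtf, config.fasta,
                    strip_versions=config.strip_versions,
                )
            }
            lib = (io_formats.read_domain_library(config.domains)
                   if config.domains else None)
            stp_events = [e for s in stps for e in s.members]
            summaries = {}
            for s in stps:
                stp_records = []
                for ev in s.members:
                    rec = consequence.classify_pair(
                        ev, models, lib,
                        cp_cutoff=config.cp_cutoff,
                        length_similar_fraction=config.length_similar_fraction,
                    )
                    if isinstance(rec, consequence.ConsequenceRecord):
                        stp_records.append(rec)
                    else:
                        logger.warning("skipped pair: %s", rec.reason)
                records.extend(stp_records)
                if stp_records:
                    summaries[s.name] = consequence.summarize_stp(stp_records)
            cons_frame = pd.DataFrame({
                "gene_id": [r.event.gene_id for r in records],
                "gained_iso": [r.gained_iso for r in records],
                "lost_iso": [r.lost_iso for r in records],
                "cp_class": [r.cp_class for r in records],
                "orf_class": [r.orf_class for r in records],
                "nmd_class": [r.nmd_class for r in records],
                "ir_class": [r.ir_class for r in records],
                "domains_gained": [",".join(r.domains_gained) for r in records],
                "domains_lost": [",".join(r.domains_lost) for r in records],
                "orf_similarity": [r.orf_similarity for r in records],
                "splice_events": [",".join(sorted(r.splice_events))
                                  for r in records],
            })
            manifest["consequences.tsv"] = _write_tsv(
                out / "consequences.tsv", cons_frame)
            summary_rows = []
            for name, summ in summaries.items():
                for axis, ax in summ.axes.items():
                    summary_rows.append({
                        "stp": name, "axis": axis, "gains": ax.gains,
                        "losses": ax.losses, "unchanged": ax.unchanged,
                        "p": ax.pvalue if ax.applicable else "NA",
                        "ci_low": ax.ci_low if ax.applicable else "NA",
                        "ci_high": ax.ci_high if ax.applicable else "NA",
                    })
            manifest["stp_summaries.tsv"] = _write_tsv(
                out / "stp_summaries.tsv", pd.DataFrame(summary_rows))

        stage = "aggregate"
        genes = enrichment.genes_with_switches(filtered)
        pd.DataFrame({"gene_id": sorted(genes)}).to_csv(
            out / "switching_genes.tsv", sep="\t", index=False)
        manifest["switching_genes.tsv"] = _sha256(out / "switching_genes.tsv")

        stage = "enrich"
        ora_results: list[enrichment.OraResult] = []
        if config.gmt:
            collection = io_formats.read_gmt(config.gmt)
            ora_results = enrichment.run_ora(
                genes, collection, p_max=config.ora_p_max,
                q_max=config.ora_q_max, top=config.ora_top,
            )
            ora_frame = pd.DataFrame({
                "set_id": [r.set_id for r in ora_results],
                "k": [r.k for r in ora_results],
                "K": [r.K for r in ora_results],
                "n": [r.n for r in ora_results],
                "N": [r.N for r in ora_results],
                "p": [r.p for r in ora_results],
                "p_adj": [r.p_adj for r in ora_results],
            })
            manifest["ora.tsv"] = _write_tsv(out / "ora.tsv", ora_frame)
    except Exception as exc:
        (out / "MANIFEST.json").write_text(json.dumps(
            {"complete": False, "failed_stage": stage, "outputs": manifest},
            indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = PipelineReport(
        seed=config.seed,
        n_samples=int(matrix.times.size),
        n_transcripts=matrix.n_transcripts,
        n_genes=len(matrix.genes()),
        n_events_detected=len(events),
        n_events_filtered=len(filtered),
        n_stps=len(stps),
        stp_counts=[s.count for s in stps],
        n_switching_genes=len(genes),
        n_consequence_records=len(records),
        n_enriched_sets=len(ora_results),
        manifest=manifest,
    )
    (out / "MANIFEST.json").write_text(json.dumps(
        {"complete": True, "seed": config.seed, "outputs": manifest},
        indent=2, sort_keys=True))
    return report


def gene_expression_change(
    matrix: TimeCourseMatrix, gene_id: str, t_start: float, t_end: float
) -> tuple[float, float, float]:
    """Cumulative gene TPM at two sampling times and the percent change.

    The gene's expression at a time point is the sum of its isoform TPMs;
    percent change is 100 * (end - start) / start. Large isoform-level
    reversals can coexist with a near-zero gene-level change, which is the
    bookkeeping this helper makes visible.
    """
    times = list(matrix.times)
    for t in (t_start, t_end):
        if t not in times:
            raise ValueError(f"time {t} is not a sampling time")
    isoforms = matrix.gene_transcripts(gene_id)
    if not isoforms:
        raise KeyError(f"unknown gene_id {gene_id!r}")
    j0, j1 = times.index(t_start), times.index(t_end)
    idx = [matrix.transcript_ids.index(tx) for tx in isoforms]
    tpm_start = float(matrix.values[idx, j0].sum())
    tpm_end = float(matrix.values[idx, j1].sum())
    if tpm_start == 0:
        raise ZeroDivisionError("gene has zero TPM at the start time")
    pct = 100.0 * (tpm_end - tpm_start) / tpm_start
    return tpm_start, tpm_end, pct
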