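"""Single-execution orchestration: read -> filter -> metrics -> dashboard.

The stages run in a fixed order; each logs its inputs and counts. On any
stage failure the partially written outputs are removed and the error is
re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import enrichment, filters, io, library, profiling, ranking, xcor
from .model import GenomicInterval, OccuqcError, TagSet

logger = logging.getLogger("occuqc")


@dataclass
class RunConfig:
    """Resolved inputs and parameters for one QC run."""

    reads: str
    peaks: str
    genes: Optional[str] = None
    out_dir: str = "occuqc_out"
    normalized_peaks: Optional[str] = None
    control_reads: Optional[str] = None
    blacklist: Optional[str] = None
    fastq: Optional[str] = None
    chrom_sizes: Optional[str] = None          # 2-column TSV, for tag BED input
    min_mapq: int = io.DEFAULT_MIN_MAPQ
    shift_lo: int = xcor.DEFAULT_SHIFT_LO
    shift_hi: int = xcor.DEFAULT_SHIFT_HI
    shift_step: int = xcor.DEFAULT_SHIFT_STEP
    stitch_gap: int = enrichment.DEFAULT_STITCH_GAP
    promoter_half: int = profiling.DEFAULT_PROMOTER_HALF
    window_half: int = profiling.DEFAULT_WINDOW_HALF
    matrix_half_window: int = profiling.DEFAULT_MATRIX_HALF_WINDOW
    matrix_bin: int = profiling.DEFAULT_MATRIX_BIN
    body_bins: int = profiling.DEFAULT_BODY_BINS
    flank: int = profiling.DEFAULT_FLANK
    flank_bin: int = profiling.DEFAULT_FLANK_BIN
    coverage_mode: str = "extend"
    fastq_max_records: int = io.DEFAULT_FASTQ_MAX_RECORDS
    prefix: str = "occuqc"
    plots: bool = False

    def validate(self) -> None:
        for label, path in (("reads", self.reads), ("peaks", self.peaks),
                            ("genes", self.genes),
                            ("normalized-peaks", self.normalized_peaks),
                            ("control-reads", self.control_reads),
                            ("blacklist", self.blacklist),
                            ("fastq", self.fastq),
                            ("chrom-sizes", self.chrom_sizes)):
            if path is not None and not Path(path).exists():
                raise OccuqcError(f"missing {label} file: {path}")
        if self.stitch_gap < 0:
            raise ValueError("stitch_gap must be >= 0")


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")[:2]
        out[chrom] = int(size)
    return out


@dataclass
class RunResult:
    panel: ranking.MetricPanel
    values: dict
    out_dir: Path
    tsv_path: Path
    html_path: Path


def _load_tags(path: str, min_mapq: int,
               chrom_sizes: Optional[dict[str, int]]) -> TagSet:
    return io.read_alignments(path, min_mapq=min_mapq,
                              chrom_sizes=chrom_sizes)


def _write_matrix(matrix: profiling.CoverageMatrix, path: Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6g",
                             index_label="gene_id")


def _write_stitched_bed(region_set: enrichment.StitchedRegionSet,
                        path: Path) -> None:
    """BED6+3: name, signal as score, strand '.', then member_peaks,
    signal, is_super."""
    with open(path, "wt") as fh:
        for r in sorted(region_set.regions,
                        key=lambda r: (r.interval.chrom, r.interval.start)):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_rank{r.rank}\t"
                f"{r.signal:.4f}\t.\t{r.member_peaks}\t{r.signal:.4f}\t"
                f"{int(r.is_super)}\n")


def run_all(config: RunConfig) -> RunResult:
    """Execute the full QC pipeline; see module docstring for stage order."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        params = emit(out_dir / "params.json")
        params.write_text(json.dumps(asdict(config), indent=2) + "\n")

        stage = "read"
        sizes = (read_chrom_sizes(config.chrom_sizes)
                 if config.chrom_sizes else None)
        tags = _load_tags(config.reads, config.min_mapq, sizes)
        logger.info("read: %d raw, %d mapped tags on %d chromosomes",
                    tags.total_raw, tags.total_mapped, len(tags.chroms))

        stage = "fastq"
        fastq_stats = None
        if config.fastq:
            fastq_stats = io.read_fastq_stats(config.fastq,
                                              config.fastq_max_records)
            logger.info("fastq: %d reads sampled, mean length %.1f",
                        fastq_stats.n_sampled, fastq_stats.mean_read_length)

        stage = "library-metrics"
        values: dict = {}
        values["R"] = tags.total_raw
        values["A"] = library.aligned_percent(tags.total_raw,
                                              tags.total_mapped)
        values["NRF"] = library.compute_nrf(tags)
        values["C"] = library.compute_pbc(tags)
        values["B"] = library.base_quality_flag(fastq_stats)
        values["D"] = library.diversity_flag(fastq_stats)
        values["read_length"] = (fastq_stats.mean_read_length
                                 if fastq_stats else tags.mean_read_length())

        stage = "filter"
        blacklist: list[GenomicInterval] = []
        if config.blacklist:
            blacklist = io.read_peaks(config.blacklist)
        tags_dedup, dup_report = filters.remove_duplicates(tags)
        tags_clean, bl_report = filters.filter_blacklist(tags_dedup, blacklist)
        logger.info("filter: %d in, %d duplicates, %d blacklisted, %d out",
                    dup_report.input_tags, dup_report.duplicates_removed,
                    bl_report.blacklisted_removed, tags_clean.n_tags)
        values["_filter"] = {
            "input_tags": dup_report.input_tags,
            "duplicates_removed": dup_report.duplicates_removed,
            "blacklisted_removed": bl_report.blacklisted_removed,
            "output_tags": tags_clean.n_tags,
        }

        stage = "xcor"
        mean_rl = tags_clean.mean_read_length()
        profile = xcor.analyze(tags_clean, mean_rl, config.shift_lo,
                               config.shift_hi, config.shift_step)
        values["fragment_width"] = profile.fragment_width
        values["E"] = xcor.tag_length_delta(profile.predicted_tag_length,
                                            mean_rl)
        values["NSC"] = xcor.compute_nsc(profile)
        values["RSC"] = xcor.compute_rsc(profile)
        xcor_path = emit(out_dir / f"{config.prefix}-xcor.tsv")
        pd.DataFrame({"shift": profile.shifts, "cc": profile.cc}).to_csv(
            xcor_path, sep="\t", index=False, float_format="%.6g")
        logger.info("xcor: fragment width %d bp, NSC %s, RSC %s",
                    profile.fragment_width, values["NSC"], values["RSC"])

        stage = "enrichment"
        peaks = filters.filter_peaks_blacklist(io.read_peaks(config.peaks),
                                               blacklist)
        values["P"] = enrichment.count_peaks(peaks)
        norm_peaks = None
        if config.normalized_peaks:
            norm_peaks = filters.filter_peaks_blacklist(
                io.read_peaks(config.normalized_peaks), blacklist)
        values["N"] = enrichment.count_normalized_peaks(norm_peaks)
        control = None
        if config.control_reads:
            raw_control = _load_tags(config.control_reads, config.min_mapq,
                                     sizes)
            control, _ = filters.remove_duplicates(raw_control)
            control, _ = filters.filter_blacklist(control, blacklist)
        values["F"] = enrichment.compute_frip(tags_clean, peaks)
        region_set = enrichment.stitch_and_classify(
            peaks, tags_clean, control, config.stitch_gap)
        values["L"] = region_set.n_regions
        values["SE"] = region_set.n_super
        values["S"] = enrichment.s_ratio(region_set)
        _write_stitched_bed(region_set,
                            emit(out_dir / f"{config.prefix}-stitched.bed"))
        logger.info("enrichment: %d peaks, FRiP %.4f, %d regions "
                    "(%d super)", values["P"], values["F"] or 0.0,
                    values["L"], values["SE"])

        stage = "profiling"
        if config.genes:
            genes = io.read_genes(config.genes)
            frag = profile.fragment_width or 200
            pm = profiling.promoter_matrix(
                tags_clean, genes, config.matrix_half_window,
                config.matrix_bin, config.coverage_mode, frag)
            mm = profiling.metagene_matrix(
                tags_clean, genes, config.body_bins, config.flank,
                config.flank_bin, config.coverage_mode, frag)
            _write_matrix(pm, emit(out_dir / f"{config.prefix}-promoter-matrix.tsv"))
            _write_matrix(mm, emit(out_dir / f"{config.prefix}-metagene-matrix.tsv"))
            for name, mat in (("promoter", pm), ("metagene", mm)):
                prof = profiling.average_profile(mat)
                path = emit(out_dir / f"{config.prefix}-{name}-profile.tsv")
                pd.DataFrame({"bin": mat.bin_labels, "density": prof}).to_csv(
                    path, sep="\t", index=False, float_format="%.6g")
            dist = profiling.annotate_peaks(peaks, genes,
                                            config.promoter_half,
                                            config.window_half)
            profiling.annotation_table(dist).to_csv(
                emit(out_dir / f"{config.prefix}-annotation-summary.tsv"),
                sep="\t", index=False, float_format="%.6g")
            dist.per_peak.to_csv(
                emit(out_dir / f"{config.prefix}-peak-annotation.tsv"),
                sep="\t", index=False)
            if config.plots:
                profiling.plot_profile(
                    pm, str(emit(out_dir / f"{config.prefix}-promoter-profile.png")),
                    "Promoter profile")
                profiling.plot_heatmap(
                    pm, str(emit(out_dir / f"{config.prefix}-promoter-heatmap.png")),
                    "Promoter coverage")
            logger.info("profiling: %d genes, annotation %s",
                        len(genes), dist.counts)

        stage = "dashboard"
        panel_values = {k: v for k, v in values.items()
                        if not k.startswith("_")}
        panel = ranking.build_panel(panel_values)
        emit(out_dir / f"{config.prefix}-metrics.json").write_text(
            json.dumps(panel_values, indent=2, default=float) + "\n")
        tsv, html = ranking.render_report(panel, out_dir, config.prefix)
        emit(tsv)
        emit(html)
        logger.info("dashboard: overall Q %.3f (%s)", panel.overall_q,
                    panel.overall_rank.label)
        return RunResult(panel, values, out_dir, tsv, html)
    except Exception as exc:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise OccuqcError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
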