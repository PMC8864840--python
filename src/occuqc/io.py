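"""Readers and writers for the standard formats the toolkit touches.

BED and GTF are read with explicit line-numbered error reporting; SAM/BAM
goes through pysam. Everything is converted to the internal 0-based
half-open convention at the boundary.
"""

from __future__ import annotations

import gzip
import logging
import re
from collections import Counter
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam

from .model import GeneModel, GenomicInterval, ParseError, TagSet

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_MIN_MAPQ = 10
DEFAULT_FASTQ_MAX_RECORDS = 1_000_000


def _open_text(path: PathLike) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# BED

def read_peaks(path: PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals, preserving record order.

    Column 4 is stored as name, column 5 as score when present. Raises
    :class:`ParseError` naming the line number on malformed records.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            out.append(
                GenomicInterval(fields[0], start, end, strand=strand,
                                name=name, score=score)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write intervals as BED; emits up to 6 columns as fields are present."""
    with open(path, "wt") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name or iv.score is not None or iv.strand != ".":
                cols.append(iv.name or ".")
            if iv.score is not None or iv.strand != ".":
                cols.append("." if iv.score is None else format(iv.score, "g"))
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GTF

_GENE_ID_RE = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_genes(path: PathLike) -> list[GeneModel]:
    """Read gene models from a GTF file.

    One :class:`GeneModel` per distinct gene_id, built from its ``gene``
    feature or, when absent, from the union span of its transcripts.
    GTF 1-based inclusive coordinates become 0-based half-open. Records
    with strand "." are skipped (counted in a warning).
    """
    gene_spans: dict[str, tuple[str, str, int, int, bool]] = {}
    order: list[str] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: fewer than 9 columns")
            chrom, _source, feature, start_s, end_s, _score, strand = fields[:7]
            if feature not in ("gene", "transcript", "mRNA", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if strand == ".":
                skipped += 1
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            m = _GENE_ID_RE.search(fields[8])
            if not m:
                raise ParseError(f"{path}: line {lineno}: missing gene_id")
            gene_id = m.group(1)
            start, end = start1 - 1, end1  # 1-based inclusive -> half-open
            is_gene = feature == "gene"
            cur = gene_spans.get(gene_id)
            if cur is None:
                gene_spans[gene_id] = (chrom, strand, start, end, is_gene)
                order.append(gene_id)
            else:
                c, s, lo, hi, have_gene = cur
                if is_gene and not have_gene:
                    gene_spans[gene_id] = (chrom, strand, start, end, True)
                elif is_gene == have_gene:
                    gene_spans[gene_id] = (c, s, min(lo, start), max(hi, end),
                                           have_gene)
    if skipped:
        logger.warning("read_genes: skipped %d unstranded records", skipped)
    if not gene_spans:
        raise ParseError(f"{path}: no usable gene/transcript features")
    return [
        GeneModel(gid, chrom, strand,
                  GenomicInterval(chrom, start, end, strand=strand, name=gid))
        for gid, (chrom, strand, start, end, _) in
        ((g, gene_spans[g]) for g in order)
    ]


def write_genes_gtf(genes: Iterable[GeneModel], path: PathLike,
                    source: str = "occuqc") -> None:
    """Write gene models as minimal GTF ``gene`` features."""
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}"
                f"\t.\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )


# ---------------------------------------------------------------------------
# Alignments

def read_alignments(
    path: PathLike,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> TagSet:
    """Load single-end tags from SAM/BAM or a 6-column tag BED.

    For SAM/BAM: unmapped, secondary and supplementary records are excluded
    from the tags but counted in ``total_raw``; reads below ``min_mapq``
    are dropped entirely. The 5' position is the leftmost coordinate for
    + reads and the rightmost aligned base for − reads. ``total_mapped``
    is the number of retained tags.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".gz") and not _looks_like_sam(path):
        return _read_tag_bed(path, chrom_sizes)
    return _read_sam(path, min_mapq)


def _looks_like_sam(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith((".sam", ".bam", ".sam.gz"))


def _read_sam(path: Path, min_mapq: int) -> TagSet:
    rows: dict[str, list[tuple[int, int, int]]] = {}
    total_raw = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        sizes = dict(zip(af.references or (), af.lengths or ()))
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                total_raw += 1
                continue
            total_raw += 1
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if rec.is_reverse:
                pos5 = rec.reference_end - 1
                strand = 1
            else:
                pos5 = rec.reference_start
                strand = 0
            rlen = rec.query_length or rec.infer_read_length() or (
                rec.reference_end - rec.reference_start)
            rows.setdefault(chrom, []).append((pos5, strand, rlen))
    if not sizes:
        logger.warning("%s: no sequence lengths in header; inferring from "
                       "max coordinate", path)
        sizes = {c: max(p for p, _, _ in r) + 1 for c, r in rows.items()}
    n_tags = sum(len(r) for r in rows.values())
    ts = TagSet(sizes, total_raw=total_raw, total_mapped=n_tags)
    for chrom, r in rows.items():
        arr = np.asarray(r, dtype=np.int64)
        ts._set_chrom(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    return ts


def _read_tag_bed(path: Path, chrom_sizes: Optional[dict[str, int]]) -> TagSet:
    rows: dict[str, list[tuple[int, int, int]]] = {}
    n = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: tag BED requires 6 columns "
                    "(strand missing)"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            strand = fields[5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if strand == "+":
                pos5, code = start, 0
            elif strand == "-":
                pos5, code = end - 1, 1
            else:
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            rows.setdefault(chrom, []).append((pos5, code, end - start))
            n += 1
    if chrom_sizes is None:
        logger.warning("%s: no chromosome sizes given; inferring from max "
                       "coordinate", path)
        chrom_sizes = {c: max(p for p, _, _ in r) + 1 for c, r in rows.items()}
    ts = TagSet(chrom_sizes, total_raw=n, total_mapped=n)
    for chrom, r in rows.items():
        arr = np.asarray(r, dtype=np.int64)
        ts._set_chrom(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    ts._check()
    return ts


def write_tag_bed(tags: TagSet, path: PathLike) -> None:
    """Write a TagSet as 6-column tag BED (inverse of the BED reader)."""
    with open(path, "wt") as fh:
        i = 0
        for chrom, pos5, strand, rlen in tags.iter_tags():
            if strand == "+":
                start, end = pos5, pos5 + rlen
            else:
                start, end = pos5 - rlen + 1, pos5 + 1
            start = max(start, 0)
            fh.write(f"{chrom}\t{start}\t{end}\ttag{i}\t0\t{strand}\n")
            i += 1


# ---------------------------------------------------------------------------
# FASTQ

class FastqStats:
    """Read-level summaries: per-cycle quality quartiles, exact-sequence
    frequency table, mean read length."""

    def __init__(self, per_cycle: pd.DataFrame, seq_freq: pd.Series,
                 mean_read_length: float, n_sampled: int) -> None:
        self.per_cycle = per_cycle          # columns: mean, median, lower_quartile, n
        self.seq_freq = seq_freq            # sequence -> fraction of sampled reads
        self.mean_read_length = mean_read_length
        self.n_sampled = n_sampled


def _hist_quantile(cum: np.ndarray, total: int, q: float) -> int:
    """Lower-interpolation quantile from a cumulative histogram."""
    rank = int(np.ceil(q * total))
    return int(np.searchsorted(cum, max(rank, 1)))


def read_fastq_stats(
    path: PathLike, max_records: int = DEFAULT_FASTQ_MAX_RECORDS
) -> FastqStats:
    """Summarize the first ``max_records`` reads of a Phred+33 FASTQ.

    Returns per-cycle mean/median/lower-quartile quality, an
    exact-sequence frequency table and the mean read length. Raises
    :class:`ParseError` naming the record index on truncation.
    """
    max_q = 94
    hist = np.zeros((0, max_q), dtype=np.int64)  # [cycle, quality] counts
    seq_counts: Counter = Counter()
    total_len = 0
    n = 0
    with _open_text(path) as fh:
        while n < max_records:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ParseError(f"{path}: truncated FASTQ record {n + 1}")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {n + 1}: sequence/quality length mismatch")
            seq_counts[seq] += 1
            total_len += len(seq)
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int64) - 33
            if q.size > hist.shape[0]:
                hist = np.vstack(
                    [hist, np.zeros((q.size - hist.shape[0], max_q), np.int64)])
            np.add.at(hist, (np.arange(q.size), np.clip(q, 0, max_q - 1)), 1)
            n += 1
    if n == 0:
        raise ParseError(f"{path}: empty FASTQ")
    rows = []
    qvals = np.arange(max_q, dtype=float)
    for cycle in range(hist.shape[0]):
        counts = hist[cycle]
        m = counts.sum()
        cum = np.cumsum(counts)
        rows.append({
            "cycle": cycle + 1,
            "mean": float((counts * qvals).sum() / m),
            "median": float(_hist_quantile(cum, m, 0.5)),
            "lower_quartile": float(_hist_quantile(cum, m, 0.25)),
            "n": int(m),
        })
    per_cycle = pd.DataFrame(rows).set_index("cycle")
    freq = pd.Series(seq_counts, dtype=float) / n
    freq = freq.sort_values(ascending=False)
    return FastqStats(per_cycle, freq, total_len / n, n)
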