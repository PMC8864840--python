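"""Promoter and metagene coverage profiling, and peak annotation.

Coverage matrices are per-gene, per-bin tag densities in tags-per-million
per bp. Rows of − strand genes are orientation-flipped so bin 1 is always
the 5' side. Tag contribution is either the bare 5' position ("point") or
the fragment-extended footprint ("extend", the default) — extension is
what makes promoter profiles reflect occupancy rather than read ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import GeneModel, GenomicInterval, OccuqcError, TagSet

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_HALF = 1_000       # promoter = TSS +/- 1 kb
DEFAULT_WINDOW_HALF = 10_000        # gene-centric window = TSS +/- 10 kb
DEFAULT_MATRIX_HALF_WINDOW = 2_000
DEFAULT_MATRIX_BIN = 50
DEFAULT_BODY_BINS = 100
DEFAULT_FLANK = 2_000
DEFAULT_FLANK_BIN = 50


@dataclass
class CoverageMatrix:
    """Per-gene, per-bin tag densities; NaN marks truncated/missing bins."""

    row_ids: list[str]
    bin_labels: list[str]
    values: np.ndarray              # shape (genes, bins), TPM per bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.bin_labels)


@dataclass
class AnnotationDistribution:
    """Peak counts per genic category plus per-peak nearest-gene calls."""

    counts: dict[str, int]          # promoter / gene_body / gene_window / intergenic
    per_peak: pd.DataFrame          # peak, category, nearest_gene, distance

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# coverage substrate

def _chrom_coverage(tags: TagSet, chrom: str, mode: str,
                    fragment_length: int) -> np.ndarray:
    """Per-bp tag coverage for one chromosome.

    point: 1 count at each 5' position. extend: 1 count at every bp of the
    fragment extended ``fragment_length`` bp 3'-ward from the 5' end.
    """
    length = tags.chrom_sizes[chrom]
    if chrom not in tags.chroms:
        return np.zeros(length, dtype=np.float64)
    pos, strand, _ = tags.arrays(chrom)
    if mode == "point":
        return np.bincount(pos, minlength=length).astype(np.float64)
    if mode != "extend":
        raise ValueError(f"unknown coverage mode {mode!r}")
    starts = np.where(strand == 0, pos, pos - fragment_length + 1)
    ends = starts + fragment_length
    starts = np.clip(starts, 0, length)
    ends = np.clip(ends, 0, length)
    diff = np.zeros(length + 1, dtype=np.float64)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, ends, -1.0)
    return np.cumsum(diff)[:length]


def _prefix_sums(tags: TagSet, mode: str, fragment_length: int
                 ) -> dict[str, np.ndarray]:
    """chrom -> prefix sums S with S[i] = coverage on [0, i)."""
    out = {}
    for chrom in tags.chrom_sizes:
        cov = _chrom_coverage(tags, chrom, mode, fragment_length)
        S = np.zeros(cov.size + 1, dtype=np.float64)
        np.cumsum(cov, out=S[1:])
        out[chrom] = S
    return out


def _bin_counts(S: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Tag counts per bin from prefix sums; edges clipped to the chromosome,
    fully out-of-range bins yield NaN."""
    length = S.size - 1
    clipped = np.clip(edges, 0, length)
    counts = S[clipped[1:]] - S[clipped[:-1]]
    widths = clipped[1:] - clipped[:-1]
    counts = counts.astype(float)
    counts[widths <= 0] = np.nan
    return counts


def _densities(counts: np.ndarray, widths: np.ndarray, total_tags: int
               ) -> np.ndarray:
    """TPM per bp; truncated bins use their truncated width."""
    scale = 1e6 / total_tags if total_tags else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts * scale / widths


def _effective_widths(edges: np.ndarray, length: int) -> np.ndarray:
    clipped = np.clip(edges, 0, length)
    return (clipped[1:] - clipped[:-1]).astype(float)


# ---------------------------------------------------------------------------
# matrices

def promoter_matrix(tags: TagSet, genes: Sequence[GeneModel],
                    half_window: int = DEFAULT_MATRIX_HALF_WINDOW,
                    bin: int = DEFAULT_MATRIX_BIN,
                    mode: str = "extend",
                    fragment_length: int = 200) -> CoverageMatrix:
    """Fixed-width binned density across [TSS − half_window, TSS + half_window)
    for every gene, strand-flipped so bin 1 is upstream."""
    if not genes:
        raise OccuqcError("promoter_matrix: no genes")
    if half_window % bin:
        raise ValueError("half_window must be a multiple of bin")
    n_bins = 2 * half_window // bin
    prefix = _prefix_sums(tags, mode, fragment_length)
    total = tags.n_tags
    values = np.full((len(genes), n_bins), np.nan)
    for i, g in enumerate(genes):
        S = prefix.get(g.chrom)
        if S is None:
            continue
        length = S.size - 1
        edges = g.tss - half_window + np.arange(n_bins + 1) * bin
        counts = _bin_counts(S, edges)
        widths = _effective_widths(edges, length)
        row = _densities(counts, widths, total)
        if g.strand == "-":
            row = row[::-1]
        values[i] = row
    labels = [f"{(k - n_bins // 2) * bin}" for k in range(n_bins)]
    return CoverageMatrix([g.gene_id for g in genes], labels, values)


def metagene_matrix(tags: TagSet, genes: Sequence[GeneModel],
                    body_bins: int = DEFAULT_BODY_BINS,
                    flank: int = DEFAULT_FLANK,
                    flank_bin: int = DEFAULT_FLANK_BIN,
                    mode: str = "extend",
                    fragment_length: int = 200) -> CoverageMatrix:
    """Length-normalized gene-body profile with fixed-bp flanks.

    The body is rescaled into ``body_bins`` equal-fraction bins; per-bp
    density makes the rescaling length-fair. Genes shorter than
    ``body_bins`` bp are skipped (with a warning count).
    """
    if flank % flank_bin:
        raise ValueError("flank must be a multiple of flank_bin")
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    prefix = _prefix_sums(tags, mode, fragment_length)
    total = tags.n_tags
    rows = []
    row_ids = []
    skipped = 0
    for g in genes:
        if g.body.length < body_bins:
            skipped += 1
            continue
        S = prefix.get(g.chrom)
        if S is None:
            continue
        length = S.size - 1
        body_edges = g.body.start + np.round(
            np.linspace(0, g.body.length, body_bins + 1)).astype(np.int64)
        up_edges = g.body.start - flank + np.arange(n_flank + 1) * flank_bin
        down_edges = g.body.end + np.arange(n_flank + 1) * flank_bin
        edges = np.concatenate([up_edges, body_edges[1:], down_edges[1:]])
        counts = _bin_counts(S, edges)
        widths = _effective_widths(edges, length)
        row = _densities(counts, widths, total)
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        row_ids.append(g.gene_id)
    if skipped:
        logger.warning("metagene_matrix: skipped %d genes shorter than "
                       "%d bp", skipped, body_bins)
    if not rows:
        raise OccuqcError("metagene_matrix: no usable genes")
    labels = (
        [f"up{-flank + k * flank_bin}" for k in range(n_flank)]
        + [f"body{k + 1}" for k in range(body_bins)]
        + [f"down{k * flank_bin}" for k in range(n_flank)]
    )
    return CoverageMatrix(row_ids, labels, np.asarray(rows))


def average_profile(matrix: CoverageMatrix) -> np.ndarray:
    """Column-wise mean density; truncated (NaN) bins are excluded from
    their column's mean."""
    if matrix.values.size == 0:
        raise OccuqcError("average_profile: empty matrix")
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix.values, axis=0)


# ---------------------------------------------------------------------------
# peak annotation

CATEGORIES = ("promoter", "gene_body", "gene_window", "intergenic")


def annotate_peaks(peaks: Sequence[GenomicInterval],
                   genes: Sequence[GeneModel],
                   promoter_half: int = DEFAULT_PROMOTER_HALF,
                   window_half: int = DEFAULT_WINDOW_HALF
                   ) -> AnnotationDistribution:
    """Assign each peak one genic category by precedence
    promoter > gene body > gene-centric window > intergenic
    (interval overlap >= 1 bp), plus its nearest gene by TSS distance.

    The nearest-gene distance is 0 when that gene's TSS lies inside the
    peak, else the signed genomic offset (peak midpoint − TSS).
    """
    if not genes:
        raise OccuqcError("annotate_peaks: no genes")
    trees: dict[str, dict[str, IntervalTree]] = {
        "promoter": {}, "gene_body": {}, "gene_window": {}}
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        pstart = max(0, g.tss - promoter_half)
        wstart = max(0, g.tss - window_half)
        trees["promoter"].setdefault(g.chrom, IntervalTree()).addi(
            pstart, g.tss + promoter_half, g.gene_id)
        trees["gene_body"].setdefault(g.chrom, IntervalTree()).addi(
            g.body.start, g.body.end, g.gene_id)
        trees["gene_window"].setdefault(g.chrom, IntervalTree()).addi(
            wstart, g.tss + window_half, g.gene_id)
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    tss_arrays = {
        chrom: (np.asarray([t for t, _ in sorted(items)]),
                [gid for _, gid in sorted(items)])
        for chrom, items in tss_by_chrom.items()
    }
    counts = {c: 0 for c in CATEGORIES}
    records = []
    for peak in peaks:
        category = "intergenic"
        for cat in ("promoter", "gene_body", "gene_window"):
            tree = trees[cat].get(peak.chrom)
            if tree is not None and tree.overlap(peak.start, peak.end):
                category = cat
                break
        counts[category] += 1
        nearest_gene, distance = _nearest_tss(peak, tss_arrays)
        records.append({
            "chrom": peak.chrom, "start": peak.start, "end": peak.end,
            "name": peak.name, "category": category,
            "nearest_gene": nearest_gene, "distance": distance,
        })
    return AnnotationDistribution(counts, pd.DataFrame(records))


def _nearest_tss(peak: GenomicInterval,
                 tss_arrays: dict[str, tuple[np.ndarray, list[str]]]
                 ) -> tuple[Optional[str], Optional[int]]:
    entry = tss_arrays.get(peak.chrom)
    if entry is None:
        return None, None
    positions, gene_ids = entry
    mid = peak.midpoint
    i = int(np.argmin(np.abs(positions - mid)))
    tss = int(positions[i])
    distance = 0 if peak.start <= tss < peak.end else mid - tss
    return gene_ids[i], int(distance)


def annotation_table(dist: AnnotationDistribution) -> pd.DataFrame:
    """Category / count / fraction summary table."""
    total = dist.total
    return pd.DataFrame({
        "category": list(CATEGORIES),
        "count": [dist.counts[c] for c in CATEGORIES],
        "fraction": [dist.counts[c] / total if total else float("nan")
                     for c in CATEGORIES],
    })


# ---------------------------------------------------------------------------
# optional plotting (thin layer over the matrices)

def plot_profile(matrix: CoverageMatrix, path: str, title: str = "") -> None:
    """Line plot of the average profile; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = average_profile(matrix)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(np.arange(prof.size), prof, lw=1.5)
    ax.set_xlabel("bin")
    ax.set_ylabel("density (TPM/bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(matrix: CoverageMatrix, path: str, title: str = "") -> None:
    """Per-gene heatmap, rows sorted by total density; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with np.errstate(invalid="ignore"):
        order = np.argsort(np.nansum(matrix.values, axis=1))[::-1]
    fig, ax = plt.subplots(figsize=(5, 6))
    ax.imshow(matrix.values[order], aspect="auto", interpolation="nearest",
              cmap="Reds")
    ax.set_xlabel("bin")
    ax.set_ylabel("gene")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
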