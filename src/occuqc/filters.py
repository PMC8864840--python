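"""Redundant-read removal and blacklist filtering.

Filter order is fixed pipeline-wide: duplicates first, then blacklist, so
library-complexity metrics (computed pre-filtering) never depend on the
blacklist supplied.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import FilterReport, GenomicInterval, TagSet


def remove_duplicates(tags: TagSet) -> tuple[TagSet, FilterReport]:
    """Keep at most one tag per (chrom, 5' position, strand) key.

    The retained tag is the first encountered in input order; read length
    is not part of the key (single-end tag semantics).
    """
    keep: dict[str, np.ndarray] = {}
    n_in = tags.n_tags
    n_out = 0
    for chrom, key in tags.keys().items():
        _, first_idx = np.unique(key, return_index=True)
        mask = np.zeros(key.size, dtype=bool)
        mask[first_idx] = True
        keep[chrom] = mask
        n_out += first_idx.size
    out = tags.subset(keep)
    return out, FilterReport(input_tags=n_in, duplicates_removed=n_in - n_out)


def _interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted, merged (starts, ends) arrays."""
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in per.items():
        pairs.sort()
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def points_in_intervals(
    pos: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Boolean mask: which positions fall in the merged half-open intervals."""
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = idx >= 0
    inside[inside] &= pos[inside] < ends[idx[inside]]
    return inside


def filter_blacklist(
    tags: TagSet, blacklist: Sequence[GenomicInterval]
) -> tuple[TagSet, FilterReport]:
    """Drop tags whose 5' position lies within any blacklist interval.

    The test is half-open on the interval end and ignores strand; the read
    footprint beyond the 5' base is not considered (tags are the unit of
    every downstream metric).
    """
    n_in = tags.n_tags
    if not blacklist:
        return tags.subset({}), FilterReport(input_tags=n_in)
    bl = _interval_arrays(blacklist)
    keep: dict[str, np.ndarray] = {}
    removed = 0
    for chrom in tags.chroms:
        pos, _, _ = tags.arrays(chrom)
        if chrom not in bl:
            continue
        starts, ends = bl[chrom]
        inside = points_in_intervals(pos, starts, ends)
        keep[chrom] = ~inside
        removed += int(inside.sum())
    out = tags.subset(keep)
    return out, FilterReport(input_tags=n_in, blacklisted_removed=removed)


def filter_peaks_blacklist(
    peaks: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    if not blacklist:
        return list(peaks)
    bl = _interval_arrays(blacklist)
    out = []
    for peak in peaks:
        entry = bl.get(peak.chrom)
        if entry is not None:
            starts, ends = entry
            # overlap iff some blacklist interval starts before the peak end
            # and ends after the peak start
            i = np.searchsorted(starts, peak.end, side="left")
            if i > 0 and np.any(ends[:i] > peak.start):
                continue
        out.append(peak)
    return out
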