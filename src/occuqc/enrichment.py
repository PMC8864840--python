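"""Peak-level enrichment metrics and stitched-region (super-enhancer-like)
identification.

Peaks are gap-merged into stitched regions; each region's control-corrected
tag density is ranked, and a slope-based inflection cutoff on the scaled
rank/signal curve separates exceptionally signal-rich ("super") regions
from typical ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .filters import _interval_arrays, points_in_intervals
from .model import GenomicInterval, TagSet

logger = logging.getLogger(__name__)

DEFAULT_STITCH_GAP = 12_500


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    member_peaks: int
    signal: float = 0.0          # tags-per-million, control-corrected
    rank: int = 0                # 1-based, ascending signal
    is_super: bool = False


@dataclass
class StitchedRegionSet:
    regions: list[StitchedRegion]
    stitch_gap: int
    cutoff_signal: Optional[float] = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_super(self) -> int:
        return sum(r.is_super for r in self.regions)

    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.regions]


def compute_frip(tags: TagSet, peaks: Sequence[GenomicInterval]
                 ) -> Optional[float]:
    """Fraction of tags whose 5' position falls in the union of peaks.

    Overlapping peaks are merged first so no tag is double-counted.
    None on an empty tag set; 0.0 on an empty peak set.
    """
    n = tags.n_tags
    if n == 0:
        return None
    if not peaks:
        return 0.0
    union = _interval_arrays(peaks)
    inside = 0
    for chrom in tags.chroms:
        entry = union.get(chrom)
        if entry is None:
            continue
        pos, _, _ = tags.arrays(chrom)
        inside += int(points_in_intervals(pos, *entry).sum())
    return inside / n


def count_peaks(peaks: Sequence[GenomicInterval]) -> int:
    return len(peaks)


def count_normalized_peaks(
    normalized_peaks: Optional[Sequence[GenomicInterval]],
) -> Optional[int]:
    """Count of input/control-corrected peaks; None when no control-corrected
    peak file was supplied (metric reported missing)."""
    if normalized_peaks is None:
        return None
    return len(normalized_peaks)


def stitch_peaks(peaks: Sequence[GenomicInterval],
                 stitch_gap: int = DEFAULT_STITCH_GAP) -> StitchedRegionSet:
    """Merge peaks whose gap (start of later − end of earlier) is at most
    ``stitch_gap`` bp, transitively; region = span of its members."""
    if stitch_gap < 0:
        raise ValueError("stitch_gap must be >= 0")
    per: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        per.setdefault(p.chrom, []).append(p)
    regions: list[StitchedRegion] = []
    for chrom in sorted(per):
        chrom_peaks = sorted(per[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end, members = None, None, 0
        for p in chrom_peaks:
            if cur_start is None:
                cur_start, cur_end, members = p.start, p.end, 1
            elif p.start - cur_end <= stitch_gap:
                cur_end = max(cur_end, p.end)
                members += 1
            else:
                regions.append(StitchedRegion(
                    GenomicInterval(chrom, cur_start, cur_end), members))
                cur_start, cur_end, members = p.start, p.end, 1
        if cur_start is not None:
            regions.append(StitchedRegion(
                GenomicInterval(chrom, cur_start, cur_end), members))
    return StitchedRegionSet(regions=regions, stitch_gap=stitch_gap)


def _region_tpm(regions: Sequence[StitchedRegion], tags: TagSet) -> np.ndarray:
    """Tags-per-million of ``tags`` in each region (5'-position membership)."""
    total = tags.n_tags
    out = np.zeros(len(regions), dtype=float)
    if total == 0:
        return out
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.interval.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        if chrom not in tags.chrom_sizes and chrom not in tags.chroms:
            continue
        try:
            pos, _, _ = tags.arrays(chrom)
        except KeyError:
            continue
        pos_sorted = np.sort(pos)
        for i in idxs:
            iv = regions[i].interval
            lo = np.searchsorted(pos_sorted, iv.start, side="left")
            hi = np.searchsorted(pos_sorted, iv.end, side="left")
            out[i] = (hi - lo) / total * 1e6
    return out


def score_regions(region_set: StitchedRegionSet, tags: TagSet,
                  control_tags: Optional[TagSet] = None) -> StitchedRegionSet:
    """Assign control-corrected signal and ascending rank to each region.

    signal = sample TPM − control TPM, floored at 0 (negative densities
    are artifacts of sparse controls); without a control, sample TPM.
    Ties in signal are broken by genomic order (chrom, start).
    """
    regions = region_set.regions
    sample = _region_tpm(regions, tags)
    if control_tags is not None:
        control = _region_tpm(regions, control_tags)
        signal = np.maximum(sample - control, 0.0)
    else:
        signal = sample
    order = sorted(
        range(len(regions)),
        key=lambda i: (signal[i], regions[i].interval.chrom,
                       regions[i].interval.start),
    )
    for rank0, i in enumerate(order):
        regions[i].signal = float(signal[i])
        regions[i].rank = rank0 + 1
    return region_set


def find_cutoff(signals: Sequence[float]) -> tuple[float, np.ndarray]:
    """Slope-1 tangent cutoff on the ascending signal curve.

    Rank index and signal are each min-max scaled to [0, 1]; the cutoff is
    the signal at the tangent point of a slope-1 support line — the point
    minimizing y − x, where the discrete slope of the scaled curve crosses
    1. Returns (cutoff, is_super mask aligned with the ascending input);
    regions strictly above the cutoff are super. A curve whose
    forward-difference slope never exceeds 1 (e.g. exactly linear) yields
    zero supers.
    """
    s = np.asarray(signals, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 regions to place a cutoff")
    if np.any(np.diff(s) < 0):
        raise ValueError("signals must be sorted ascending")
    smin, smax = float(s[0]), float(s[-1])
    if smax == smin:
        logger.warning("find_cutoff: all signals identical; no super regions")
        return smax, np.zeros(s.size, dtype=bool)
    x = np.arange(s.size, dtype=float) / (s.size - 1)
    y = (s - smin) / (smax - smin)
    slope = np.diff(y) / np.diff(x)      # forward difference, 1-point window
    # epsilon guards float round-off: an exactly linear curve must not fire
    if not (slope > 1.0 + 1e-9).any():
        return smax, np.zeros(s.size, dtype=bool)
    cutoff = float(s[int(np.argmin(y - x))])
    return cutoff, s > cutoff


def classify_regions(region_set: StitchedRegionSet) -> StitchedRegionSet:
    """Apply the slope-cutoff rule to a scored region set."""
    regions = sorted(region_set.regions, key=lambda r: r.rank)
    signals = [r.signal for r in regions]
    if len(regions) < 3 or len(set(signals)) == 1:
        cutoff = max(signals) if signals else None
        for r in regions:
            r.is_super = False
        region_set.cutoff_signal = cutoff
        if regions:
            logger.warning("classify_regions: degenerate signal curve; "
                           "no super regions called")
        return region_set
    cutoff, is_super = find_cutoff(signals)
    for r, flag in zip(regions, is_super):
        r.is_super = bool(flag)
    region_set.cutoff_signal = cutoff
    return region_set


def s_ratio(region_set: StitchedRegionSet) -> Optional[float]:
    """Super-stitched over linear-stitched region count; None when empty."""
    if region_set.n_regions == 0:
        return None
    return region_set.n_super / region_set.n_regions


def stitch_and_classify(peaks: Sequence[GenomicInterval], tags: TagSet,
                        control_tags: Optional[TagSet] = None,
                        stitch_gap: int = DEFAULT_STITCH_GAP
                        ) -> StitchedRegionSet:
    """stitch -> score -> classify in one call."""
    region_set = stitch_peaks(peaks, stitch_gap)
    score_regions(region_set, tags, control_tags)
    return classify_regions(region_set)
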