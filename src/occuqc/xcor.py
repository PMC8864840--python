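"""Strand cross-correlation analysis.

For a shift s, cc(s) is the Pearson correlation between the binary
occupancy vector of + strand 5' positions and the − strand vector shifted
left by s, computed per chromosome and combined as a tag-count-weighted
mean. The profile peaks near the fragment length (true signal) and near
the read length (the mappability "phantom peak"); NSC and RSC summarize
the two against the background level.

The substrate should be deduplicated tags; occupancy is binary at 1 bp
resolution, so residual duplicates collapse anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import argrelextrema

from .model import OccuqcError, TagSet, STRAND_MINUS, STRAND_PLUS

logger = logging.getLogger(__name__)

DEFAULT_SHIFT_LO = 0
DEFAULT_SHIFT_HI = 500
DEFAULT_SHIFT_STEP = 5
MIN_TAGS_PER_CHROM = 200
PHANTOM_HALF_WIDTH = 10


@dataclass
class XcorProfile:
    """Cross-correlation profile with derived fragment/read-length peaks."""

    shifts: np.ndarray
    cc: np.ndarray
    cc_background: float
    fragment_width: Optional[int] = None
    cc_fragment: Optional[float] = None
    predicted_tag_length: Optional[int] = None
    cc_readlen: Optional[float] = None

    def cc_at(self, shift: int) -> float:
        i = int(np.argmin(np.abs(self.shifts - shift)))
        return float(self.cc[i])


def strand_cross_correlation(
    tags: TagSet,
    shift_lo: int = DEFAULT_SHIFT_LO,
    shift_hi: int = DEFAULT_SHIFT_HI,
    step: int = DEFAULT_SHIFT_STEP,
    min_tags_per_chrom: int = MIN_TAGS_PER_CHROM,
) -> XcorProfile:
    """Compute cc(shift) over an evenly spaced shift grid.

    Chromosomes with fewer than ``min_tags_per_chrom`` tags, a single
    represented strand, or length <= ``shift_hi`` are skipped with a
    warning. Raises if no chromosome is usable or only one strand is
    present overall.
    """
    if shift_hi <= shift_lo or step <= 0:
        raise ValueError("need shift_hi > shift_lo and step > 0")
    plus_total, minus_total = tags.strand_counts()
    if plus_total == 0 or minus_total == 0:
        raise OccuqcError("cross-correlation undefined: single-strand data")
    shifts = np.arange(shift_lo, shift_hi + 1, step, dtype=np.int64)
    acc = np.zeros(shifts.size, dtype=np.float64)
    total_weight = 0.0
    for chrom in tags.chroms:
        pos, strand, _ = tags.arrays(chrom)
        length = tags.chrom_sizes[chrom]
        if pos.size < min_tags_per_chrom:
            continue
        if length <= shift_hi:
            logger.warning("xcor: skipping %s (length %d <= max shift %d)",
                           chrom, length, shift_hi)
            continue
        plus_pos = np.unique(pos[strand == STRAND_PLUS])
        minus_pos = np.unique(pos[strand == STRAND_MINUS])
        if plus_pos.size == 0 or minus_pos.size == 0:
            continue
        cc = _chrom_cc(plus_pos, minus_pos, length, shifts)
        weight = float(pos.size)
        acc += weight * cc
        total_weight += weight
    if total_weight == 0:
        raise OccuqcError("cross-correlation undefined: no usable chromosome")
    cc = acc / total_weight
    return XcorProfile(shifts=shifts, cc=cc, cc_background=float(cc.min()))


def _chrom_cc(plus_pos: np.ndarray, minus_pos: np.ndarray, length: int,
              shifts: np.ndarray) -> np.ndarray:
    """Pearson cc between binary occupancy vectors for each shift.

    Only the overlap window [0, length-s) x [s, length) is correlated.
    Window sums come from position counts; the cross term n11 is a dot
    product of float32 slices (BLAS path).
    """
    plus = np.zeros(length, dtype=np.float32)
    plus[plus_pos] = 1.0
    minus = np.zeros(length, dtype=np.float32)
    minus[minus_pos] = 1.0
    out = np.empty(shifts.size, dtype=np.float64)
    for i, s in enumerate(shifts):
        n = length - int(s)
        x = plus[:n]
        y = minus[int(s):]
        sx = float(np.searchsorted(plus_pos, n))           # ones in x
        sy = float(minus_pos.size - np.searchsorted(minus_pos, s))  # ones in y
        n11 = float(np.dot(x, y))
        cov = n11 - sx * sy / n
        varx = sx - sx * sx / n
        vary = sy - sy * sy / n
        denom = np.sqrt(varx * vary)
        out[i] = cov / denom if denom > 0 else 0.0
    return out


def _local_maxima(cc: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima (plateaus count via >=)."""
    if cc.size < 3:
        return np.arange(cc.size)
    idx = argrelextrema(cc, np.greater_equal, order=1)[0]
    return idx[(idx > 0) & (idx < cc.size - 1)]


def phantom_window(mean_read_length: float,
                   half_width: int = PHANTOM_HALF_WIDTH) -> tuple[float, float]:
    return mean_read_length - half_width, mean_read_length + half_width


def estimate_fragment_width(profile: XcorProfile,
                            mean_read_length: float,
                            half_width: int = PHANTOM_HALF_WIDTH) -> int:
    """Shift maximizing cc outside the phantom-peak exclusion window
    [read length − half_width, read length + half_width]."""
    lo, hi = phantom_window(mean_read_length, half_width)
    mask = (profile.shifts < lo) | (profile.shifts > hi)
    if not mask.any():
        raise OccuqcError("fragment width undefined: all shifts inside the "
                          "phantom exclusion window")
    shifts = profile.shifts[mask]
    cc = profile.cc[mask]
    best = int(np.argmax(cc))
    profile.fragment_width = int(shifts[best])
    profile.cc_fragment = float(cc[best])
    return profile.fragment_width


def predicted_tag_length(profile: XcorProfile,
                         mean_read_length: float,
                         half_width: int = PHANTOM_HALF_WIDTH) -> int:
    """Shift of the phantom (read-length) peak.

    Preference order: argmax of cc among shifts inside the phantom window
    when the window holds a local maximum; otherwise the local maximum
    nearest the mean read length, excluding the fragment-width shift;
    otherwise fall back to the mean read length with a warning.
    """
    lo, hi = phantom_window(mean_read_length, half_width)
    in_window = (profile.shifts >= lo) & (profile.shifts <= hi)
    maxima = _local_maxima(profile.cc)
    window_maxima = maxima[in_window[maxima]] if maxima.size else maxima
    if window_maxima.size:
        idx = window_maxima[np.argmax(profile.cc[window_maxima])]
    elif in_window.any() and maxima.size == 0:
        # no interior structure at all: take window argmax
        wi = np.flatnonzero(in_window)
        idx = wi[np.argmax(profile.cc[wi])]
    else:
        candidates = maxima
        if profile.fragment_width is not None and candidates.size:
            candidates = candidates[
                profile.shifts[candidates] != profile.fragment_width]
        if candidates.size == 0:
            logger.warning("xcor: no phantom-peak candidate; predicted tag "
                           "length falls back to mean read length")
            profile.predicted_tag_length = int(round(mean_read_length))
            profile.cc_readlen = profile.cc_at(profile.predicted_tag_length)
            return profile.predicted_tag_length
        dist = np.abs(profile.shifts[candidates] - mean_read_length)
        idx = candidates[int(np.argmin(dist))]
    profile.predicted_tag_length = int(profile.shifts[idx])
    profile.cc_readlen = float(profile.cc[idx])
    return profile.predicted_tag_length


def tag_length_delta(predicted: int, mean_read_length: float) -> float:
    """Metric E: |predicted tag length − mean read length| in bp."""
    return abs(predicted - mean_read_length)


def compute_nsc(profile: XcorProfile) -> Optional[float]:
    """Normalized strand coefficient: max cc over background cc.

    None (missing) when the background is not positive — the ratio is
    undefined there.
    """
    if profile.cc_background <= 0:
        return None
    return float(profile.cc.max()) / profile.cc_background


def compute_rsc(profile: XcorProfile) -> Optional[float]:
    """Relative strand coefficient:
    (cc_fragment − background) / (cc_readlen − background)."""
    if profile.cc_fragment is None or profile.cc_readlen is None:
        raise OccuqcError("RSC requires fragment and read-length peaks")
    denom = profile.cc_readlen - profile.cc_background
    if denom == 0:
        return None
    return (profile.cc_fragment - profile.cc_background) / denom


def analyze(tags: TagSet, mean_read_length: Optional[float] = None,
            shift_lo: int = DEFAULT_SHIFT_LO, shift_hi: int = DEFAULT_SHIFT_HI,
            step: int = DEFAULT_SHIFT_STEP) -> XcorProfile:
    """Full cross-correlation analysis: profile + fragment width +
    predicted tag length populated."""
    if mean_read_length is None:
        mean_read_length = tags.mean_read_length()
    profile = strand_cross_correlation(tags, shift_lo, shift_hi, step)
    estimate_fragment_width(profile, mean_read_length)
    predicted_tag_length(profile, mean_read_length)
    return profile
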