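"""Sequencing-library quality metrics.

Aligned percent, non-redundant fraction (NRF), PCR bottleneck coefficient
(PBC), per-base quality flag and sequence-diversity flag. NRF and PBC are
computed on mapped tags *before* duplicate/blacklist filtering, with all
mapped tags as the NRF denominator (ENCODE convention). Metrics that
cannot be computed from the provided inputs return ``None`` and are
reported as missing downstream.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .io import FastqStats
from .model import TagSet

# FastQC-style per-base quality thresholds
BASE_QUALITY_FAIL = {"lower_quartile": 5, "median": 20}
BASE_QUALITY_WARN = {"lower_quartile": 10, "median": 25}

# overrepresentation thresholds, as fractions of sampled reads
DIVERSITY_WARN_FRACTION = 0.001
DIVERSITY_FAIL_FRACTION = 0.01


def aligned_percent(total_raw: int, total_mapped: int) -> Optional[float]:
    """Percentage of input reads that mapped; None when undefined."""
    if total_raw <= 0:
        return None
    if total_mapped > total_raw:
        raise ValueError("total_mapped exceeds total_raw")
    return 100.0 * total_mapped / total_raw


def _key_counts(tags: TagSet) -> np.ndarray:
    counts = [np.unique(key, return_counts=True)[1]
              for key in tags.keys().values()]
    if not counts:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(counts)


def compute_nrf(tags: TagSet) -> Optional[float]:
    """Non-redundant fraction: distinct (chrom, pos5, strand) keys over
    mapped tags."""
    if tags.total_mapped <= 0:
        return None
    distinct = int(_key_counts(tags).size)
    return distinct / tags.total_mapped


def compute_pbc(tags: TagSet) -> Optional[float]:
    """PCR bottleneck coefficient: genomic locations with exactly one tag
    over locations with at least one."""
    counts = _key_counts(tags)
    if counts.size == 0:
        return None
    return int((counts == 1).sum()) / counts.size


def base_quality_flag(stats: Optional[FastqStats]) -> Optional[str]:
    """pass / warn / fail on the per-cycle quality distribution.

    fail if any cycle has lower quartile < 5 or median < 20; warn if any
    has lower quartile < 10 or median < 25; else pass. None without FASTQ.
    """
    if stats is None:
        return None
    pc = stats.per_cycle
    if ((pc["lower_quartile"] < BASE_QUALITY_FAIL["lower_quartile"])
            | (pc["median"] < BASE_QUALITY_FAIL["median"])).any():
        return "fail"
    if ((pc["lower_quartile"] < BASE_QUALITY_WARN["lower_quartile"])
            | (pc["median"] < BASE_QUALITY_WARN["median"])).any():
        return "warn"
    return "pass"


def diversity_flag(stats: Optional[FastqStats]) -> Optional[str]:
    """pass / warn / fail on exact-sequence overrepresentation.

    fail if any sequence exceeds 1% of sampled reads, warn above 0.1%.
    """
    if stats is None:
        return None
    if stats.seq_freq.empty:
        return "pass"
    top = float(stats.seq_freq.iloc[0])
    if top > DIVERSITY_FAIL_FRACTION:
        return "fail"
    if top > DIVERSITY_WARN_FRACTION:
        return "warn"
    return "pass"
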