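"""Core data model shared across the toolkit.

All genomic coordinates are 0-based half-open (BED convention). GTF input
is converted on read; nothing downstream ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

STRAND_PLUS = 0
STRAND_MINUS = 1

_STRAND_CODE = {"+": STRAND_PLUS, "-": STRAND_MINUS}
_STRAND_CHAR = {STRAND_PLUS: "+", STRAND_MINUS: "-"}


class OccuqcError(Exception):
    """Base class for toolkit errors."""


class ParseError(OccuqcError):
    """Malformed input file; message carries the offending line/record."""


@dataclass(frozen=True)
class GenomicInterval:
    """A [start, end) region anchored to a chromosome.

    The unit of peaks, blacklist entries, stitched regions and gene parts.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded body interval with TSS/TES anchors.

    ``tss`` is body.start for + genes and body.end - 1 for − genes; ``tes``
    is the opposite anchor.
    """

    gene_id: str
    chrom: str
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.body.chrom != self.chrom:
            raise ValueError(f"gene {self.gene_id}: body on wrong chromosome")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tes(self) -> int:
        return self.body.end - 1 if self.strand == "+" else self.body.start


class TagSet:
    """Single-end read tags: per-chromosome arrays of (5' position, strand,
    read length), plus library-level counts.

    ``total_raw`` is the number of input sequencing reads; ``total_mapped``
    the number of retained tags. The arrays are the substrate of every
    read-based metric, so they stay numpy-native.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        total_raw: int = 0,
        total_mapped: int = 0,
    ) -> None:
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.total_raw = int(total_raw)
        self.total_mapped = int(total_mapped)
        # chrom -> (pos5 int64[], strand int8[], read_length int32[])
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_tags(
        cls,
        tags: Iterable[tuple[str, int, str, int]],
        chrom_sizes: dict[str, int],
        total_raw: Optional[int] = None,
        total_mapped: Optional[int] = None,
    ) -> "TagSet":
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        n = 0
        for chrom, pos5, strand, read_length in tags:
            per_chrom.setdefault(chrom, []).append(
                (int(pos5), _STRAND_CODE[strand], int(read_length))
            )
            n += 1
        ts = cls(
            chrom_sizes,
            total_raw=n if total_raw is None else total_raw,
            total_mapped=n if total_mapped is None else total_mapped,
        )
        for chrom, rows in per_chrom.items():
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            ts._data[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int8),
                arr[:, 2].astype(np.int32),
            )
        ts._check()
        return ts

    def _check(self) -> None:
        if self.total_mapped > self.total_raw:
            raise ValueError("total_mapped exceeds total_raw")
        for chrom, (pos, _, _) in self._data.items():
            size = self.chrom_sizes.get(chrom)
            if size is not None and pos.size and (pos.min() < 0 or pos.max() >= size):
                raise ValueError(f"tag position outside chromosome {chrom}")

    def _set_chrom(
        self, chrom: str, pos: np.ndarray, strand: np.ndarray, rlen: np.ndarray
    ) -> None:
        if pos.size:
            self._data[chrom] = (
                pos.astype(np.int64),
                strand.astype(np.int8),
                rlen.astype(np.int32),
            )

    # -- access -----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pos5, strand code, read length) arrays for one chromosome."""
        return self._data[chrom]

    @property
    def n_tags(self) -> int:
        return sum(p.size for p, _, _ in self._data.values())

    def strand_counts(self) -> tuple[int, int]:
        plus = minus = 0
        for _, strand, _ in self._data.values():
            minus += int(strand.sum())
            plus += strand.size - int(strand.sum())
        return plus, minus

    def mean_read_length(self) -> float:
        total = n = 0
        for _, _, rlen in self._data.values():
            total += int(rlen.sum(dtype=np.int64))
            n += rlen.size
        return total / n if n else float("nan")

    def iter_tags(self) -> Iterator[tuple[str, int, str, int]]:
        for chrom in self.chroms:
            pos, strand, rlen = self._data[chrom]
            for p, s, r in zip(pos, strand, rlen):
                yield chrom, int(p), _STRAND_CHAR[int(s)], int(r)

    def subset(self, keep: dict[str, np.ndarray]) -> "TagSet":
        """New TagSet retaining per-chromosome boolean/index masks.

        Library counters are preserved; callers adjust them if the subset
        changes the notion of 'mapped'.
        """
        out = TagSet(self.chrom_sizes, self.total_raw, self.total_mapped)
        for chrom, (pos, strand, rlen) in self._data.items():
            mask = keep.get(chrom)
            if mask is None:
                out._set_chrom(chrom, pos, strand, rlen)
            else:
                out._set_chrom(chrom, pos[mask], strand[mask], rlen[mask])
        return out

    def keys(self) -> dict[str, np.ndarray]:
        """Per-chromosome encoded (pos5, strand) duplicate keys."""
        return {
            chrom: pos * 2 + strand
            for chrom, (pos, strand, _) in self._data.items()
        }


@dataclass
class FilterReport:
    """Accounting for one filtering stage; counts always reconcile."""

    input_tags: int
    duplicates_removed: int = 0
    blacklisted_removed: int = 0

    @property
    def output_tags(self) -> int:
        return self.input_tags - self.duplicates_removed - self.blacklisted_removed

    def __post_init__(self) -> None:
        if min(self.input_tags, self.duplicates_removed, self.blacklisted_removed) < 0:
            raise ValueError("negative filter counts")
        if self.output_tags < 0:
            raise ValueError("filter removed more tags than were present")


def strand_char(code: int) -> str:
    return _STRAND_CHAR[int(code)]


def strand_code(char: str) -> int:
    try:
        return _STRAND_CODE[char]
    except KeyError:
        raise ValueError(f"invalid strand {char!r}") from None
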