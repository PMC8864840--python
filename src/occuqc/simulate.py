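"""Synthetic fixtures with exact ground truth.

Generates stranded single-end tag sets, peak sets, gene annotations,
blacklists and FASTQ files in the same formats the pipeline consumes,
together with a :class:`SimulationTruth` whose tallies are computed from
the emitted tags themselves — so truth-vs-measured comparisons are exact,
not approximate.

Fragments are placed in a peak with probability ``frip_target`` and
uniformly on the genome otherwise; sequencing both fragment ends (one +
tag at the start, one − tag at the end) gives the strand cross-correlation
a genuine fragment-length peak. All randomness flows through one explicit
seed; no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .filters import _interval_arrays, points_in_intervals
from .io import write_genes_gtf, write_tag_bed
from .model import GeneModel, GenomicInterval, OccuqcError, TagSet

# Default study conditions for the toy experiment
DEFAULT_GENOME = {"chr1": 1_000_000, "chr2": 1_000_000}
DEFAULT_N_FRAGMENTS = 50_000
DEFAULT_FRAGMENT_LENGTH = 200
DEFAULT_FRAGMENT_LENGTH_SD = 15.0   # sonication-like size spread
DEFAULT_DUPLICATE_RATE = 0.1
DEFAULT_FRIP_TARGET = 0.3
DEFAULT_READ_LENGTH = 50
DEFAULT_PEAK_STRENGTH_SD = 1.0      # lognormal sigma of per-peak enrichment
DEFAULT_N_PEAKS = 60
DEFAULT_N_GENES = 40


@dataclass
class SimulationTruth:
    """Exact tallies of an emitted tag fixture."""

    seed: int
    n_reads: int                 # fragments simulated
    n_tags: int                  # tags emitted (incl. duplicates)
    fragment_length: int
    duplicate_rate: float
    frip_target: float
    true_distinct_keys: int
    true_singleton_keys: int
    true_in_peak_tags: int
    n_plus: int
    n_minus: int

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def nrf(self) -> float:
        return self.true_distinct_keys / self.n_tags

    @property
    def pbc(self) -> float:
        return self.true_singleton_keys / self.true_distinct_keys

    @property
    def frip(self) -> float:
        return self.true_in_peak_tags / self.n_tags


# ---------------------------------------------------------------------------
# interval placement

def _place_intervals(chrom_sizes: dict[str, int], n: int,
                     width_range: tuple[int, int], rng: np.random.Generator,
                     avoid: Optional[Sequence[GenomicInterval]] = None,
                     max_tries: int = 10_000) -> list[GenomicInterval]:
    """Rejection-sample n non-overlapping intervals, optionally avoiding
    an existing interval set. Raises when the genome is too small."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: list[GenomicInterval] = []
    taken: list[GenomicInterval] = list(avoid or [])
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise OccuqcError(
                f"could not place {n} intervals: genome too small or "
                "too crowded")
        tries += 1
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        if chrom_sizes[chrom] <= width:
            continue
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        cand = GenomicInterval(chrom, start, start + width)
        if any(cand.overlaps(t) for t in taken):
            continue
        placed.append(cand)
        taken.append(cand)
    placed.sort(key=lambda iv: (iv.chrom, iv.start))
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"peak{i + 1}")
        for i, iv in enumerate(placed)
    ]


def simulate_peaks(chrom_sizes: Optional[dict[str, int]] = None,
                   n_peaks: int = DEFAULT_N_PEAKS,
                   width_range: tuple[int, int] = (500, 2_000),
                   seed: int = 0) -> list[GenomicInterval]:
    """Non-overlapping peak intervals over the toy genome."""
    chrom_sizes = chrom_sizes or DEFAULT_GENOME
    rng = np.random.default_rng(seed)
    return _place_intervals(chrom_sizes, n_peaks, width_range, rng)


def simulate_blacklist(chrom_sizes: Optional[dict[str, int]] = None,
                       n: int = 3, width: int = 5_000, seed: int = 0,
                       avoid: Optional[Sequence[GenomicInterval]] = None
                       ) -> list[GenomicInterval]:
    """Artifact ("blacklist") regions, placed clear of ``avoid``."""
    chrom_sizes = chrom_sizes or DEFAULT_GENOME
    rng = np.random.default_rng(seed + 104_729)
    ivs = _place_intervals(chrom_sizes, n, (width, width), rng, avoid=avoid)
    return [GenomicInterval(iv.chrom, iv.start, iv.end, name=f"bl{i + 1}")
            for i, iv in enumerate(ivs)]


# ---------------------------------------------------------------------------
# tags

def simulate_tags(chrom_sizes: Optional[dict[str, int]] = None,
                  peaks: Optional[Sequence[GenomicInterval]] = None,
                  frip_target: float = DEFAULT_FRIP_TARGET,
                  fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                  fragment_length_sd: float = DEFAULT_FRAGMENT_LENGTH_SD,
                  n_fragments: int = DEFAULT_N_FRAGMENTS,
                  duplicate_rate: float = DEFAULT_DUPLICATE_RATE,
                  read_length: int = DEFAULT_READ_LENGTH,
                  peak_strength_sd: float = DEFAULT_PEAK_STRENGTH_SD,
                  seed: int = 0,
                  paired_ends: bool = True
                  ) -> tuple[TagSet, SimulationTruth]:
    """Simulate a stranded tag set with known library structure.

    With ``paired_ends`` (default) each fragment emits a + tag at its
    start and a − tag at its end, coupling the strands at the fragment
    length. With ``paired_ends=False`` each fragment instead emits two
    tags at independent positions with random strands — identical marginal
    placement, no +/− coupling (a strand-independent null). Each emitted
    tag is duplicated once with probability ``duplicate_rate``.

    Per-fragment lengths are Gaussian around ``fragment_length`` with
    spread ``fragment_length_sd`` (sonication/tagmentation produces a size
    distribution, and the strand cross-correlation peak of a real library
    is correspondingly broad). In-peak placement weights each peak by
    width times a lognormal per-peak strength (sigma
    ``peak_strength_sd``), giving the heavy-tailed region-signal landscape
    that super-enhancer calling expects.
    """
    if not (0 <= frip_target <= 1 and 0 <= duplicate_rate <= 1):
        raise ValueError("frip_target and duplicate_rate must be in [0, 1]")
    chrom_sizes = chrom_sizes or DEFAULT_GENOME
    peaks = list(peaks) if peaks is not None else []
    if frip_target > 0 and not peaks:
        raise OccuqcError("frip_target > 0 requires a peak set")
    for p in peaks:
        if p.chrom not in chrom_sizes or p.end > chrom_sizes[p.chrom]:
            raise OccuqcError(f"peak {p.chrom}:{p.start}-{p.end} outside genome")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if peaks:
        strengths = rng.lognormal(0.0, peak_strength_sd, size=len(peaks))
        weights = np.array([p.length for p in peaks]) * strengths
        weights /= weights.sum()

    def draw_lengths(n: int) -> np.ndarray:
        if fragment_length_sd <= 0:
            return np.full(n, fragment_length, dtype=np.int64)
        flen = np.round(rng.normal(fragment_length, fragment_length_sd, n))
        return np.clip(flen, 1, None).astype(np.int64)

    def draw_starts(n: int, flen: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """(chrom index, fragment start) for n fragments."""
        in_peak = rng.random(n) < frip_target if peaks else np.zeros(n, bool)
        ci = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
        hi = np.maximum(sizes[ci] - flen, 1)
        start = (rng.random(n) * hi).astype(np.int64)
        if in_peak.any():
            pi = rng.choice(len(peaks), size=int(in_peak.sum()), p=weights)
            pstart = np.array([peaks[i].start for i in pi])
            pwidth = np.array([peaks[i].length for i in pi])
            off = (rng.random(pi.size) * pwidth).astype(np.int64)
            s = pstart + off
            c = np.array([chroms.index(peaks[i].chrom) for i in pi])
            limit = sizes[c] - flen[in_peak]
            s = np.minimum(s, np.maximum(limit, 0))
            start[in_peak] = s
            ci[in_peak] = c
        return ci, start

    if paired_ends:
        flen = draw_lengths(n_fragments)
        ci, start = draw_starts(n_fragments, flen)
        tag_ci = np.concatenate([ci, ci])
        tag_pos = np.concatenate([start, start + flen - 1])
        tag_strand = np.concatenate([
            np.zeros(n_fragments, np.int8), np.ones(n_fragments, np.int8)])
    else:
        flen = draw_lengths(2 * n_fragments)
        ci, start = draw_starts(2 * n_fragments, flen)
        tag_ci = ci
        tag_pos = start + (rng.random(ci.size) * flen).astype(np.int64)
        tag_strand = rng.integers(0, 2, size=ci.size).astype(np.int8)
    tag_pos = np.minimum(tag_pos, sizes[tag_ci] - 1)

    dup = rng.random(tag_pos.size) < duplicate_rate
    tag_ci = np.concatenate([tag_ci, tag_ci[dup]])
    tag_pos = np.concatenate([tag_pos, tag_pos[dup]])
    tag_strand = np.concatenate([tag_strand, tag_strand[dup]])

    n_tags = tag_pos.size
    ts = TagSet(chrom_sizes, total_raw=n_tags, total_mapped=n_tags)
    for i, chrom in enumerate(chroms):
        mask = tag_ci == i
        if mask.any():
            ts._set_chrom(chrom, tag_pos[mask], tag_strand[mask],
                          np.full(int(mask.sum()), read_length, np.int32))

    # exact truth tallies from the emitted tags
    distinct = singleton = 0
    for key in ts.keys().values():
        counts = np.unique(key, return_counts=True)[1]
        distinct += counts.size
        singleton += int((counts == 1).sum())
    in_peak_tags = 0
    if peaks:
        union = _interval_arrays(peaks)
        for chrom in ts.chroms:
            entry = union.get(chrom)
            if entry is None:
                continue
            pos, _, _ = ts.arrays(chrom)
            in_peak_tags += int(points_in_intervals(pos, *entry).sum())
    n_minus = int(tag_strand.sum())
    truth = SimulationTruth(
        seed=seed, n_reads=n_fragments, n_tags=n_tags,
        fragment_length=fragment_length, duplicate_rate=duplicate_rate,
        frip_target=frip_target, true_distinct_keys=distinct,
        true_singleton_keys=singleton, true_in_peak_tags=in_peak_tags,
        n_plus=n_tags - n_minus, n_minus=n_minus,
    )
    return ts, truth


# Conditions for the strand-independent null used to check that NSC has no
# spurious fragment peak. Two requirements drive the scale (see
# docs/methods.md): enrichment structure must live on scales much larger
# than the maximum shift, otherwise the enrichment autocorrelation itself
# makes cc(s) decay across the grid; and depth must be high enough that
# per-shift counting noise is small relative to the cc level.
NULL_GENOME = {f"chr{i + 1}": 2_000_000 for i in range(8)}
NULL_N_FRAGMENTS = 2_000_000
NULL_FRIP = 0.9
NULL_N_DOMAINS = 8
NULL_DOMAIN_WIDTH = (100_000, 100_000)


def simulate_null_tags(seed: int = 0) -> tuple[TagSet, SimulationTruth]:
    """Strand-independent null: broad-domain enrichment, no +/− coupling."""
    domains = simulate_peaks(NULL_GENOME, NULL_N_DOMAINS, NULL_DOMAIN_WIDTH,
                             seed=seed)
    return simulate_tags(NULL_GENOME, domains, frip_target=NULL_FRIP,
                         n_fragments=NULL_N_FRAGMENTS, duplicate_rate=0.0,
                         peak_strength_sd=0.0, seed=seed, paired_ends=False)


# ---------------------------------------------------------------------------
# annotation / signals / fastq

def simulate_annotation(n_genes: int = DEFAULT_N_GENES,
                        chrom_sizes: Optional[dict[str, int]] = None,
                        gene_length: tuple[int, int] = (5_000, 20_000),
                        seed: int = 0) -> list[GeneModel]:
    """Non-overlapping stranded gene models on the toy genome."""
    chrom_sizes = chrom_sizes or DEFAULT_GENOME
    rng = np.random.default_rng(seed + 7_919)
    bodies = _place_intervals(chrom_sizes, n_genes, gene_length, rng)
    genes = []
    for i, body in enumerate(bodies):
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1}"
        genes.append(GeneModel(
            gid, body.chrom, strand,
            GenomicInterval(body.chrom, body.start, body.end,
                            strand=strand, name=gid)))
    return genes


def simulate_region_signals(n_regions: int = 100,
                            outlier_factor: float = 50.0,
                            n_outliers: int = 1,
                            seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Signal vector of draws near 1.0 with designed high outliers.

    Returns (signals, is_outlier). ``outlier_factor=1`` produces no
    designed outliers (the flag vector is all False).
    """
    rng = np.random.default_rng(seed)
    signals = np.abs(rng.normal(1.0, 0.05, size=n_regions))
    is_outlier = np.zeros(n_regions, dtype=bool)
    if outlier_factor > 1 and n_outliers > 0:
        idx = rng.choice(n_regions, size=n_outliers, replace=False)
        signals[idx] *= outlier_factor
        is_outlier[idx] = True
    return signals, is_outlier


def simulate_fastq(path: Union[str, Path], n_reads: int = 2_000,
                   read_length: int = DEFAULT_READ_LENGTH,
                   overrepresented_fraction: float = 0.0,
                   quality_char: str = "I", seed: int = 0) -> None:
    """Constant-quality FASTQ of random sequences; a fixed fraction can be
    replaced by one repeated sequence to exercise the diversity flag."""
    rng = np.random.default_rng(seed + 65_537)
    bases = np.array(list("ACGT"))
    over_seq = "".join(rng.choice(bases, size=read_length))
    qual = quality_char * read_length
    with open(path, "wt") as fh:
        for i in range(n_reads):
            if rng.random() < overrepresented_fraction:
                seq = over_seq
            else:
                seq = "".join(rng.choice(bases, size=read_length))
            fh.write(f"@read{i + 1}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# full fixture

@dataclass
class Fixture:
    tags_bed: Path
    peaks_bed: Path
    genes_gtf: Path
    blacklist_bed: Path
    fastq: Path
    truth_json: Path
    chrom_sizes: dict[str, int]


def simulate_fixture(out_dir: Union[str, Path], seed: int = 0,
                     chrom_sizes: Optional[dict[str, int]] = None,
                     n_fragments: int = DEFAULT_N_FRAGMENTS,
                     frip_target: float = DEFAULT_FRIP_TARGET,
                     fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                     duplicate_rate: float = DEFAULT_DUPLICATE_RATE,
                     n_peaks: int = DEFAULT_N_PEAKS,
                     n_genes: int = DEFAULT_N_GENES,
                     fastq_reads: int = 2_000) -> Fixture:
    """Emit a complete QC input fixture (tag BED, peaks, GTF, blacklist,
    FASTQ, truth JSON) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes = chrom_sizes or dict(DEFAULT_GENOME)
    peaks = simulate_peaks(chrom_sizes, n_peaks, seed=seed)
    blacklist = simulate_blacklist(chrom_sizes, seed=seed, avoid=peaks)
    genes = simulate_annotation(n_genes, chrom_sizes, seed=seed)
    tags, truth = simulate_tags(
        chrom_sizes, peaks, frip_target=frip_target,
        fragment_length=fragment_length, n_fragments=n_fragments,
        duplicate_rate=duplicate_rate, seed=seed)
    from .io import write_bed  # local to avoid import cycle at module load

    fx = Fixture(
        tags_bed=out / "tags.bed", peaks_bed=out / "peaks.bed",
        genes_gtf=out / "genes.gtf", blacklist_bed=out / "blacklist.bed",
        fastq=out / "reads.fastq", truth_json=out / "truth.json",
        chrom_sizes=chrom_sizes,
    )
    write_tag_bed(tags, fx.tags_bed)
    write_bed(peaks, fx.peaks_bed)
    write_bed(blacklist, fx.blacklist_bed)
    write_genes_gtf(genes, fx.genes_gtf)
    simulate_fastq(fx.fastq, n_reads=fastq_reads, seed=seed)
    truth.to_json(fx.truth_json)
    (out / "chrom.sizes").write_text(
        "".join(f"{c}\t{chrom_sizes[c]}\n" for c in sorted(chrom_sizes)))
    return fx
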