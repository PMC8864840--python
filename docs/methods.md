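# Methods

This note records the models and conventions behind each stage, the
defaults that matter, and what the synthetic fixtures do and do not
establish about real data.

## Coordinates and data model

All internal coordinates are 0-based half-open (BED convention); GTF
input (1-based inclusive) is converted at the boundary, so start shifts
by −1 and end is unchanged. A gene's TSS is `body.start` on + and
`body.end − 1` on −. Reads are reduced to single-end *tags*
(chromosome, 5′ position, strand, read length): the 5′ position is the
leftmost aligned base for + reads and the rightmost for − reads. SAM/BAM
records that are unmapped, secondary or supplementary are excluded from
tags but counted in the raw total; records below the MAPQ threshold
(default 10, configurable) are dropped entirely. Tag BED input requires
the 6th (strand) column.

## Library metrics

NRF and PBC are computed on mapped tags *before* duplicate and blacklist
filtering, with all mapped tags as the NRF denominator (the ENCODE
convention; the common alternative denominator, raw reads, makes NRF
confound mapping rate with redundancy). Duplicates are keyed by
(chromosome, 5′ position, strand) — single-end tag semantics; read
length and sequence are not part of the key, so two distinct molecules
ending at the same base count as one. Filter order is fixed: duplicates
first, then blacklist, so complexity metrics never depend on which
blacklist was supplied. A tag is blacklisted when its 5′ position lies
in a blacklist interval (half-open); peaks are blacklisted on ≥ 1 bp
overlap.

The FASTQ flags use FastQC-style rules on the first 1 M reads: base
quality fails when any cycle's lower quartile < 5 or median < 20 (warns
at 10/25); sequence diversity fails when one exact sequence exceeds 1%
of sampled reads (warns above 0.1%). Per-cycle quartiles are computed
from a count histogram with lower interpolation.

## Strand cross-correlation

cc(s) is the Pearson correlation between binary occupancy vectors of
distinct + strand and (left-shifted) − strand 5′ positions at 1 bp
resolution, evaluated on a shift grid of 0–500 bp in 5 bp steps
(covering typical fragmentation sizes), per chromosome and combined as a
tag-count-weighted mean. Chromosomes with fewer than 200 tags, one
represented strand, or length ≤ the maximum shift are skipped. The
background is the minimum cc over the grid; with that convention
NSC = max cc / background is ≥ 1 whenever it is defined, and it is
reported missing when the background is not positive (the ratio is then
meaningless — this happens for structureless data whose cc fluctuates
around 0).

The fragment width is the cc argmax outside the phantom-peak exclusion
window (mean read length ± 10 bp, mirroring the ±10 bp tolerance of the
tag-length metric E). The predicted tag length is the cc argmax inside
that window when the window holds a local maximum; otherwise the local
maximum nearest the read length (excluding the fragment peak), so a
phantom peak drifted outside the window is still identified; otherwise
it falls back to the read length with E = 0 and a warning.
E = |predicted − mean read length|.

## Stitched regions and the super cutoff

Peaks whose gap is ≤ 12 500 bp (the conventional stitching distance for
enhancer clustering; TSS exclusion is available but off by default) are
merged transitively; each region's signal is sample tags-per-million
minus control tags-per-million, floored at 0 (negative densities are
sparse-control artifacts), using post-filter tag totals. Regions are
ranked ascending; rank index and signal are each min-max scaled to
[0, 1]. The cutoff is the signal at the slope-1 tangent point of the
scaled curve — the index minimizing y − x — and regions strictly above
it are super. The naive alternative, "first forward difference whose
slope exceeds 1", is identical on smooth convex curves (both give
0.25·max on y = x²) but fires on bottom-end noise for realistic
near-linear curves and then calls nearly every region super; the tangent
rule is the geometry the enhancer-ranking literature actually uses. A
1e-9 slope epsilon keeps exactly linear curves (slope ≡ 1 up to float
round-off) at zero supers. On pure-noise signals the tangent sits near
the +1σ quantile, so ~10–15% of regions land above it — a property of
the geometry, not a bug; super calls are only meaningful when the signal
curve has a genuine elbow.

## Profiles and annotation

Coverage matrices are tags-per-million per bp. Tag contribution is
either the bare 5′ position ("point") or, by default, the tag extended
to the cross-correlation-estimated fragment width 3′-ward ("extend") —
extension is what makes promoter profiles reflect occupancy rather than
read ends. Promoter matrices span TSS ± 2 kb in 50 bp bins; metagene
matrices rescale each body into 100 equal-fraction bins with 2 kb flanks
in 50 bp bins, per-bp density making the rescaling length-fair; genes
shorter than the bin count are skipped with a warning. − strand rows are
flipped so bin 1 is always 5′. Bins truncated by chromosome ends use
their truncated width and are excluded (NaN) from column means.

Peak annotation assigns one category by precedence promoter (TSS ± 1 kb)
≻ gene body ≻ gene-centric window (TSS ± 10 kb) ≻ intergenic, on ≥ 1 bp
overlap; category sizes are configurable since no standard fixes them.
The nearest gene minimizes |peak midpoint − TSS|; its distance is 0 when
that TSS lies inside the peak, else the signed offset midpoint − TSS.

## Rank dashboard

Scores are Excellent = 2, Good = 1, Average = 0, Below-average = −1,
Poor = −2 — the only assignment under which a mean of per-metric scores
can reach the published Q ≥ 2 band. Every numeric boundary is inclusive
toward the better band. pass/warn/fail metrics map to
Excellent/Average/Poor; E under 10 bp is Excellent, otherwise Poor;
NSC is Excellent at ≥ 1.045, otherwise Poor. Missing metrics are
excluded from Q rather than scored 0: absence of a FASTQ or control
should not penalize quality. Colors are a diverging green→red palette
(#1a9850, #91cf60, #fee08b, #fc8d59, #d73027). The TSV and the
self-contained HTML table are pure functions of the panel, hence
byte-identical across reruns.

## Synthetic fixtures

The generator emulates a small but structurally complete experiment:
2 chromosomes of 1 Mb, 60 non-overlapping peaks (0.5–2 kb), 40 genes
(5–20 kb), 50 000 fragments, fragment length Gaussian (mean 200 bp,
sd 15 bp), 30% in-peak placement weighted by peak width × lognormal
strength (σ = 1), 10% per-tag duplication, 50 bp reads,
constant-quality FASTQ. Each fragment emits a + tag at its start and a
− tag at its end, which is what gives the cross-correlation a genuine
fragment-length peak; the length spread matters because a fixed length
concentrates the +/− coupling at a single 1 bp shift that a 5 bp grid
misses. Truth tallies (distinct keys, singletons, in-peak tags) are
counted from the emitted tags themselves, so NRF/PBC/FRiP recovery is
exact, not approximate. All randomness flows through one explicit seed.

The strand-independent null (`simulate_null_tags`) keeps the marginal
placement law but draws every tag position independently with a random
strand. Its scale is dictated by what makes NSC ≈ 1 a valid expectation:
enrichment domains must be much wider than the maximum shift (otherwise
the enrichment autocorrelation itself makes cc decay across the grid —
with 500 bp peaks the null legitimately shows NSC ≫ 1), and depth must
be high enough that per-shift counting noise is small against the cc
level. The null therefore uses 8 domains of 100 kb on 8 × 2 Mb with 2 M
fragments at 90% in-domain placement, where measured NSC is ~1.005.

What the fixtures do not model: mappability structure (so no real
phantom peak — the predicted tag length on simulated data reflects
window-local noise and E stays small), base-call errors, GC bias,
paired-end information, and genome-scale metric magnitudes (read/peak
counts rank Poor by construction on a 2 Mb genome). Passing tests
establish correctness of the computations and conventions, not
instrument-level realism.

## Problem sizes and runtime

Defaults keep a full pipeline run on the toy fixture under ~2 s and the
whole test suite under a minute: 50 k fragments for recovery runs (80
simulations across fragment lengths 100/150/200/300), 100 randomized
instances per brute-force oracle, 2 null seeds. The acceptance script
re-runs the complete pipeline plus one null in ~10 s.

## Known limitations

Single-end tag semantics throughout (no mate rescue, no
optical-duplicate or UMI handling); no mappability correction in the
cross-correlation; GTF parsing covers gene/transcript/exon features with
`gene_id` attributes, not full GFF3 semantics; the super cutoff is
rank-curve geometry and inherits its instability when region counts are
very small (fewer than 3 regions → no supers, with a warning).
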