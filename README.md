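# occuqc

Quality control for chromatin occupancy sequencing (ChIP-seq, CUT&RUN).

Antibody-pulldown sequencing experiments stand or fall on library quality
and enrichment strength, yet the relevant diagnostics are scattered across
many tools. `occuqc` computes the standard panel in one pass from the
files every pipeline already produces — aligned reads, peak calls, a gene
annotation, optionally a blacklist and the raw FASTQ — and renders every
metric on a five-scale color-rank dashboard with a single overall quality
score, so a failed experiment is visible at a glance.

## Metrics

**Sequencing library.** Raw read count *R*; aligned percent
*A = 100 · mapped/raw*; non-redundant fraction
*NRF = distinct (chrom, 5′ position, strand) keys / mapped tags*
(ENCODE convention); PCR bottleneck coefficient
*C = singleton keys / covered keys*; per-base quality flag *B* and
exact-sequence overrepresentation flag *D* from the FASTQ.

**Strand cross-correlation.** For each shift *s*, cc(*s*) is the Pearson
correlation between the + strand 5′-occupancy vector and the − strand
vector shifted by *s* (per chromosome, tag-weighted mean). The profile
peaks near the fragment length and, on real data, near the read length
(the mappability "phantom peak"). From it: the estimated fragment width,
the predicted tag length and its deviation *E* from the FASTQ read
length, *NSC = max cc / background cc*, and
*RSC = (cc_fragment − background)/(cc_readlen − background)*.

**Enrichment.** Peak count *P* (and control-corrected peak count *N* when
a second peak file is given); fraction of reads in peaks *F*; ROSE-style
stitching of peaks within 12.5 kb into regions, scored as
control-corrected tags-per-million and split into typical and
super-enhancer-like regions by the slope-1 tangent of the min-max-scaled
rank/signal curve, giving the stitched count *L* and super ratio
*S = supers / L*.

**Profiles.** Promoter (TSS ± 2 kb) and metagene (length-normalized body
+ flanks) coverage matrices in tags-per-million per bp, with average
profiles and a promoter / gene body / gene-centric window / intergenic
annotation of every peak.

Each metric is flagged Excellent / Good / Average / Below-average / Poor
(scores 2 / 1 / 0 / −1 / −2; e.g. NRF ≥ 0.8 and FRiP ≥ 0.05 are
Excellent, NSC ≥ 1.045 passes); the overall quality *Q* is the mean score
of the computable metrics, flagged on the same scale. Metrics whose
inputs are absent (FASTQ-based flags, normalized peaks) are reported NA
and excluded from *Q*.

## Worked example

`occuqc` ships a synthetic-data generator (toy 2 × 1 Mb genome, 50 000
fragments, 30% in-peak placement, 10% duplication) so the whole pipeline
can be exercised without downloads:

```sh
occuqc simulate --out demo --seed 7
occuqc qc --reads demo/tags.bed --peaks demo/peaks.bed \
          --genes demo/genes.gtf --blacklist demo/blacklist.bed \
          --fastq demo/reads.fastq --chrom-sizes demo/chrom.sizes \
          --out demo_qc
```

prints `overall quality Q = 0.923 (Average)` and writes
`demo_qc/occuqc-stats.tsv`:

```
metric	value	rank	score
Aligned percent (A)	100.0	Excellent	2
Base quality (B)	pass	Excellent	2
Estimated fragment width	200	–
Estimated tag length (E)	5	Excellent	2
FRiP (F)	0.2757	Excellent	2
Linear stitched peaks (L)	40	Poor	-2
Non-redundant fraction (NRF)	0.8579	Excellent	2
Normalized peaks (N)	NA	–
NSC	1.8818	Excellent	2
Sequence diversity (D)	pass	Excellent	2
PCR bottleneck coefficient (C)	0.8536	Good	1
Peaks (P)	60	Poor	-2
Raw reads (R)	110,092	Poor	-2
Read length	50	–
RSC	3.4469	Excellent	2
SE-like enriched regions	7	–
Super stitched ratio (S)	0.1750	Good	1
Overall quality (Q)	0.9231	Average	0
```

Reading the panel: the library itself is clean (everything mapped, NRF
0.86, fragment width recovered at the simulated 200 bp, NSC/RSC well
above threshold, FRiP 0.28), while the count-based metrics (*R*, *P*,
*L*) are Poor simply because a 2 Mb toy genome cannot yield 30 M reads or
10 000 peaks — exactly the mixed verdict the averaged *Q* is designed to
express. `occuqc-stats.html` is the same table with color-coded rank
cells; the stitched regions, coverage matrices, profiles and per-peak
annotations are written alongside.

The same analyses are available per-stage (`occuqc xcor`, `stitch`,
`profile`, `annotate`, `report`) and as library functions
(`occuqc.library`, `occuqc.xcor`, `occuqc.enrichment`,
`occuqc.profiling`, `occuqc.ranking`).

Tag BED input is 6-column BED (name/score ignored, strand required);
SAM/BAM input is filtered to primary mapped records with MAPQ ≥ 10
(`--mapq`). All internal coordinates are 0-based half-open.

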