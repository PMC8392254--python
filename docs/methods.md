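# Methods

## Scope and data model

The package analyzes one linearized mitochondrial reference at a time. All
internal coordinates are 0-based half-open; GFF3 and boundary tables are
converted at the I/O boundary, BED/bedGraph pass through unchanged. Features
spanning the origin of a circular genome are not supported: rotate or split
the annotation first. Trans-spliced genes are modelled as separate gene
regions sharing a `coding_unit_id`, so boundary analyses run per region.

Masked intervals (plastid-like insertions that attract mis-mapped chloroplast
reads) stay in the depth arrays — coordinates never shift — but receive no
counts and are excluded from every statistic; they also split low-coverage
intervals.

## Depth semantics

A read contributes depth at each reference position with an aligned base
(CIGAR M/=/X); deletions and skips do not increment depth. This fixed rule
makes the conservation check (array sum = aligned bases of retained reads on
unmasked positions) meaningful. Template-strand assignment for paired-end
stranded libraries is configurable via `mate_defines_strand`; the default (2)
matches TruSeq stranded chemistry, where read 2 aligns in the sense of the
transcript. Unpaired records are taken at face value. No mapping-quality
filter is applied by default (`min_mapq` exposes one).

"Both strands" coverage fractions use the denominator 2 × unmasked length:
each strand-position counts separately, which is the only reading under which
a both-strands fraction can fall below the single-strand one.

## RPKM

RPKM = counts × 10⁹ / (spliced transcript length × total counts), with the
total restricted to protein-coding genes — the convention for organellar
expression tables, where rRNA dominates raw totals. Fragment counting
(distinct query names) is the default unit for paired-end data;
`count_mates=True` counts records instead. When only a depth track is
available, counts are approximated as total exonic depth / read length
(default 89 bp).

## TSS inference

Slopes of per-base depth are computed by least squares within each 50-bp
window tiling the 2-kb upstream span (both defaults configurable; the window
must divide the span). Regression rather than an endpoint difference is used
because it is noise-robust and equals the endpoint response on clean steps.
Each window's fit includes one guard base beyond each window edge: a step
landing exactly on a window boundary would otherwise leave both adjacent
windows flat and the ranking uninformative; on a linear ramp the guard bases
leave the estimate unchanged. Slopes are sign-oriented so positive means
rising toward the gene on either strand.

The top-n windows by slope (ties broken toward the gene-proximal window;
default n = 3, since genes commonly carry several promoters) are putative
TSS. A call is `matched` when a known TSS lies within 50 bp of the window
midpoint (a 100-bp total window), `inside_upstream_gene` when the window
overlaps another same-strand gene's exons (depth there is uninformative
about initiation), `upstream_of_known` when it lies 5′ of every known TSS,
else `unmatched`.

## 3′ termini

Scanning downstream of the stop in 50-bp windows, the terminus is the first
window whose mean depth falls below `drop_fraction` (default 0.5) of the
gene-body mean. Reported drops are typically near-complete returns to
background, so the calls are insensitive to the exact fraction; it is exposed
because no numeric rule is canonical. If a downstream same-strand gene is
reached before any drop the call is `obscured_by_downstream_gene`.

## Co-transcription

Candidate pairs are *all* same-strand pairs with separation ≤ 2 kb between
nearest coding ends (not only adjacent ones); overlaps are reported with
negative separation. Pairs separated by < 150 bp, or overlapping, are
excluded from classification — the transcription bubbles of independently
transcribed neighbors already overlap at that distance — but their depth
statistics are still reported. Otherwise the minimum of 50-bp windowed mean
depth across the gap is compared with τ × the weaker gene-body mean
(τ = 0.5 default): at or above is `continuous`, below is `drop`. The ratio
criterion is this package's operationalization of visual continuity; it is
monotone in τ, and τ is a flag.

## Splicing efficiency

Junctions are scored on extended per-gene references (±100 bp flanks):
EI5′ and I3′E on the unspliced reference, EE on the spliced one. A read
supports a junction when its alignment crosses the boundary with ≥ 1 aligned
base on each side; the ±30-bp windows bound the evaluation region rather
than imposing a minimum overhang (an overhang rule would discard most 89-bp
reads asymmetrically). Each query counts at most once per junction.
Exon-only reads map to both references and cross no junction, so no
de-duplication between the two alignments is needed.

SE = N_EE / (N_EE + 0.5·N_EI5′ + 0.5·N_I3′E). The halves reflect that one
intact precursor molecule carries two unspliced junctions for every single
exon–exon junction of a mature molecule, making SE an unbiased estimate of
the spliced fraction under uniform junction sampling. The I3′E/EI5′ ratio is
reported as undefined (empty cell) when N_EI5′ = 0. Tables print SE and the
ratio at two decimals with half-up rounding. Junction counting refuses
introns whose flanking exon is shorter than the flank window (the reason the
two trans-spliced nad5 introns around the very short exon 3 are not
analyzable) and reports why.

Group comparisons (cis vs trans; branching vs hydrolytic vs both) use
one-way ANOVA via `scipy.stats.f_oneway`, with the two degenerate
zero-within-variance cases handled explicitly: identical group means give
F = 0, p = 1; perfectly separated groups give F = +inf, p = 0.

## Synthetic data

The generator emulates the coverage anatomy the analyses rely on: background
depth on both strands everywhere (pervasive transcription, default 20×),
stepwise increases at each promoter with plateau height equal to promoter
strength, co-transcribed units covered by one transcription interval, a drop
to background at the programmed terminus, intron depth reduced to background
plus (1 − s) of the elevation, and optional per-base Poisson noise (the
default — the simplest count-noise model for depth data). Junction evidence
is emitted as minimal SAM records: per sampled molecule, one EE read if
spliced (probability s) or one EI5′ plus one I3′E read if unspliced, with
uniform junction-crossing start positions. Under this molecule-level model
the SE estimator is exactly a binomial proportion, which is what makes
"within k binomial standard errors" a well-defined recovery criterion. The
`random` layout places one gene per 6-kb slot with promoter strengths of
100–1000× over a 20× background — gene-body elevations of the order seen for
mitochondrial protein-coding genes — and is the configuration used for the
parameter-recovery tests (120 genes for TSS recovery; 200 replicates of
10,000 molecules at s ∈ {0.5, 0.8, 0.95} for SE recovery).

What the generator does *not* model: read-length effects and paired-end
fragment geometry in the coverage track (depth is drawn directly), mapping
ambiguity from repeats or plastid-like regions, RNA editing, base-quality or
sequencing error, and coverage heterogeneity within exons beyond the intron
effect. Passing recovery tests therefore demonstrate correctness of the
estimators under clean step-like signals with count noise, not robustness to
every artifact of real libraries.

A separate fixture reproduces two published inputs for the Arabidopsis
mtDNA: the junction-count triples of its 21 analyzable group II introns
(pooled PRJEB15579 runs, against accession BK010421), used to reproduce the
printed SE/ratio table, and a synthetic genome mirroring the close-pair
geometry (11 same-strand pairs within 2 kb; three unresolvable by overlap or
< 150 bp separation; of the 8 evaluable, 3 co-transcribed and 5 independent).

## Numerical choices

* Half-up rounding (via `decimal`) for printed 2-decimal values; Python's
  banker's rounding would flip ties like 5.455 → 5.46.
* Least-squares slopes use the closed form with centered x; windows shorter
  than 2 bases return slope 0.
* Window histograms assign each 100-bp window to the half-open depth bin
  containing its unmasked mean; fully masked windows are dropped.
* Pair classification uses ≥ τ for `continuous` so τ = 1.0 still allows a
  perfectly flat dicistron.
* `zero_coverage_intervals` treats masked positions as absent: runs split at
  mask edges.

## Limitations

* Circular-origin features are unsupported by design; linearize first.
* The depth-based read-count approximation ignores read-length edge effects
  at exon boundaries.
* TSS calls report candidate *regions* (window midpoints), not base-precise
  starts; accuracy is bounded by the window size.
* Multi-mapped reads are counted once per gene reference they align to;
  callers who need unique-read counting should pre-filter their alignments.
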