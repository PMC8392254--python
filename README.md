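# mito-txscape

Transcriptional-landscape analysis for plant mitochondrial genomes from
strand-specific RNAseq.

Plant mtDNAs are pervasively transcribed: nearly every base of both strands
carries some read depth, while functional genes sit on strongly elevated
plateaus. Promoters have no conserved motif and genes often have several, so
the *shape* of the stranded coverage profile — not sequence — is the usable
signal for where transcription starts and stops, which neighboring genes are
transcribed together, and how efficiently group II introns are spliced. This
package turns those profile-reading heuristics into a tested, reusable
pipeline for anyone with a mitochondrial annotation plus stranded coverage
(bedGraph) or alignments (SAM).

## What it computes

* **Coverage statistics** — per-strand per-base depth with masking of
  plastid-like regions; the fraction of strand-positions with depth ≥ *t*,
  pooled and intergenic mean depth, 100-bp window depth histograms, and
  maximal low/zero-coverage intervals.
* **Expression** — per-gene counts and
  RPKM<sub>g</sub> = N<sub>g</sub>·10⁹ / (L<sub>g</sub>·N<sub>total</sub>),
  with the denominator restricted to protein-coding genes and L the spliced
  transcript length; per-exon mean depths.
* **Transcription start sites** — least-squares slopes of depth in 50-bp
  windows across the 2 kb upstream of each gene (strand-aware); the
  top-ranked windows are putative TSS and are matched against known
  promoters within a 100-bp window.
* **3′ termini** — the first downstream 50-bp window whose mean depth falls
  below half the gene-body mean, flagged when a downstream gene obscures the
  signal.
* **Co-transcription** — same-strand gene pairs within 2 kb are
  `continuous` when the minimum windowed intergenic depth stays at or above
  τ (default 0.5) times the weaker gene-body mean, `drop` otherwise; pairs
  closer than 150 bp or overlapping are reported but not classified.
* **Splicing efficiency** — junction-spanning reads on spliced/unspliced
  per-gene references, counted in ±30-bp windows around each junction:

  SE = N<sub>EE</sub> / (N<sub>EE</sub> + 0.5·N<sub>EI5′</sub> + 0.5·N<sub>I3′E</sub>)

  together with the I3′E/EI5′ ratio and one-way ANOVA of SE across cis/trans
  splice types or splicing mechanisms (branching / hydrolytic).
* **Synthetic data** — a generator that emits genome FASTA, GFF3, boundary
  tables, stranded bedGraph and junction SAM files with full ground truth
  (true TSS, termini, co-transcription labels, splicing fractions), so every
  stage is testable without downloads.

## Worked example

```python
from mitotxscape.synthetic import SyntheticSpec, SyntheticGene, SyntheticIntron, generate
from mitotxscape.boundaries import slope_profile, call_tss
from mitotxscape.splicing import count_junction_reads, splicing_efficiency

spec = SyntheticSpec(
    genome_length=20_000,
    genes=[SyntheticGene("nad-like", 3000, 6000, "+", promoters=[(430, 150.0)],
                         introns=[SyntheticIntron("nad-like_i1", 800, 1200, s=0.8,
                                                  n_molecules=5000)])],
    background_depth=20, seed=11)
bundle = generate(spec, outdir="demo")

calls = call_tss(slope_profile(bundle.depth, bundle.genes[0]),
                 bundle.boundaries, bundle.genes)
print(f"rank-1 TSS window {calls[0].window}, slope {calls[0].slope:.2f}, "
      f"status {calls[0].match_status} (true TSS {bundle.truth.true_tss['nad-like'][0]})")

counts = count_junction_reads("demo/junctions/nad-like_unspliced.sam",
                              "demo/junctions/nad-like_spliced.sam",
                              bundle.introns[0], bundle.genes[0])
rec = splicing_efficiency(counts)
print(f"EI5'={counts.n_EI5} I3'E={counts.n_I3E} EE={counts.n_EE} "
      f"-> SE={rec.se:.3f} (true 0.8)")
```

prints

```
rank-1 TSS window (2550, 2600), slope 4.18, status matched (true TSS 2570)
EI5'=1024 I3'E=1024 EE=3976 -> SE=0.795 (true 0.8)
```

The highest-slope upstream window lands on the planted promoter step (its
midpoint is within 50 bp of the true start), and the junction-read SE
estimate recovers the true splicing fraction of 0.8 to within binomial
sampling error at 5,000 sampled molecules.

The same stages are available from the shell:

```sh
mito-txscape simulate --seed 5 --n-genes 20 --outdir sim/
mito-txscape run-all --config config.yaml
```

`run-all` executes coverage → expression → boundaries → co-transcription →
splicing, writes one TSV per stage plus `report.json` and `run.log`, and
embeds the resolved configuration in the report.

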