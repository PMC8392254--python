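"""Synthetic mitochondrial transcriptomes with known ground truth.

The generator emulates the coverage anatomy of a pervasively transcribed
plant mtDNA: a low background depth everywhere on both strands, stepwise
depth increases at each promoter (step height proportional to promoter
strength), an elevated plateau across gene bodies and co-transcribed units,
a drop back to background at the 3' terminus, reduced depth over introns in
proportion to their splicing fraction, and optional per-base Poisson count
noise.  Junction evidence is emitted as minimal aligned SAM records against
the spliced/unspliced per-gene references — one EE read per spliced molecule
and one EI5' plus one I3'E read per unspliced molecule — so every pipeline
stage can be exercised hermetically, without an external aligner.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``SyntheticSpec.seed``; the same spec and seed produce byte-identical output.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .annotation import (GeneFeature, GenomeRef, IntronFeature, KnownBoundary,
                         write_boundary_table, write_gff3)
from .coverage import StrandedDepth, write_bedgraph
from .splicing import JunctionCounts, junction_ref_positions


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticIntron:
    """An intron planted inside a synthetic gene.  ``offset``/``length`` are
    relative to the gene's genomic start; ``s`` is the true splicing
    fraction; ``n_molecules`` transcript molecules are sampled for junction
    reads."""

    intron_id: str
    offset: int
    length: int
    s: float
    splice_type: str = "cis"
    mechanism: str = "branching"
    n_molecules: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise SyntheticSpecError(f"{self.intron_id}: s={self.s} outside [0, 1]")


@dataclass
class SyntheticGene:
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    promoters: list[tuple[int, float]] = field(default_factory=lambda: [(500, 100.0)])
    terminus_offset: int = 200
    terminus_drop: bool = True
    feature_class: str = "protein"
    introns: list[SyntheticIntron] = field(default_factory=list)


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic genome."""

    genome_length: int
    genes: list[SyntheticGene]
    background_depth: float = 20.0
    noise_model: str = "poisson"  # poisson | none
    seed: int = 0
    cotranscribed_units: list[list[str]] = field(default_factory=list)
    planted_motifs: list[tuple[str, str, int, str]] = field(default_factory=list)
    read_length: int = 89
    extension: int = 100
    ref_name: str = "synth_mt"

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson", "none"):
            raise SyntheticSpecError(f"unknown noise model {self.noise_model!r}")
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.genome_length):
                raise SyntheticSpecError(f"{g.gene_id}: outside genome")

    @classmethod
    def random(cls, n_genes: int, seed: int, slot: int = 6000,
               background_depth: float = 20.0,
               gene_depth_range: tuple[float, float] = (100.0, 1000.0),
               gene_length_range: tuple[int, int] = (900, 2000),
               tss_offset_range: tuple[int, int] = (100, 1800),
               noise_model: str = "poisson", mixed_strands: bool = True
               ) -> "SyntheticSpec":
        """One gene per ``slot`` bp, each with a single promoter of strength
        drawn from ``gene_depth_range`` (above background) and a programmed
        3' drop — the layout used for TSS/terminus parameter-recovery
        studies.  Slots are wide enough that transcription bubbles of
        neighboring genes never overlap."""
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(n_genes):
            base = i * slot
            length = int(rng.integers(*gene_length_range, endpoint=True))
            start = base + 2200
            strand = "+" if (not mixed_strands or rng.random() < 0.5) else "-"
            offset = int(rng.integers(*tss_offset_range, endpoint=True))
            strength = float(rng.uniform(*gene_depth_range))
            genes.append(SyntheticGene(
                gene_id=f"g{i:03d}", start=start, end=start + length, strand=strand,
                promoters=[(offset, strength)]))
        return cls(genome_length=n_genes * slot, genes=genes,
                   background_depth=background_depth, noise_model=noise_model,
                   seed=seed)


@dataclass
class SyntheticTruth:
    true_tss: dict[str, list[int]]
    true_termini: dict[str, int]
    true_se: dict[str, float]
    true_cotx: dict[tuple[str, str], bool]
    manifest: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    ref: GenomeRef
    genes: list[GeneFeature]
    introns: list[IntronFeature]
    boundaries: list[KnownBoundary]
    depth: StrandedDepth
    junction_sams: dict[str, tuple[str, str]]  # gene_id -> (unspliced, spliced) SAM text
    truth: SyntheticTruth


def _gene_exons(g: SyntheticGene) -> list[tuple[int, int]]:
    cuts = []
    for i in sorted(g.introns, key=lambda i: i.offset):
        cuts.append((g.start + i.offset, g.start + i.offset + i.length))
    exons, prev = [], g.start
    for i_s, i_e in cuts:
        if not (g.start < i_s < i_e < g.end):
            raise SyntheticSpecError(f"{g.gene_id}: intron outside gene body")
        exons.append((prev, i_s))
        prev = i_e
    exons.append((prev, g.end))
    return exons


def _sam_text(ref_name: str, ref_seq: str, reads: list[tuple[str, int]],
              read_length: int) -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown",
             f"@SQ\tSN:{ref_name}\tLN:{len(ref_seq)}"]
    for qname, pos in reads:
        seq = ref_seq[pos:pos + read_length]
        lines.append("\t".join([qname, "0", ref_name, str(pos + 1), "60",
                                f"{len(seq)}M", "*", "0", "0", seq, "*"]))
    return "\n".join(lines) + "\n"


def _crossing_starts(rng: np.random.Generator, boundary: int, n: int,
                     read_length: int, ref_length: int) -> np.ndarray:
    """Uniform start positions whose reads cross ``boundary`` with >= 1 base
    on each side."""
    lo = max(boundary - read_length + 1, 0)
    hi = min(boundary - 1, ref_length - read_length)
    if hi < lo:
        raise SyntheticSpecError("reference too short for junction reads")
    return rng.integers(lo, hi, size=n, endpoint=True)


def generate(spec: SyntheticSpec, outdir: str | None = None) -> SyntheticBundle:
    """Realize a synthetic spec into genome, annotation, stranded depth,
    junction alignments and a ground-truth record; optionally write the
    bundle (FASTA, GFF3, boundary TSV, bedGraph pair, per-gene SAMs, truth
    JSON) under ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=L)].tobytes().decode("ascii")
    for label, motif, pos, strand in spec.planted_motifs:
        m = motif.upper() if strand == "+" else str(Seq(motif.upper()).reverse_complement())
        if pos + len(m) > L:
            raise SyntheticSpecError(f"planted motif {label} runs past genome end")
        seq = seq[:pos] + m + seq[pos + len(m):]
    ref = GenomeRef(spec.ref_name, L, sequence=seq)

    # annotation objects
    genes: list[GeneFeature] = []
    introns: list[IntronFeature] = []
    by_id: dict[str, SyntheticGene] = {}
    unit_of = {gid: f"unit{k}" for k, unit in enumerate(spec.cotranscribed_units)
               for gid in unit}
    for g in spec.genes:
        by_id[g.gene_id] = g
        exons = _gene_exons(g)
        gf = GeneFeature(gene_id=g.gene_id, strand=g.strand,
                         feature_class=g.feature_class, exons=exons,
                         coding_unit_id=unit_of.get(g.gene_id))
        genes.append(gf)
        for intr in sorted(g.introns, key=lambda i: i.offset):
            i_s, i_e = g.start + intr.offset, g.start + intr.offset + intr.length
            donor, acceptor = (i_s, i_e) if g.strand == "+" else (i_e, i_s)
            from .annotation import _flanking_exon_lengths
            introns.append(IntronFeature(
                intron_id=intr.intron_id, gene_id=g.gene_id,
                splice_type=intr.splice_type, mechanism=intr.mechanism,
                donor_pos=donor, acceptor_pos=acceptor,
                flanking_exon_lengths=_flanking_exon_lengths(gf, i_s, i_e)))

    # reject overlapping same-strand genes unless co-transcribed together
    by_strand: dict[str, list[GeneFeature]] = {"+": [], "-": []}
    for gf in genes:
        by_strand[gf.strand].append(gf)
    for strand, gs in by_strand.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            same_unit = a.gene_id in unit_of and \
                unit_of.get(a.gene_id) == unit_of.get(b.gene_id)
            if b.start < a.end and not same_unit:
                raise SyntheticSpecError(
                    f"{a.gene_id} and {b.gene_id} overlap on strand {strand} "
                    "but are not declared co-transcribed")

    # expected (noise-free) depth
    expected = {"+": np.full(L, float(spec.background_depth)),
                "-": np.full(L, float(spec.background_depth))}
    units: list[list[SyntheticGene]] = [
        sorted((by_id[gid] for gid in unit), key=lambda g: g.start)
        for unit in spec.cotranscribed_units]
    in_unit = set(unit_of)
    units += [[g] for g in spec.genes if g.gene_id not in in_unit]

    true_tss: dict[str, list[int]] = {g.gene_id: [] for g in spec.genes}
    true_termini: dict[str, int] = {}
    for unit in units:
        strand = unit[0].strand
        lead = unit[0] if strand == "+" else unit[-1]
        trail = unit[-1] if strand == "+" else unit[0]
        if strand == "+":
            terminus = min(trail.end + trail.terminus_offset
                           if trail.terminus_drop else trail.end + 3000, L)
        else:
            terminus = max(trail.start - trail.terminus_offset
                           if trail.terminus_drop else trail.start - 3000, 0)
        for off, strength in lead.promoters:
            if strand == "+":
                tss = max(lead.start - off, 0)
                expected["+"][tss:terminus] += strength
            else:
                tss = min(lead.end + off, L)
                expected["-"][terminus:tss] += strength
            true_tss[lead.gene_id].append(tss)
        if trail.terminus_drop:
            true_termini[trail.gene_id] = terminus

    # introns: unspliced fraction (1 - s) of the elevated signal remains
    for g in spec.genes:
        arr = expected[g.strand]
        for intr in g.introns:
            i_s, i_e = g.start + intr.offset, g.start + intr.offset + intr.length
            arr[i_s:i_e] = spec.background_depth + \
                (1.0 - intr.s) * (arr[i_s:i_e] - spec.background_depth)

    if spec.noise_model == "poisson":
        plus = rng.poisson(expected["+"]).astype(np.int64)
        minus = rng.poisson(expected["-"]).astype(np.int64)
    else:
        plus = np.rint(expected["+"]).astype(np.int64)
        minus = np.rint(expected["-"]).astype(np.int64)
    depth = StrandedDepth(ref, plus, minus)

    # junction reads against per-gene references
    junction_sams: dict[str, tuple[str, str]] = {}
    true_se: dict[str, float] = {}
    intron_by_gene: dict[str, list[IntronFeature]] = {}
    for i in introns:
        intron_by_gene.setdefault(i.gene_id, []).append(i)
    for gf in genes:
        if gf.gene_id not in intron_by_gene:
            continue
        sg = by_id[gf.gene_id]
        ext = spec.extension
        s0, e0 = gf.span
        us_seq = seq[max(s0 - ext, 0):min(e0 + ext, L)]
        sp_seq = (seq[max(s0 - ext, 0):s0]
                  + "".join(seq[a:b] for a, b in gf.exons)
                  + seq[e0:min(e0 + ext, L)])
        if gf.strand == "-":
            us_seq = str(Seq(us_seq).reverse_complement())
            sp_seq = str(Seq(sp_seq).reverse_complement())
        us_reads: list[tuple[str, int]] = []
        sp_reads: list[tuple[str, int]] = []
        for intr_f in intron_by_gene[gf.gene_id]:
            sintr = next(i for i in sg.introns if i.intron_id == intr_f.intron_id)
            ei5, i3e, ee = junction_ref_positions(gf, intr_f, ext)
            m = sintr.n_molecules
            n_spliced = int(rng.binomial(m, sintr.s))
            n_unspliced = m - n_spliced
            for k, p in enumerate(_crossing_starts(rng, ee, n_spliced,
                                                   spec.read_length, len(sp_seq))):
                sp_reads.append((f"{intr_f.intron_id}_ee_{k}", int(p)))
            for k, p in enumerate(_crossing_starts(rng, ei5, n_unspliced,
                                                   spec.read_length, len(us_seq))):
                us_reads.append((f"{intr_f.intron_id}_ei5_{k}", int(p)))
            for k, p in enumerate(_crossing_starts(rng, i3e, n_unspliced,
                                                   spec.read_length, len(us_seq))):
                us_reads.append((f"{intr_f.intron_id}_i3e_{k}", int(p)))
            true_se[intr_f.intron_id] = sintr.s
        junction_sams[gf.gene_id] = (
            _sam_text(f"{gf.gene_id}_unspliced", us_seq, us_reads, spec.read_length),
            _sam_text(f"{gf.gene_id}_spliced", sp_seq, sp_reads, spec.read_length))

    # co-transcription truth over candidate pairs
    from .cotranscription import candidate_pairs
    true_cotx = {(a.gene_id, b.gene_id): unit_of.get(a.gene_id) is not None
                 and unit_of.get(a.gene_id) == unit_of.get(b.gene_id)
                 for a, b, _sep in candidate_pairs(genes)}

    boundaries = [KnownBoundary(gid, "tss", pos, label=f"p{gid}-{k}")
                  for gid, positions in true_tss.items()
                  for k, pos in enumerate(positions, 1)]
    boundaries += [KnownBoundary(gid, "terminus_3p", pos)
                   for gid, pos in true_termini.items()]

    truth = SyntheticTruth(true_tss=true_tss, true_termini=true_termini,
                           true_se=true_se, true_cotx=true_cotx)
    bundle = SyntheticBundle(spec=spec, ref=ref, genes=genes, introns=introns,
                             boundaries=boundaries, depth=depth,
                             junction_sams=junction_sams, truth=truth)
    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: SyntheticBundle, outdir: str) -> None:
    from Bio.Seq import Seq as _Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    os.makedirs(outdir, exist_ok=True)
    man = bundle.truth.manifest
    man["fasta"] = os.path.join(outdir, "genome.fasta")
    seqio_write([SeqRecord(_Seq(bundle.ref.sequence), id=bundle.ref.name,
                           description="synthetic mitochondrial genome")],
                man["fasta"], "fasta")
    man["gff3"] = os.path.join(outdir, "annotation.gff3")
    write_gff3(bundle.ref, bundle.genes, bundle.introns, man["gff3"])
    man["boundaries"] = os.path.join(outdir, "boundaries.tsv")
    write_boundary_table(bundle.boundaries, man["boundaries"])
    man["bedgraph_plus"] = os.path.join(outdir, "depth_plus.bedgraph")
    man["bedgraph_minus"] = os.path.join(outdir, "depth_minus.bedgraph")
    write_bedgraph(bundle.depth, man["bedgraph_plus"], man["bedgraph_minus"])
    jdir = os.path.join(outdir, "junctions")
    os.makedirs(jdir, exist_ok=True)
    for gid, (us, sp) in bundle.junction_sams.items():
        for kind, text in (("unspliced", us), ("spliced", sp)):
            path = os.path.join(jdir, f"{gid}_{kind}.sam")
            with open(path, "w") as fh:
                fh.write(text)
            man[f"junctions/{gid}/{kind}"] = path
    man["truth"] = os.path.join(outdir, "truth.json")
    with open(man["truth"], "w") as fh:
        json.dump({
            "true_tss": bundle.truth.true_tss,
            "true_termini": bundle.truth.true_termini,
            "true_se": bundle.truth.true_se,
            "true_cotx": {f"{a}|{b}": v for (a, b), v in bundle.truth.true_cotx.items()},
        }, fh, indent=1, sort_keys=True)


def simulate_junction_counts(rng: np.random.Generator, s: float,
                             n_molecules: int) -> JunctionCounts:
    """Counts-level junction model: each sampled molecule is spliced with
    probability ``s`` and yields one EE read; an unspliced molecule yields
    one EI5' and one I3'E read.  The SE estimator on these counts is exactly
    a binomial proportion with ``n_molecules`` trials."""
    n_spliced = int(rng.binomial(n_molecules, s))
    n_unspliced = n_molecules - n_spliced
    return JunctionCounts(intron_id="sim", n_EI5=n_unspliced, n_I3E=n_unspliced,
                          n_EE=n_spliced)


# ---------------------------------------------------------------------------
# published Arabidopsis inputs

#: Junction-spanning read counts for the 21 analyzable group II introns of the
#: Arabidopsis thaliana Col-0 mitochondrial genome (accession BK010421),
#: derived from the pooled public RNAseq runs of BioProject PRJEB15579.
#: Columns: intron_id, splice_type, mechanism, n_EI5, n_I3E, n_EE.  The
#: trans-spliced introns nad5i2/nad5i3 are absent: nad5 exon 3 is shorter
#: than the 30-bp junction flank.
ARABIDOPSIS_INTRON_COUNTS: list[tuple[str, str, str, int, int, int]] = [
    ("ccmFci", "cis", "branching", 192, 356, 1149),
    ("cox2i", "cis", "branching", 129, 282, 12433),
    ("nad1i1", "trans", "hydrolytic", 180, 1197, 944),
    ("nad1i2", "cis", "hydrolytic", 151, 174, 2322),
    ("nad1i3", "trans", "both", 187, 945, 3210),
    ("nad1i4", "cis", "branching", 240, 1280, 1982),
    ("nad2i1", "cis", "hydrolytic", 141, 437, 919),
    ("nad2i2", "trans", "branching", 54, 476, 1958),
    ("nad2i3", "cis", "branching", 59, 581, 1471),
    ("nad2i4", "cis", "branching", 389, 460, 2688),
    ("nad4i1", "cis", "both", 480, 633, 2498),
    ("nad4i2", "cis", "hydrolytic", 144, 125, 6924),
    ("nad4i3", "cis", "branching", 163, 468, 8402),
    ("nad5i1", "cis", "branching", 278, 817, 1452),
    ("nad5i4", "cis", "branching", 189, 1031, 17008),
    ("nad7i1", "cis", "hydrolytic", 75, 135, 639),
    ("nad7i2", "cis", "branching", 177, 1379, 1169),
    ("nad7i3", "cis", "branching", 104, 332, 4001),
    ("nad7i4", "cis", "branching", 209, 304, 2685),
    ("rpl2i", "cis", "both", 122, 685, 465),
    ("rps3i", "cis", "branching", 496, 211, 734),
]


@dataclass
class ArabidopsisFixture:
    """Published junction counts plus a synthetic genome reproducing the
    co-transcription geometry of the Arabidopsis mtDNA's 11 close gene
    pairs (8 evaluable: 3 continuous, 5 with an intergenic drop)."""

    junction_counts: list[JunctionCounts]
    splice_meta: dict[str, tuple[str, str]]  # intron_id -> (splice_type, mechanism)
    pair_ref: GenomeRef
    pair_genes: list[GeneFeature]
    pair_depth: StrandedDepth
    continuous_pairs: set[tuple[str, str]]
    excluded_pairs: set[tuple[str, str]]


def arabidopsis_fixture(background_depth: int = 20,
                        gene_depth: int = 200) -> ArabidopsisFixture:
    """Build the Arabidopsis reference fixture.

    The gene-pair genome mirrors the published geometry: the 11 same-strand
    pairs within 2 kb, of which rps3-rpl16 overlap, nad3-rps12 and
    nad1e4e5-nad5e1e2 sit closer than 150 bp (all three unresolvable), and of
    the remaining 8 the units rpl16-nad9, rpl5(psi-rps14)-cob and nad4L-atp4
    are co-transcribed (continuously elevated depth) while the other five
    show an intergenic drop to background.
    """
    counts = [JunctionCounts(intron_id=i, n_EI5=a, n_I3E=b, n_EE=c)
              for i, _st, _m, a, b, c in ARABIDOPSIS_INTRON_COUNTS]
    meta = {i: (st, m) for i, st, m, *_ in ARABIDOPSIS_INTRON_COUNTS}

    layout = [  # gene_id, start, end
        ("rps3", 800, 3000), ("rpl16", 2900, 3400), ("nad9", 5100, 5700),
        ("nad5e4e5", 6700, 7200), ("rps4", 10000, 11000),
        ("nad2e1e2", 11500, 12500), ("rpl5_psi_rps14", 15000, 15500),
        ("cob", 16000, 17000), ("rpl2", 19500, 20500), ("mttB", 21000, 21700),
        ("nad1e4e5", 24000, 24500), ("nad5e1e2", 24600, 25100),
        ("atp8", 27200, 27700), ("nad7", 28500, 30500), ("nad3", 32600, 33000),
        ("rps12", 33080, 33400), ("nad5e3", 35500, 35900),
        ("nad4L", 37600, 37900), ("atp4", 38200, 38800),
    ]
    continuous = {("rpl16", "nad9"), ("rpl5_psi_rps14", "cob"), ("nad4L", "atp4")}
    excluded = {("rps3", "rpl16"), ("nad3", "rps12"), ("nad1e4e5", "nad5e1e2")}

    ref = GenomeRef("ath_pairs_synthetic", 40000)
    genes = [GeneFeature(gene_id=gid, strand="+", exons=[(s, e)])
             for gid, s, e in layout]
    plus = np.full(ref.length, background_depth, dtype=np.int64)
    span = {gid: (s, e) for gid, s, e in layout}
    for gid, s, e in layout:
        plus[s:e] = gene_depth
    for a, b in continuous | excluded:  # elevated across unresolvable gaps too
        plus[span[a][0]:span[b][1]] = gene_depth
    minus = np.full(ref.length, background_depth, dtype=np.int64)
    depth = StrandedDepth(ref, plus, minus)
    return ArabidopsisFixture(junction_counts=counts, splice_meta=meta,
                              pair_ref=ref, pair_genes=genes, pair_depth=depth,
                              continuous_pairs=continuous, excluded_pairs=excluded)
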